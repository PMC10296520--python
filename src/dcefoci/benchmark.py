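"""Desk-scale benchmark configurations.

The full study-scale configuration (default :class:`CohortParams` /
:class:`ModelConfig`) is impractical for quick verification runs, so the
package pins one reduced configuration here and uses it everywhere a
desk-scale end-to-end check is needed (test suite, acceptance script,
examples). Pinning it in one place keeps those checks comparable.

Choices (see docs/methods.md for rationale):

* volumes ``16 x 80 x 80`` voxels at ``2 x 0.66 x 0.66`` mm — enough in-plane
  field of view (53 mm) for every prior-scan lesion at native resolution;
* benchmark cohort: 15 cancer-with-abnormality + 25 cancer-free subjects with
  the contrast-separation knob at 100 signal units (20x the default noise sd),
  i.e. a deliberately separable cohort that tests learning machinery rather
  than clinical difficulty;
* model: the same block pattern as the default network with halved widths
  (8/16 and 8/16/32/32 channels, 64 hidden units), 12 epochs at learning rate
  1e-3 — small enough to retrain from scratch in every leave-one-out fold on
  one CPU.
"""

from __future__ import annotations

from .classifier import ModelConfig
from .cohort import CohortParams

#: Reduced-resolution grid for desk-scale runs (slices, rows, cols).
DESK_VOLUME_SHAPE = (16, 80, 80)

#: Contrast-separation knob for the separable benchmark, in signal units
#: (default noise sd is 5, so the margin is 20x the noise).
BENCHMARK_CONTRAST_SEPARATION = 100.0


def benchmark_cohort_params(seed: int = 0) -> CohortParams:
    """40-subject separable benchmark cohort at reduced resolution."""
    return CohortParams(
        n_cancer_with_abnormality=15,
        n_cancer_without=0,
        n_cancer_free=25,
        volume_shape=DESK_VOLUME_SHAPE,
        contrast_separation=BENCHMARK_CONTRAST_SEPARATION,
        seed=seed,
    )


def benchmark_model_config(seed: int = 0) -> ModelConfig:
    """Desk-scale network: halved widths, short schedule, faster Adam rate."""
    return ModelConfig(
        local_branch_blocks=[8, 16],
        context_branch_blocks=[8, 16, 32, 32],
        mlp_hidden=64,
        epochs=12,
        learning_rate=1e-3,
        batch_size=16,
        seed=seed,
    )
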