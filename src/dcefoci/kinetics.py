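"""Kinetic curve-type analysis for DCE-MRI lesions.

A lesion's time–intensity curve is summarized by two percent changes of the
ROI-mean signal enhancement (SE):

* initial enhancement  = 100 * (SE_post1 - SE_pre) / SE_pre
* delayed phase        = 100 * (SE_post4 - SE_post1) / SE_post1

and each is binned into the standard clinical categories: initial
``slow`` (< 50%), ``medium`` (50–100%, boundaries included), ``fast`` (> 100%);
delayed ``washout`` (< -10%), ``plateau`` (-10% to +10%, boundaries included),
``persistent`` (> +10%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateBaselineError

#: Baselines at or below this magnitude (signal units) are treated as degenerate.
EPSILON = 1e-6

INITIAL_CATEGORIES = ("slow", "medium", "fast")
DELAYED_CATEGORIES = ("persistent", "plateau", "washout")


@dataclass(frozen=True)
class TimeIntensityCurve:
    """ROI-mean raw signal at the pre-contrast, 1st and 4th post-contrast points."""

    se_pre: float
    se_post1: float
    se_post4: float
    #: optional full 5-point curve (pre + 4 post), when available
    all_points: tuple[float, ...] | None = None


@dataclass(frozen=True)
class KineticFeatures:
    initial_enhancement_pct: float
    delayed_phase_pct: float
    initial_category: str
    delayed_category: str


def initial_enhancement(curve: TimeIntensityCurve) -> float:
    """Percent signal change from pre-contrast to the first post-contrast point."""
    if curve.se_pre <= EPSILON:
        raise DegenerateBaselineError(
            f"pre-contrast SE {curve.se_pre!r} is at or below epsilon {EPSILON}"
        )
    return 100.0 * (curve.se_post1 - curve.se_pre) / curve.se_pre


def delayed_phase(curve: TimeIntensityCurve) -> float:
    """Percent signal change from the first to the fourth post-contrast point."""
    if curve.se_post1 <= EPSILON:
        raise DegenerateBaselineError(
            f"first post-contrast SE {curve.se_post1!r} is at or below epsilon {EPSILON}"
        )
    return 100.0 * (curve.se_post4 - curve.se_post1) / curve.se_post1


def categorize(initial_pct: float, delayed_pct: float) -> tuple[str, str]:
    """Bin the two percent changes into (initial, delayed) curve-type categories.

    Boundary convention: 50% and 100% belong to ``medium``; -10% and +10%
    belong to ``plateau``.
    """
    if not (math.isfinite(initial_pct) and math.isfinite(delayed_pct)):
        raise ValueError("kinetic percentages must be finite")
    if initial_pct < 50.0:
        initial = "slow"
    elif initial_pct <= 100.0:
        initial = "medium"
    else:
        initial = "fast"
    if delayed_pct < -10.0:
        delayed = "washout"
    elif delayed_pct <= 10.0:
        delayed = "plateau"
    else:
        delayed = "persistent"
    return initial, delayed


def features_from_curve(curve: TimeIntensityCurve) -> KineticFeatures:
    """Compute both percentages (reported to one decimal) and their categories."""
    ipct = initial_enhancement(curve)
    dpct = delayed_phase(curve)
    icat, dcat = categorize(ipct, dpct)
    return KineticFeatures(
        initial_enhancement_pct=round(ipct, 1),
        delayed_phase_pct=round(dpct, 1),
        initial_category=icat,
        delayed_category=dcat,
    )


def kinetic_features_for_lesion(series, annotation) -> KineticFeatures:
    """ROI-mean curve of a lesion -> percent changes -> categories.

    Composes :func:`dcefoci.io.roi_time_curve` with the two ratio features.
    Categorization uses the unrounded percentages.
    """
    from .io import roi_time_curve  # local import to avoid a cycle

    return features_from_curve(roi_time_curve(series, annotation))
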