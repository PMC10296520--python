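"""Synthetic cohort generator: growth model, invariants, round-trips."""

import numpy as np
import pytest

from conftest import TEST_SHAPE, tiny_params
from dcefoci.cohort import (
    CohortParams,
    SubjectRecord,
    _make_subject,
    find_prominent_focus,
    generate_cohort,
    simulate_growth,
    synthesize_dce_series,
)
from dcefoci.errors import ParameterError
from dcefoci.io import SubtractionImage, compute_subtraction, roi_time_curve
from dcefoci.kinetics import features_from_curve


# -- growth model -----------------------------------------------------------


def test_growth_closed_form():
    # one diameter doubling = three volume doublings
    assert simulate_growth(6.1, 138, 46) == pytest.approx(12.2)
    assert simulate_growth(6.1, 0, 46) == pytest.approx(6.1)
    # independently evaluated closed form: 6.1 * 2**(365/138)
    assert simulate_growth(6.1, 365, 46) == pytest.approx(6.1 * 2 ** (365 / 138))
    assert simulate_growth(6.1, 365, 46) == pytest.approx(38.153, abs=1e-3)


@pytest.mark.parametrize("args", [(-1, 10, 46), (5, -1, 46), (5, 10, 0)])
def test_growth_rejects_non_positive(args):
    with pytest.raises(ParameterError):
        simulate_growth(*args)


# -- parameter validation ---------------------------------------------------


def test_bad_simplex_rejected():
    params = tiny_params()
    params.bpe_level_probs = (0.6, 0.6)
    with pytest.raises(ParameterError):
        params.validate()


def test_negative_count_rejected():
    with pytest.raises(ParameterError):
        tiny_params(n_cancer_free=-1).validate()


def test_unknown_parameter_rejected():
    with pytest.raises(ParameterError):
        CohortParams.from_dict({"not_a_field": 1})


# -- generated cohort invariants --------------------------------------------


def test_group_sizes_and_label_invariants(tiny_cohort):
    df = tiny_cohort.df
    counts = df["group"].value_counts().to_dict()
    assert counts == {
        "cancer_with_abnormality": 4,
        "cancer_without_abnormality": 2,
        "cancer_free": 5,
    }
    for row in df.itertuples(index=False):
        if row.group == "cancer_with_abnormality":
            assert row.prior_mask_path and row.later_mask_path
            assert row.true_label == "cancer"
        elif row.group == "cancer_without_abnormality":
            assert not row.prior_mask_path and row.later_mask_path
            assert row.true_label == "cancer"
        else:
            assert row.prior_mask_path
            assert row.true_label == "non-cancer"


def test_every_manifest_path_exists(tiny_cohort):
    df = tiny_cohort.df
    n_files = 0
    for row in df.itertuples(index=False):
        for col in ("prior_scan_path", "later_scan_path", "prior_mask_path",
                    "later_mask_path"):
            p = getattr(row, col)
            if p:
                assert (tiny_cohort.root / p).exists(), p
                n_files += 1
    # scans: 2 per subject; masks: with=2, without=1, free=1 or 2 (vanish)
    assert n_files >= 2 * len(df) + 4 * 2 + 2 * 1 + 5 * 1


def test_zero_cancer_with_group_means_no_cancer_prior_annotations(tmp_path):
    params = tiny_params(n_cancer_with_abnormality=0, n_cancer_without=1,
                         n_cancer_free=2, seed=9)
    manifest = generate_cohort(params, tmp_path / "c")
    df = manifest.df
    cancer = df[df["true_label"] == "cancer"]
    assert (cancer["prior_mask_path"] == "").all()


def test_seed_determinism_byte_identical(tmp_path):
    import nibabel as nib

    params = tiny_params(n_cancer_with_abnormality=1, n_cancer_without=1,
                         n_cancer_free=1, seed=17)
    m1 = generate_cohort(params, tmp_path / "a")
    m2 = generate_cohort(params, tmp_path / "b")
    b1 = (tmp_path / "a" / "manifest.csv").read_bytes()
    b2 = (tmp_path / "b" / "manifest.csv").read_bytes()
    assert b1 == b2
    v1 = np.asarray(nib.load(tmp_path / "a" / "S000" / "prior_dce.nii").dataobj)
    v2 = np.asarray(nib.load(tmp_path / "b" / "S000" / "prior_dce.nii").dataobj)
    assert np.array_equal(v1, v2)
    assert m1.df.equals(m2.df)


def test_different_seeds_differ(tmp_path):
    a = generate_cohort(tiny_params(n_cancer_with_abnormality=1, n_cancer_without=0,
                                    n_cancer_free=0, seed=1), tmp_path / "a")
    b = generate_cohort(tiny_params(n_cancer_with_abnormality=1, n_cancer_without=0,
                                    n_cancer_free=0, seed=2), tmp_path / "b")
    assert not a.df.equals(b.df)


# -- kinetic-class round trip -----------------------------------------------


def _recover_class(rec, params, seed):
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0, 0)))
    series, annot = synthesize_dce_series(rec, params, "prior", rng)
    feats = features_from_curve(roi_time_curve(series, annot))
    return (feats.initial_category, feats.delayed_category)


@pytest.mark.parametrize("group", ["cancer_with_abnormality", "cancer_free"])
def test_noiseless_round_trip_exact(group):
    params = tiny_params(noise_sd=0.0, seed=21)
    for i in range(8):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=21, spawn_key=(i,)))
        rec = _make_subject(i, group, params, rng)
        assert _recover_class(rec, params, seed=1000 + i) == rec.true_kinetic_class


def test_forced_fast_washout_example():
    """A (fast, washout) subject yields ROI means that reproduce the class."""
    params = tiny_params(noise_sd=0.0)
    rec = SubjectRecord(
        subject_id="X", group="cancer_with_abnormality", mutated_gene="BRCA1",
        bpe_level="minimal-mild", days_between_scans=365, true_label="cancer",
        true_kinetic_class=("fast", "washout"), initial_pct=150.0, delayed_pct=-20.0,
        prior_diameter_mm=6.0, prior_morphology="focus",
        lesion_center_mm=(8.0, 20.0, 20.0),
    )
    rng = np.random.default_rng(0)
    series, annot = synthesize_dce_series(rec, params, "prior", rng)
    curve = roi_time_curve(series, annot)
    assert curve.se_pre == pytest.approx(100.0, abs=1e-3)
    assert curve.se_post1 == pytest.approx(250.0, abs=1e-2)
    assert curve.se_post4 == pytest.approx(200.0, abs=1e-2)
    feats = features_from_curve(curve)
    assert (feats.initial_category, feats.delayed_category) == ("fast", "washout")


def test_mask_derived_prior_diameter_mean_near_target():
    """Mean mask-derived diameter of cancer priors stays within 0.5 mm of 6.1."""
    params = tiny_params(noise_sd=0.0, seed=77, volume_shape=(16, 80, 80))
    diams = []
    for i in range(200):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=77, spawn_key=(i,)))
        rec = _make_subject(i, "cancer_with_abnormality", params, rng)
        vrng = np.random.default_rng(np.random.SeedSequence(entropy=77, spawn_key=(i, 0)))
        _, annot = synthesize_dce_series(rec, params, "prior", vrng)
        diams.append(annot.diameter_mm)
    assert abs(float(np.mean(diams)) - 6.1) <= 0.5


def test_benign_vanish_probability_respected(tmp_path):
    params = tiny_params(n_cancer_with_abnormality=0, n_cancer_without=0,
                         n_cancer_free=30, benign_vanish_prob=1.0, seed=5)
    manifest = generate_cohort(params, tmp_path / "v")
    assert (manifest.df["later_mask_path"] == "").all()


# -- prominence picker ------------------------------------------------------


def test_find_prominent_focus_locates_brightest_blob(rng):
    data = rng.normal(0, 1, size=(6, 48, 48)).astype(np.float32)
    yy, xx = np.mgrid[0:48, 0:48]
    blob = ((yy - 30) ** 2 + (xx - 12) ** 2 <= 9).astype(np.float32)
    data[3] += 40 * blob
    sub = SubtractionImage(data, (2.0, 0.66, 0.66))
    annot = find_prominent_focus(sub)
    assert annot.central_slice_index == 3
    com = np.argwhere(annot.mask).mean(axis=0)
    assert np.allclose(com, (30, 12), atol=2)
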