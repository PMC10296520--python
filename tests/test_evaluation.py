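"""Dataset assembly, LOO partitioning, metrics and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dcefoci.classifier import ModelConfig, PatchDataset
from dcefoci.cohort import CohortManifest
from dcefoci.errors import DataError
from dcefoci.evaluation import (
    assemble_network_dataset,
    cohort_summary,
    confusion_and_metrics,
    fold_seed,
    kinetic_feature_table,
    loo_cross_validate,
    loo_splits,
    report_from_predictions,
    round_half_up,
    thresholded_mean_baseline,
)


# -- assembly ---------------------------------------------------------------


def test_assembly_inclusion_rule(tiny_cohort):
    ds = assemble_network_dataset(tiny_cohort)
    # cancer-with (4, labeled 1) + cancer-free (5, labeled 0); excluded group absent
    assert len(ds) == 9
    assert int(ds.labels.sum()) == 4
    excluded = set(
        tiny_cohort.df.loc[
            tiny_cohort.df["group"] == "cancer_without_abnormality", "subject_id"
        ]
    )
    assert not excluded & set(ds.subject_ids)


def test_assembly_missing_file_names_subject(tiny_cohort, tmp_path):
    df = tiny_cohort.df.copy()
    first = df.index[df["group"] == "cancer_with_abnormality"][0]
    df.loc[first, "prior_mask_path"] = "S999/does_not_exist.nii"
    broken = CohortManifest(df=df, root=tiny_cohort.root, params=tiny_cohort.params)
    with pytest.raises(DataError, match=df.loc[first, "subject_id"]):
        assemble_network_dataset(broken)


# -- LOO partition property -------------------------------------------------


@given(n=st.integers(2, 60))
def test_loo_partition_property(n):
    held_out = []
    for train_idx, i in loo_splits(n):
        assert len(train_idx) == n - 1
        assert i not in train_idx
        held_out.append(i)
    assert sorted(held_out) == list(range(n))  # disjoint, exhaustive, singleton


def test_fold_seeds_deterministic_and_distinct():
    seeds = [fold_seed(42, k) for k in range(50)]
    assert seeds == [fold_seed(42, k) for k in range(50)]
    assert len(set(seeds)) == 50
    assert all(0 <= s < 2**31 for s in seeds)


def test_loo_cross_validate_two_samples_two_folds():
    rng = np.random.default_rng(0)
    ds = PatchDataset(
        rng.standard_normal((4, 24, 24)).astype(np.float32),
        rng.standard_normal((4, 128, 128)).astype(np.float32),
        np.array([1, 0, 1, 0]),
        ["a", "b", "c", "d"],
    )
    cfg = ModelConfig(local_branch_blocks=[2], context_branch_blocks=[2, 2],
                      mlp_hidden=4, epochs=1, batch_size=4, augment_flips=False)
    pred = loo_cross_validate(ds.subset([0, 1]), cfg, seed=0)
    assert len(pred) == 2
    assert sorted(pred["subject_id"]) == ["a", "b"]
    with pytest.raises(DataError):
        loo_cross_validate(ds.subset([0, 2]), cfg, seed=0)  # single class


def test_folds_cap_is_stratified_and_flagged():
    rng = np.random.default_rng(0)
    n = 12
    ds = PatchDataset(
        rng.standard_normal((n, 24, 24)).astype(np.float32),
        rng.standard_normal((n, 128, 128)).astype(np.float32),
        np.array([1] * 4 + [0] * 8),
        [f"s{i}" for i in range(n)],
    )
    cfg = ModelConfig(local_branch_blocks=[2], context_branch_blocks=[2, 2],
                      mlp_hidden=4, epochs=1, batch_size=6, augment_flips=False)
    pred = loo_cross_validate(ds, cfg, seed=1, folds_cap=6)
    assert pred.attrs["approximate"] is True
    assert len(pred) == 6
    assert (pred["true_label"] == "cancer").sum() == 2  # 4/12 of 6


# -- metrics ----------------------------------------------------------------


def test_confusion_matches_published_counts():
    preds = ["cancer"] * 21 + ["non-cancer"] * 11 + ["non-cancer"] * 47 + ["cancer"] * 6
    labels = ["cancer"] * 32 + ["non-cancer"] * 53
    rep = confusion_and_metrics(preds, labels)
    assert (rep.tp, rep.fn, rep.tn, rep.fp) == (21, 11, 47, 6)
    assert rep.sensitivity_pct == 65.6
    assert rep.specificity_pct == 88.7


def test_all_correct_and_guards():
    rep = confusion_and_metrics([1, 0, 1], [1, 0, 1])
    assert (rep.sensitivity_pct, rep.specificity_pct) == (100.0, 100.0)
    with pytest.raises(DataError):
        confusion_and_metrics([1, 1], [1, 1])  # specificity undefined
    with pytest.raises(DataError):
        confusion_and_metrics([0, 0], [0, 0])  # sensitivity undefined
    with pytest.raises(DataError):
        confusion_and_metrics([0], [0, 1])  # length mismatch


@given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=2))
def test_count_identities_on_random_inputs(pairs):
    preds = [p for p, _ in pairs]
    labels = [t for _, t in pairs]
    n_cancer = sum(labels)
    if n_cancer in (0, len(labels)):
        with pytest.raises(DataError):
            confusion_and_metrics(preds, labels)
        return
    rep = confusion_and_metrics(preds, labels)
    assert rep.tp + rep.fn == n_cancer
    assert rep.tn + rep.fp == len(labels) - n_cancer
    assert rep.sensitivity_pct == round_half_up(100 * rep.tp / (rep.tp + rep.fn))
    assert rep.specificity_pct == round_half_up(100 * rep.tn / (rep.tn + rep.fp))


def test_metrics_identity_from_per_sample_records():
    rng = np.random.default_rng(8)
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(40)],
            "true_label": rng.choice(["cancer", "non-cancer"], 40),
            "predicted_label": rng.choice(["cancer", "non-cancer"], 40),
        }
    )
    rep = report_from_predictions(df)
    again = confusion_and_metrics(df["predicted_label"], df["true_label"])
    assert (rep.tp, rep.fn, rep.tn, rep.fp) == (again.tp, again.fn, again.tn, again.fp)


def test_round_half_up_convention():
    assert round_half_up(65.625) == 65.6
    assert round_half_up(88.679245) == 88.7
    assert round_half_up(60.377) == 60.4
    assert round_half_up(2.25) == 2.3  # half rounds up, not to even
    assert round_half_up(2.35) == 2.4


# -- baseline ---------------------------------------------------------------


def test_thresholded_mean_baseline_separates_offset_patches():
    rng = np.random.default_rng(4)
    n = 16
    labels = np.array([1, 0] * (n // 2))
    local = rng.standard_normal((n, 24, 24)).astype(np.float32)
    local[labels == 1] += 3.0
    ds = PatchDataset(local, np.zeros((n, 128, 128), np.float32), labels,
                      [f"s{i}" for i in range(n)])
    rep = report_from_predictions(thresholded_mean_baseline(ds))
    assert rep.sensitivity_pct == 100.0
    assert rep.specificity_pct == 100.0


# -- summaries --------------------------------------------------------------


def test_cohort_summary_contents(tiny_cohort):
    s = cohort_summary(tiny_cohort)
    assert s["n_subjects"] == 11
    assert s["prior_abnormality_pct"] == round_half_up(100 * 4 / 6)
    assert s["days_between_scans"]["mean"] > 0
    assert "prior_cancer_diameter_mm" in s
    assert "benign_focus_diameter_mm" in s
    assert set(s["kinetic_initial_freq"]) >= {"cancer_with_abnormality", "cancer_free"}


def test_cohort_summary_empty_manifest_rejected(tiny_cohort):
    empty = CohortManifest(df=tiny_cohort.df.iloc[0:0], root=tiny_cohort.root,
                           params=tiny_cohort.params)
    with pytest.raises(DataError):
        cohort_summary(empty)


def test_kinetic_feature_table_one_row_per_annotation(tiny_cohort):
    table = kinetic_feature_table(tiny_cohort)
    df = tiny_cohort.df
    expected = int((df["prior_mask_path"] != "").sum() + (df["later_mask_path"] != "").sum())
    assert len(table) == expected
    assert set(table["visit"]) <= {"prior", "later"}
    assert table["initial_category"].isin(["slow", "medium", "fast"]).all()
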