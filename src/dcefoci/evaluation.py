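"""Dataset assembly, leave-one-out evaluation and cohort summaries.

The network dataset follows the study's inclusion rule: the prior scans of
cancer subjects that carry a prior-scan abnormality (labeled cancer) plus the
prior scans of every cancer-free subject (labeled non-cancer); cancer
subjects without a prior abnormality are excluded. With group sizes
(32, 21, 53) this yields 85 samples.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import (
    CLASS_NAMES,
    DualPatchCNN,
    ModelConfig,
    PatchDataset,
    build_model,
    pretrain_extractors,
    train,
)
from .cohort import CohortManifest
from .errors import DataError
from .io import (
    LesionAnnotation,
    compute_subtraction,
    extract_patch_pair,
    normalize_subtraction,
    read_dce_series,
    read_mask,
)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding, matching clinical reporting (65.625 -> 65.6)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EvaluationReport:
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity_pct: float
    specificity_pct: float
    per_sample: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def confusion_text(self) -> str:
        lines = [
            "                 predicted",
            "                 cancer  non-cancer",
            f"true cancer      {self.tp:6d}  {self.fn:10d}",
            f"true non-cancer  {self.fp:6d}  {self.tn:10d}",
            f"sensitivity {self.sensitivity_pct}%   specificity {self.specificity_pct}%",
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def assemble_network_dataset(manifest: CohortManifest) -> PatchDataset:
    """Build the labeled patch-pair set from a cohort's prior scans."""
    locals_, contexts, labels, ids = [], [], [], []
    for row in manifest.df.itertuples(index=False):
        if row.group == "cancer_without_abnormality":
            continue
        if row.group == "cancer_with_abnormality":
            label = 1
        elif row.group == "cancer_free":
            label = 0
        else:
            raise DataError(f"{row.subject_id}: unknown group {row.group!r}")
        if not row.prior_mask_path:
            raise DataError(f"{row.subject_id}: missing prior annotation")
        scan = manifest.root / row.prior_scan_path
        mpath = manifest.root / row.prior_mask_path
        for p in (scan, mpath):
            if not p.exists():
                raise DataError(f"{row.subject_id}: missing file {p}")
        series = read_dce_series(scan)
        sub = compute_subtraction(series)
        annotation = LesionAnnotation(
            central_slice_index=int(row.prior_central_slice),
            mask=read_mask(mpath),
            morphology=row.prior_morphology,
            visit="prior",
        )
        pair = extract_patch_pair(
            sub, annotation, normalized=normalize_subtraction(sub, annotation=annotation)
        )
        locals_.append(pair.local_patch)
        contexts.append(pair.context_patch)
        labels.append(label)
        ids.append(row.subject_id)
    if not ids:
        raise DataError("manifest yielded an empty network dataset")
    return PatchDataset(
        np.stack(locals_), np.stack(contexts), np.asarray(labels), ids
    )


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------


def loo_splits(n: int):
    """Yield (train_indices, held_out_index) for each of the n folds."""
    all_idx = np.arange(n)
    for i in range(n):
        yield np.delete(all_idx, i), i


def fold_seed(global_seed: int, fold: int) -> int:
    """Deterministic per-fold seed derived from the global seed (< 2**31)."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(fold,))
    return int(ss.generate_state(1)[0] % (2**31))


def loo_cross_validate(
    dataset: PatchDataset,
    config: ModelConfig,
    seed: int = 0,
    folds_cap: int | None = None,
) -> pd.DataFrame:
    """Leave-one-out predictions: each sample held out once, a fresh model
    trained from scratch on the remaining n-1 samples.

    ``folds_cap`` (desk-speed option) evaluates only a stratified subsample of
    folds; the result is flagged approximate in ``df.attrs``.
    """
    n = len(dataset)
    if n < 2:
        raise DataError("leave-one-out needs at least 2 samples")
    if len(np.unique(dataset.labels)) < 2:
        raise DataError("leave-one-out needs both classes present")

    folds = list(range(n))
    approximate = False
    if folds_cap is not None and folds_cap < n:
        approximate = True
        rng = np.random.default_rng(seed)
        keep = []
        for cls in np.unique(dataset.labels):
            cls_idx = np.flatnonzero(dataset.labels == cls)
            k = max(1, int(round(folds_cap * len(cls_idx) / n)))
            keep.extend(rng.choice(cls_idx, size=min(k, len(cls_idx)), replace=False))
        folds = sorted(int(i) for i in keep)

    records = []
    for i in folds:
        train_idx = np.delete(np.arange(n), i)
        fold_cfg = dataclasses.replace(config, seed=fold_seed(seed, i))
        model = build_model(fold_cfg)
        if fold_cfg.pretrain:
            model = pretrain_extractors(model)
        train(model, dataset.subset(train_idx), allow_single_class=True)
        proba = model.predict_proba(dataset.local[i : i + 1], dataset.context[i : i + 1])[0]
        records.append(
            {
                "subject_id": dataset.subject_ids[i],
                "true_label": CLASS_NAMES[int(dataset.labels[i])],
                "predicted_label": CLASS_NAMES[int(np.argmax(proba))],
                "probability_cancer": float(proba[1]),
            }
        )
    df = pd.DataFrame.from_records(records)
    df.attrs["approximate"] = approximate
    df.attrs["n_folds"] = len(folds)
    return df


def thresholded_mean_baseline(dataset: PatchDataset) -> pd.DataFrame:
    """Leave-one-out baseline: threshold on the local-patch mean intensity.

    For each fold the threshold (and its direction) maximizing balanced
    accuracy on the training samples is chosen, then applied to the held-out
    sample. Serves as the independent yardstick the network must match.
    """
    means = dataset.local.reshape(len(dataset), -1).mean(axis=1)
    labels = dataset.labels
    records = []
    for train_idx, i in loo_splits(len(dataset)):
        m, y = means[train_idx], labels[train_idx]
        order = np.argsort(m)
        ms = m[order]
        cuts = np.concatenate([[ms[0] - 1], (ms[1:] + ms[:-1]) / 2, [ms[-1] + 1]])
        best = (-1.0, ms[0], 1)
        for thr in cuts:
            for sign in (1, -1):
                pred = (sign * m > sign * thr).astype(int)
                pos, neg = y == 1, y == 0
                bacc = 0.5 * ((pred[pos] == 1).mean() + (pred[neg] == 0).mean())
                if bacc > best[0]:
                    best = (bacc, thr, sign)
        _, thr, sign = best
        pred_i = int(sign * means[i] > sign * thr)
        records.append(
            {
                "subject_id": dataset.subject_ids[i],
                "true_label": CLASS_NAMES[int(labels[i])],
                "predicted_label": CLASS_NAMES[pred_i],
                "probability_cancer": float(pred_i),
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def confusion_and_metrics(predictions, labels, per_sample: pd.DataFrame | None = None
                          ) -> EvaluationReport:
    """Confusion counts plus sensitivity/specificity (1-decimal, half-up).

    ``predictions``/``labels`` are aligned sequences of class names
    ("cancer"/"non-cancer") or 0/1 integers (1 = cancer).
    """

    def to_int(seq):
        out = []
        for v in seq:
            if isinstance(v, str):
                out.append(1 if v == "cancer" else 0)
            else:
                out.append(int(v))
        return np.asarray(out)

    pred = to_int(predictions)
    true = to_int(labels)
    if len(pred) != len(true):
        raise DataError(f"length mismatch: {len(pred)} predictions, {len(true)} labels")
    tp = int(((pred == 1) & (true == 1)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    if tp + fn == 0:
        raise DataError("sensitivity undefined: no cancer samples")
    if tn + fp == 0:
        raise DataError("specificity undefined: no non-cancer samples")
    return EvaluationReport(
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity_pct=round_half_up(100.0 * tp / (tp + fn)),
        specificity_pct=round_half_up(100.0 * tn / (tn + fp)),
        per_sample=per_sample,
    )


def report_from_predictions(df: pd.DataFrame) -> EvaluationReport:
    return confusion_and_metrics(df["predicted_label"], df["true_label"], per_sample=df)


# ---------------------------------------------------------------------------
# Kinetic feature table
# ---------------------------------------------------------------------------


def kinetic_feature_table(manifest: CohortManifest) -> pd.DataFrame:
    """Kinetic features for every annotated ROI in the cohort.

    One row per (subject, visit) annotation: the two percent changes (one
    decimal) and their categories, computed from the ROI-mean raw-signal
    curve of that visit's series.
    """
    from .kinetics import features_from_curve
    from .io import roi_time_curve

    rows = []
    for row in manifest.df.itertuples(index=False):
        for visit, scan_col, mask_col, slice_col, morph_col in (
            ("prior", "prior_scan_path", "prior_mask_path", "prior_central_slice",
             "prior_morphology"),
            ("later", "later_scan_path", "later_mask_path", "later_central_slice",
             "later_morphology"),
        ):
            mask_path = getattr(row, mask_col)
            if not mask_path:
                continue
            scan = manifest.root / getattr(row, scan_col)
            mpath = manifest.root / mask_path
            for p in (scan, mpath):
                if not p.exists():
                    raise DataError(f"{row.subject_id}: missing file {p}")
            series = read_dce_series(scan)
            annotation = LesionAnnotation(
                central_slice_index=int(getattr(row, slice_col)),
                mask=read_mask(mpath),
                morphology=getattr(row, morph_col),
                visit=visit,
            )
            feats = features_from_curve(roi_time_curve(series, annotation))
            rows.append(
                {
                    "subject_id": row.subject_id,
                    "visit": visit,
                    "morphology": annotation.morphology,
                    "initial_enhancement_pct": feats.initial_enhancement_pct,
                    "delayed_phase_pct": feats.delayed_phase_pct,
                    "initial_category": feats.initial_category,
                    "delayed_category": feats.delayed_category,
                }
            )
    if not rows:
        raise DataError("manifest contains no annotations")
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------


def cohort_summary(manifest: CohortManifest) -> dict:
    """Group counts, prior-abnormality proportion, lesion-size and timing
    statistics, and morphology/kinetic frequency tables."""
    df = manifest.df
    if len(df) == 0:
        raise DataError("empty manifest")
    counts = df["group"].value_counts().to_dict()
    n_with = counts.get("cancer_with_abnormality", 0)
    n_without = counts.get("cancer_without_abnormality", 0)
    n_cancer = n_with + n_without
    summary: dict = {"group_counts": counts, "n_subjects": len(df)}
    if n_cancer > 0:
        summary["prior_abnormality_pct"] = round_half_up(100.0 * n_with / n_cancer)

    def num(col, sel):
        vals = pd.to_numeric(df.loc[sel, col], errors="coerce").dropna()
        return vals

    days = pd.to_numeric(df["days_between_scans"], errors="coerce").dropna()
    summary["days_between_scans"] = {
        "mean": float(days.mean()), "sd": float(days.std(ddof=1)) if len(days) > 1 else 0.0
    }
    for group, key in (
        ("cancer_with_abnormality", "prior_cancer_diameter_mm"),
        ("cancer_free", "benign_focus_diameter_mm"),
    ):
        vals = num("prior_diameter_mm", df["group"] == group)
        if len(vals):
            summary[key] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            }
    morph, kin_i, kin_d = {}, {}, {}
    for group, gdf in df.groupby("group"):
        has = gdf["prior_morphology"] != ""
        if has.any():
            morph[group] = (
                gdf.loc[has, "prior_morphology"].value_counts(normalize=True).to_dict()
            )
        hask = gdf["kinetic_initial_class"] != ""
        if hask.any():
            kin_i[group] = (
                gdf.loc[hask, "kinetic_initial_class"].value_counts(normalize=True).to_dict()
            )
            kin_d[group] = (
                gdf.loc[hask, "kinetic_delayed_class"].value_counts(normalize=True).to_dict()
            )
    summary["prior_morphology_freq"] = morph
    summary["kinetic_initial_freq"] = kin_i
    summary["kinetic_delayed_freq"] = kin_d
    return summary
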