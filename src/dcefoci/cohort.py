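"""Synthetic longitudinal DCE-MRI cohort generator.

Emulates the data structure of a BRCA-carrier surveillance study: each subject
has a *prior* scan and, roughly one year later, a *diagnosis* (cancer) or
*follow-up* (cancer-free) scan. Three groups are generated:

``cancer_with_abnormality``
    A small enhancing lesion (mean diameter ~6.1 mm, mostly focus morphology)
    on the prior scan, co-located with a larger tumor on the diagnosis scan.
``cancer_without_abnormality``
    Clean prior scan; tumor appears only on the diagnosis scan.
``cancer_free``
    A benign enhancing focus (~7.4 mm) on the prior scan that is stable or
    vanishes at follow-up.

Volumes are signal-enhancement images built directly (no MR pulse-sequence
physics): a flat tissue baseline, a spatially smooth background parenchymal
enhancement (BPE) field that ramps up over the post-contrast frames, lesions
whose ROI-mean time courses realize an exactly known kinetic class, and
additive Gaussian noise. The construction guarantees that, at zero noise,
applying the kinetic ratio features to the generated ROI means recovers the
generating class exactly.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, label as cc_label
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .errors import AnnotationError, ParameterError
from .io import (
    DEFAULT_ACQUISITION_TIMES,
    DceSeries,
    LesionAnnotation,
    SubtractionImage,
    measure_diameter,
    write_dce_series,
    write_mask,
)
from .kinetics import DELAYED_CATEGORIES, INITIAL_CATEGORIES

GROUPS = ("cancer_with_abnormality", "cancer_without_abnormality", "cancer_free")

#: Tissue baseline signal (arbitrary units) present in every frame.
TISSUE_BASELINE = 100.0

#: Within-category sampling ranges (percent) for the generated kinetic targets.
#: Kept clear of the 50/100 and +/-10 category boundaries so that ROI-mean
#: noise rarely flips the recovered class.
INITIAL_RANGES = {"slow": (10.0, 43.0), "medium": (57.0, 93.0), "fast": (107.0, 200.0)}
DELAYED_RANGES = {
    "persistent": (15.0, 40.0),
    "plateau": (-6.5, 6.5),
    "washout": (-35.0, -15.0),
}

_T2 = DEFAULT_ACQUISITION_TIMES  # nominal frame times, minutes


def _default_morphology_probs() -> dict:
    # prior-scan morphology frequencies per group
    return {
        "cancer_with_abnormality": (19 / 32, 6 / 32, 7 / 32),  # focus, mass, non-mass
        "cancer_without_abnormality": (6 / 32, 18 / 32, 8 / 32),  # used for its tumor
        "cancer_free": (12 / 54, 17 / 54, 25 / 54),  # reported counts total 54
    }


def _default_kinetic_probs() -> dict:
    """Joint (initial x delayed) class simplex per group.

    Built as the outer product of the groups' reported marginal frequencies
    (rows: slow/medium/fast; columns: persistent/plateau/washout).
    """
    cancer_init = np.array([8, 13, 11]) / 32
    cancer_del = np.array([23, 8, 1]) / 32
    free_init = np.array([24, 15, 14]) / 53
    free_del = np.array([45, 7, 1]) / 53
    cancer = np.outer(cancer_init, cancer_del)
    free = np.outer(free_init, free_del)
    return {
        "cancer_with_abnormality": cancer.tolist(),
        "cancer_without_abnormality": cancer.tolist(),
        "cancer_free": free.tolist(),
    }


@dataclass
class CohortParams:
    """All knobs of the synthetic cohort; defaults reproduce the study design."""

    n_cancer_with_abnormality: int = 32
    n_cancer_without: int = 21
    n_cancer_free: int = 53
    days_between_scans_mean: float = 367.6
    days_between_scans_sd: float = 130.2
    prior_lesion_diameter_mean: float = 6.1
    prior_lesion_diameter_sd: float = 4.2
    prior_lesion_diameter_range: tuple[float, float] = (1.5, 17.0)
    benign_focus_diameter_mean: float = 7.4
    benign_focus_diameter_sd: float = 4.2
    benign_focus_diameter_range: tuple[float, float] = (1.7, 27.3)
    occult_tumor_diameter_mean: float = 7.8
    occult_tumor_diameter_sd: float = 4.0
    occult_tumor_diameter_range: tuple[float, float] = (2.0, 16.0)
    doubling_time_days_brca1: float = 46.0
    doubling_time_days_brca2: float = 52.0
    brca1_fraction: float = 0.736
    morphology_probs_by_group: dict = field(default_factory=_default_morphology_probs)
    kinetic_class_probs_by_group: dict = field(default_factory=_default_kinetic_probs)
    bpe_level_probs: tuple[float, float] = (0.67, 0.33)  # minimal-mild, moderate-marked
    bpe_amplitude_minimal: float = 12.0  # signal units (field std)
    bpe_amplitude_ratio: float = 2.5  # moderate-marked multiplier
    benign_vanish_prob: float = 0.4
    noise_sd: float = 5.0
    volume_shape: tuple[int, int, int] = (64, 128, 128)  # (slices, rows, cols)
    voxel_spacing: tuple[float, float, float] = (2.0, 0.66, 0.66)  # mm
    registration_jitter_vox: int = 3  # max in-plane shift between visits
    #: Benchmark knob: when set (signal units), every cancer lesion's
    #: subtraction contrast is placed at least this far above the visit's
    #: measured background reference while benign foci stay below it,
    #: realized through the lesion baseline (kinetic ratios unchanged).
    contrast_separation: float | None = None
    compress: bool = False  # .nii.gz instead of .nii
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_cancer_with_abnormality, self.n_cancer_without, self.n_cancer_free)
        if any(c < 0 for c in counts):
            raise ParameterError(f"group sizes must be >= 0, got {counts}")
        for name in (
            "prior_lesion_diameter_mean",
            "benign_focus_diameter_mean",
            "doubling_time_days_brca1",
            "doubling_time_days_brca2",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0 <= self.brca1_fraction <= 1:
            raise ParameterError("brca1_fraction must lie in [0, 1]")
        if not 0 <= self.benign_vanish_prob <= 1:
            raise ParameterError("benign_vanish_prob must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        self._check_simplex(np.asarray(self.bpe_level_probs), "bpe_level_probs")
        for group in GROUPS:
            m = np.asarray(self.morphology_probs_by_group[group], dtype=float)
            self._check_simplex(m, f"morphology_probs_by_group[{group}]")
            k = np.asarray(self.kinetic_class_probs_by_group[group], dtype=float)
            if k.shape != (3, 3):
                raise ParameterError(
                    f"kinetic_class_probs_by_group[{group}] must be 3x3 (initial x delayed)"
                )
            self._check_simplex(k.ravel(), f"kinetic_class_probs_by_group[{group}]")

    @staticmethod
    def _check_simplex(p: np.ndarray, name: str) -> None:
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ParameterError(f"{name} must be a simplex summing to 1, got {p.tolist()}")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown cohort parameters: {sorted(unknown)}")
        d = dict(d)
        for key in ("volume_shape", "voxel_spacing", "bpe_level_probs",
                    "prior_lesion_diameter_range", "benign_focus_diameter_range",
                    "occult_tumor_diameter_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SubjectRecord:
    """One generated subject, including the latent truths the images realize."""

    subject_id: str
    group: str
    mutated_gene: str
    bpe_level: str
    days_between_scans: float
    true_label: str  # "cancer" | "non-cancer"
    true_kinetic_class: tuple[str, str] | None  # (initial, delayed)
    initial_pct: float | None = None
    delayed_pct: float | None = None
    lesion_baseline: float = TISSUE_BASELINE
    prior_diameter_mm: float | None = None
    later_diameter_mm: float | None = None
    prior_morphology: str | None = None
    later_morphology: str | None = None
    lesion_center_mm: tuple[float, float, float] | None = None
    later_center_mm: tuple[float, float, float] | None = None
    vanished: bool = False
    benchmark_contrast_u: float | None = None
    prior_scan_path: str | None = None
    later_scan_path: str | None = None
    prior_mask_path: str | None = None
    later_mask_path: str | None = None
    prior_central_slice: int | None = None
    later_central_slice: int | None = None

    @property
    def has_prior_annotation(self) -> bool:
        return self.group in ("cancer_with_abnormality", "cancer_free")


@dataclass
class CohortManifest:
    """Cohort on disk: one manifest row per subject plus a parameter snapshot."""

    df: pd.DataFrame
    root: Path
    params: CohortParams

    @classmethod
    def load(cls, root: str | Path) -> "CohortManifest":
        root = Path(root)
        df = pd.read_csv(root / "manifest.csv", keep_default_na=False)
        with open(root / "params.json") as fh:
            snap = json.load(fh)
        return cls(df=df, root=root, params=CohortParams.from_dict(snap["params"]))


# ---------------------------------------------------------------------------
# Growth model
# ---------------------------------------------------------------------------


def simulate_growth(prior_diameter: float, days: float, doubling_time: float) -> float:
    """Exponential volume growth: diameter after ``days`` of growth.

    Volume doubles every ``doubling_time`` days; diameter scales as the cube
    root of volume, so ``d * 2**(days / (3 * doubling_time))``.
    """
    if prior_diameter <= 0 or days < 0 or doubling_time <= 0:
        raise ParameterError(
            "prior_diameter and doubling_time must be > 0 and days >= 0 "
            f"(got {prior_diameter}, {days}, {doubling_time})"
        )
    return prior_diameter * 2.0 ** (days / (3.0 * doubling_time))


# ---------------------------------------------------------------------------
# Distribution helpers
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _truncnorm_params(target_mean: float, sd: float, lo: float, hi: float):
    """Location of a [lo, hi]-truncated normal whose *truncated* mean is exact."""

    def gap(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return truncnorm.mean(a, b, loc=mu, scale=sd) - target_mean

    mu = brentq(gap, lo - 2 * sd, hi + 2 * sd, xtol=1e-8)
    return (lo - mu) / sd, (hi - mu) / sd, mu


def _draw_diameter(rng, mean: float, sd: float, bounds: tuple[float, float]) -> float:
    a, b, mu = _truncnorm_params(mean, sd, *bounds)
    return float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def _draw_kinetic_class(rng, joint: np.ndarray) -> tuple[str, str]:
    flat = np.asarray(joint, dtype=float).ravel()
    idx = rng.choice(9, p=flat / flat.sum())
    return INITIAL_CATEGORIES[idx // 3], DELAYED_CATEGORIES[idx % 3]


def _draw_percentages(rng, kclass: tuple[str, str]) -> tuple[float, float]:
    ilo, ihi = INITIAL_RANGES[kclass[0]]
    dlo, dhi = DELAYED_RANGES[kclass[1]]
    return float(rng.uniform(ilo, ihi)), float(rng.uniform(dlo, dhi))


def _kinetic_ratios(initial_pct: float, delayed_pct: float) -> np.ndarray:
    """Per-frame signal ratios r_k = SE_k / SE_pre realizing the two targets.

    r is piecewise linear in acquisition time between the 1st and 4th
    post-contrast frames.
    """
    r1 = 1.0 + initial_pct / 100.0
    r4 = r1 * (1.0 + delayed_pct / 100.0)
    t = np.asarray(_T2)
    frac = (t[2:4] - t[1]) / (t[4] - t[1])
    r = np.array([1.0, r1, 0.0, 0.0, r4])
    r[2:4] = r1 + frac * (r4 - r1)
    return r


# ---------------------------------------------------------------------------
# Volume synthesis
# ---------------------------------------------------------------------------


def _lesion_profile(
    shape, spacing, center_mm, diameter_mm, morphology, rng, blur_px=0.6
):
    """Soft [0, 1] 3-D lesion profile plus its central-slice binary mask.

    Focus/mass lesions are spheres; non-mass lesions are in-plane capsule
    (tube) segments whose largest diameter equals ``diameter_mm``. The
    support is lightly Gaussian-blurred; the mask is the 0.5 level set on the
    central slice.
    """
    nz, ny, nx = shape
    sz, sy, sx = spacing
    zz = (np.arange(nz) * sz - center_mm[0])[:, None, None]
    yy = (np.arange(ny) * sy - center_mm[1])[None, :, None]
    xx = (np.arange(nx) * sx - center_mm[2])[None, None, :]
    radius = diameter_mm / 2.0
    if morphology == "non-mass" and diameter_mm > 4.0:
        tube_r = min(1.5, diameter_mm / 4.0)
        half_len = (diameter_mm - 2.0 * tube_r) / 2.0
        theta = rng.uniform(0, np.pi)
        uy, ux = np.sin(theta), np.cos(theta)
        t = np.clip(yy * uy + xx * ux, -half_len, half_len)
        dist = np.sqrt(zz**2 + (yy - t * uy) ** 2 + (xx - t * ux) ** 2)
        support = dist <= tube_r
    else:
        dist = np.sqrt(zz**2 + yy**2 + xx**2)
        support = dist <= radius
    profile = gaussian_filter(support.astype(np.float32), sigma=(0.25, blur_px, blur_px))
    k0 = int(round(center_mm[0] / sz))
    k0 = min(max(k0, 0), nz - 1)
    mask = profile[k0] >= 0.5
    if not mask.any():  # sub-voxel lesion: keep at least the center pixel
        iy = min(max(int(round(center_mm[1] / sy)), 0), ny - 1)
        ix = min(max(int(round(center_mm[2] / sx)), 0), nx - 1)
        mask = np.zeros((ny, nx), dtype=bool)
        mask[iy, ix] = True
        profile[k0, iy, ix] = max(profile[k0, iy, ix], 1.0)
    return profile, k0, mask


def _bpe_field(shape, spacing, amplitude, rng) -> np.ndarray:
    """Smooth nonnegative BPE field with the requested amplitude (std units)."""
    sigma = (6.0 / spacing[0], 8.0 / spacing[1], 8.0 / spacing[2])
    g = gaussian_filter(rng.standard_normal(shape).astype(np.float32), sigma=sigma)
    sd = float(g.std())
    if sd > 0:
        g /= sd
    return amplitude * np.clip(g, 0.0, None)


def synthesize_dce_series(
    record: SubjectRecord,
    params: CohortParams,
    visit: str,
    rng: np.random.Generator,
) -> tuple[DceSeries, LesionAnnotation | None]:
    """Render one visit's 5-frame series (and its annotation, if any).

    The lesion term is scaled so that the ROI mean over the returned mask
    equals ``lesion_baseline * r_k`` exactly at every frame (before noise);
    the BPE field is zeroed on the lesion's soft support so it cannot
    contaminate the ROI means.
    """
    if visit not in ("prior", "later"):
        raise ParameterError(f"visit must be 'prior' or 'later', got {visit!r}")
    shape, spacing = params.volume_shape, params.voxel_spacing
    amp = params.bpe_amplitude_minimal
    if record.bpe_level == "moderate-marked":
        amp *= params.bpe_amplitude_ratio
    bpe = _bpe_field(shape, spacing, amp, rng)
    t = np.asarray(_T2)
    weights = t / t[-1]

    if visit == "prior":
        diameter = record.prior_diameter_mm
        morphology = record.prior_morphology
        center = record.lesion_center_mm
        annot_visit = "prior"
    else:
        diameter = record.later_diameter_mm
        morphology = record.later_morphology
        center = record.later_center_mm or record.lesion_center_mm
        annot_visit = "diagnosis" if record.true_label == "cancer" else "followup"

    noise = None
    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd, (5, *shape)).astype(np.float32)

    annotation = None
    lesion_term = None
    if diameter is not None:
        max_d = 0.4 * min(shape[1] * spacing[1], shape[2] * spacing[2])
        diameter = min(diameter, max_d)
        profile, k0, mask = _lesion_profile(
            shape, spacing, center, diameter, morphology, rng
        )
        f = float(profile[k0][mask].mean())
        ratios = _kinetic_ratios(record.initial_pct, record.delayed_pct)
        baseline = record.lesion_baseline
        if (
            params.contrast_separation is not None
            and record.benchmark_contrast_u is not None
        ):
            # benchmark mode: anchor the subtraction-contrast target to this
            # visit's measured background level so the cancer/benign margin
            # survives background-referenced normalization
            sub_bg = weights[2] * bpe
            if noise is not None:
                sub_bg = sub_bg + (noise[2] - noise[0])
            bg99 = max(float(np.percentile(sub_bg, 99.0)), 4.0 * params.noise_sd, 10.0)
            u = record.benchmark_contrast_u
            if record.true_label == "cancer":
                contrast = 0.95 * bg99 + params.contrast_separation + 30.0 * u
            else:
                # peak pixel values run up to ~2x the ROI-mean contrast for
                # the smallest masks, so keep benign targets below half the
                # background reference
                contrast = (0.2 + 0.3 * u) * bg99
            ratio = max(float(ratios[2] - 1.0), 1e-3)
            baseline = float(np.clip(contrast / ratio, 1.0, 8000.0))
        se = baseline * ratios  # target ROI means per frame
        lesion_term = (se - TISSUE_BASELINE)[:, None, None, None] * (profile / f)[None]
        bpe = np.where(profile > 0.01, 0.0, bpe)
        annotation = LesionAnnotation(
            central_slice_index=k0, mask=mask, morphology=morphology, visit=annot_visit
        )
        annotation.diameter_mm = measure_diameter(annotation, spacing[1:])

    frames = np.empty((5, *shape), dtype=np.float32)
    for k in range(5):
        frames[k] = TISSUE_BASELINE + weights[k] * bpe
    if lesion_term is not None:
        frames += lesion_term.astype(np.float32)
    if noise is not None:
        frames += noise
    return DceSeries(frames, spacing), annotation


# ---------------------------------------------------------------------------
# Subject latents
# ---------------------------------------------------------------------------


def _draw_center(rng, params, diameter) -> tuple[float, float, float]:
    nz, ny, nx = params.volume_shape
    sz, sy, sx = params.voxel_spacing
    pad = diameter / 2.0 + 3.0
    kz_lo = max(int(np.ceil((diameter / 2.0) / sz)) + 1, 1)
    kz = int(rng.integers(kz_lo, max(nz - kz_lo, kz_lo + 1)))
    y = float(rng.uniform(pad, ny * sy - pad))
    x = float(rng.uniform(pad, nx * sx - pad))
    return (kz * sz, y, x)


def _make_subject(index: int, group: str, params: CohortParams,
                  rng: np.random.Generator) -> SubjectRecord:
    gene = "BRCA1" if rng.random() < params.brca1_fraction else "BRCA2"
    bpe_level = (
        "minimal-mild" if rng.random() < params.bpe_level_probs[0] else "moderate-marked"
    )
    days = float(
        np.clip(
            rng.normal(params.days_between_scans_mean, params.days_between_scans_sd),
            100.0,
            None,
        )
    )
    label = "cancer" if group != "cancer_free" else "non-cancer"
    rec = SubjectRecord(
        subject_id=f"S{index:03d}",
        group=group,
        mutated_gene=gene,
        bpe_level=bpe_level,
        days_between_scans=days,
        true_label=label,
        true_kinetic_class=None,
    )

    kclass = _draw_kinetic_class(
        rng, np.asarray(params.kinetic_class_probs_by_group[group])
    )
    rec.true_kinetic_class = kclass
    rec.initial_pct, rec.delayed_pct = _draw_percentages(rng, kclass)
    morph_probs = np.asarray(params.morphology_probs_by_group[group], dtype=float)
    morphology = ("focus", "mass", "non-mass")[
        int(rng.choice(3, p=morph_probs / morph_probs.sum()))
    ]

    if group == "cancer_with_abnormality":
        rec.prior_diameter_mm = _draw_diameter(
            rng,
            params.prior_lesion_diameter_mean,
            params.prior_lesion_diameter_sd,
            params.prior_lesion_diameter_range,
        )
        td = (
            params.doubling_time_days_brca1
            if gene == "BRCA1"
            else params.doubling_time_days_brca2
        )
        rec.later_diameter_mm = simulate_growth(rec.prior_diameter_mm, days, td)
        rec.prior_morphology = morphology
        diag_probs = np.asarray(
            params.morphology_probs_by_group["cancer_without_abnormality"], dtype=float
        )
        rec.later_morphology = ("focus", "mass", "non-mass")[
            int(rng.choice(3, p=diag_probs / diag_probs.sum()))
        ]
        base_d = rec.prior_diameter_mm
    elif group == "cancer_without_abnormality":
        rec.later_diameter_mm = _draw_diameter(
            rng,
            params.occult_tumor_diameter_mean,
            params.occult_tumor_diameter_sd,
            params.occult_tumor_diameter_range,
        )
        rec.later_morphology = morphology
        base_d = rec.later_diameter_mm
    else:  # cancer_free
        rec.prior_diameter_mm = _draw_diameter(
            rng,
            params.benign_focus_diameter_mean,
            params.benign_focus_diameter_sd,
            params.benign_focus_diameter_range,
        )
        rec.prior_morphology = morphology
        rec.vanished = rng.random() < params.benign_vanish_prob
        if not rec.vanished:
            rec.later_diameter_mm = rec.prior_diameter_mm
            rec.later_morphology = morphology
        base_d = rec.prior_diameter_mm

    rec.lesion_center_mm = _draw_center(rng, params, base_d)
    jit = params.registration_jitter_vox
    if jit > 0:
        dy = int(rng.integers(-jit, jit + 1)) * params.voxel_spacing[1]
        dx = int(rng.integers(-jit, jit + 1)) * params.voxel_spacing[2]
        cz, cy, cx = rec.lesion_center_mm
        rec.later_center_mm = (cz, cy + dy, cx + dx)

    if params.contrast_separation is not None:
        # benchmark mode: the subtraction-contrast target is fixed at render
        # time relative to the visit's measured background level (benign foci
        # stay below it, cancer lesions exceed it by at least the separation
        # margin), so the margin survives background-referenced intensity
        # normalization at any BPE level. Only the uniform draw is fixed here.
        rec.benchmark_contrast_u = float(rng.uniform())
    return rec


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = [
    "subject_id", "group", "true_label", "mutated_gene", "bpe_level",
    "days_between_scans", "kinetic_initial_class", "kinetic_delayed_class",
    "prior_scan_path", "later_scan_path", "prior_mask_path", "later_mask_path",
    "prior_central_slice", "later_central_slice", "prior_morphology",
    "later_morphology", "prior_diameter_mm", "later_diameter_mm",
]


def generate_cohort(params: CohortParams, output_dir: str | Path) -> CohortManifest:
    """Write a full labeled cohort (volumes, masks, manifest) to ``output_dir``.

    Deterministic given ``params.seed``: the manifest (and every volume) is
    byte-for-byte reproducible.
    """
    params.validate()
    root = Path(output_dir)
    root.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if params.compress else ".nii"

    groups = (
        ["cancer_with_abnormality"] * params.n_cancer_with_abnormality
        + ["cancer_without_abnormality"] * params.n_cancer_without
        + ["cancer_free"] * params.n_cancer_free
    )
    rows = []
    for i, group in enumerate(groups):
        sub_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=params.seed, spawn_key=(i,))
        )
        rec = _make_subject(i, group, params, sub_rng)
        subdir = root / rec.subject_id
        subdir.mkdir(exist_ok=True)
        for visit, visit_key in (("prior", 0), ("later", 1)):
            visit_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=params.seed, spawn_key=(i, visit_key))
            )
            series, annot = synthesize_dce_series(rec, params, visit, visit_rng)
            spath = subdir / f"{visit}_dce{ext}"
            write_dce_series(series, spath)
            mpath = None
            if annot is not None:
                mpath = subdir / f"{visit}_mask{ext}"
                write_mask(annot, params.voxel_spacing, mpath)
            if visit == "prior":
                rec.prior_scan_path = str(spath.relative_to(root))
                if annot is not None:
                    rec.prior_mask_path = str(mpath.relative_to(root))
                    rec.prior_central_slice = annot.central_slice_index
                    rec.prior_diameter_mm = annot.diameter_mm
            else:
                rec.later_scan_path = str(spath.relative_to(root))
                if annot is not None:
                    rec.later_mask_path = str(mpath.relative_to(root))
                    rec.later_central_slice = annot.central_slice_index
                    rec.later_diameter_mm = annot.diameter_mm
        rows.append(_manifest_row(rec))

    _write_manifest(root / "manifest.csv", rows)
    snapshot = {
        "params": _params_to_jsonable(params),
        "seed": params.seed,
        "dcefoci_version": _version(),
    }
    with open(root / "params.json", "w") as fh:
        json.dump(snapshot, fh, indent=2, sort_keys=True)
    df = pd.read_csv(root / "manifest.csv", keep_default_na=False)
    return CohortManifest(df=df, root=root, params=params)


def _manifest_row(rec: SubjectRecord) -> dict:
    def fmt(x, nd=3):
        return "" if x is None else f"{x:.{nd}f}"

    kin_i, kin_d = rec.true_kinetic_class or ("", "")
    return {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "true_label": rec.true_label,
        "mutated_gene": rec.mutated_gene,
        "bpe_level": rec.bpe_level,
        "days_between_scans": fmt(rec.days_between_scans, 1),
        "kinetic_initial_class": kin_i,
        "kinetic_delayed_class": kin_d,
        "prior_scan_path": rec.prior_scan_path or "",
        "later_scan_path": rec.later_scan_path or "",
        "prior_mask_path": rec.prior_mask_path or "",
        "later_mask_path": rec.later_mask_path or "",
        "prior_central_slice": "" if rec.prior_central_slice is None else rec.prior_central_slice,
        "later_central_slice": "" if rec.later_central_slice is None else rec.later_central_slice,
        "prior_morphology": rec.prior_morphology if rec.prior_mask_path else "",
        "later_morphology": rec.later_morphology if rec.later_mask_path else "",
        "prior_diameter_mm": fmt(rec.prior_diameter_mm if rec.prior_mask_path else None),
        "later_diameter_mm": fmt(rec.later_diameter_mm if rec.later_mask_path else None),
    }


def _write_manifest(path: Path, rows: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_MANIFEST_COLUMNS, lineterminator="\r\n")
        writer.writeheader()
        writer.writerows(rows)


def _params_to_jsonable(params: CohortParams) -> dict:
    out = dataclasses.asdict(params)
    for key, val in out.items():
        if isinstance(val, tuple):
            out[key] = list(val)
    return out


def _version() -> str:
    from . import __version__

    return __version__


# ---------------------------------------------------------------------------
# Prominent-focus picking
# ---------------------------------------------------------------------------


def find_prominent_focus(
    sub: SubtractionImage, percentile: float = 99.5
) -> LesionAnnotation:
    """Pick the most prominent enhancing blob in a subtraction volume.

    Prominence is operationalized as the brightest connected component above
    the ``percentile``-th subtraction-intensity percentile; the annotation is
    placed on the component's largest-area slice.
    """
    thr = float(np.percentile(sub.data, percentile))
    above = sub.data > thr
    if not above.any():
        raise AnnotationError("no voxels above the prominence threshold")
    labels, n = cc_label(above)
    best, best_mean = 0, -np.inf
    for lbl in range(1, n + 1):
        m = float(sub.data[labels == lbl].mean())
        if m > best_mean:
            best, best_mean = lbl, m
    comp = labels == best
    areas = comp.sum(axis=(1, 2))
    k0 = int(np.argmax(areas))
    return LesionAnnotation(
        central_slice_index=k0, mask=comp[k0], morphology="focus", visit="prior"
    )
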