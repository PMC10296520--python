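"""DCE-MRI series I/O, subtraction images, ROIs, dual patches and diameters.

Conventions
-----------
* Volumes are ``(n_slices, n_rows, n_cols)`` float32 arrays; axial slices lie
  along the first axis; voxel indices are 0-based.
* A series holds exactly 5 aligned volumes: index 0 is pre-contrast, 1–4 are
  the post-contrast time points.
* Lesion masks are 2-D binary arrays on the subtraction grid of one axial
  slice (the lesion's central slice).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy.spatial.distance import pdist
from skimage.transform import resize

from .errors import AnnotationError, FormatError, ParameterError
from .kinetics import TimeIntensityCurve

#: Nominal acquisition times in minutes: pre-contrast, then post-contrast
#: frames centered at 1:25, 3:25, 5:25 and 7:35 after injection.
DEFAULT_ACQUISITION_TIMES = (0.0, 85 / 60, 205 / 60, 325 / 60, 455 / 60)

N_TIME_POINTS = 5
LOCAL_PATCH_SIZE = 24
CONTEXT_PATCH_SIZE = 128

MORPHOLOGIES = ("focus", "mass", "non-mass")


@dataclass
class DceSeries:
    """One visit's dynamic series: 5 aligned 3-D volumes."""

    volumes: np.ndarray  # (5, nz, ny, nx)
    voxel_spacing: tuple[float, float, float]  # mm per axis (z, y, x)
    acquisition_times: tuple[float, ...] = DEFAULT_ACQUISITION_TIMES

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=np.float32)
        if self.volumes.ndim != 4 or self.volumes.shape[0] != N_TIME_POINTS:
            raise FormatError(
                f"expected {N_TIME_POINTS} aligned volumes, got array of shape "
                f"{self.volumes.shape}"
            )
        if len(self.acquisition_times) != N_TIME_POINTS:
            raise FormatError("need one acquisition time per time point")
        if any(s <= 0 for s in self.voxel_spacing):
            raise FormatError(f"voxel spacing must be positive, got {self.voxel_spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]


@dataclass
class SubtractionImage:
    """Signed post-minus-pre volume; negative values are retained."""

    data: np.ndarray  # (nz, ny, nx), signed
    voxel_spacing: tuple[float, float, float]
    baseline_index: int = 0
    post_index: int = 2


@dataclass
class LesionAnnotation:
    """A marked abnormality: central axial slice plus a 2-D binary mask."""

    central_slice_index: int
    mask: np.ndarray  # 2-D bool on that slice's grid
    morphology: str = "focus"
    visit: str = "prior"
    diameter_mm: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise AnnotationError(f"mask must be 2-D, got {self.mask.ndim}-D")
        if not self.mask.any():
            raise AnnotationError("annotation mask is empty")
        if self.morphology not in MORPHOLOGIES:
            raise AnnotationError(f"unknown morphology {self.morphology!r}")


@dataclass
class PatchPair:
    """The classifier's two inputs, cut from one subtraction slice."""

    local_patch: np.ndarray  # (24, 24)
    context_patch: np.ndarray  # (128, 128)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.local_patch.shape != (LOCAL_PATCH_SIZE, LOCAL_PATCH_SIZE):
            raise FormatError(f"local patch must be 24x24, got {self.local_patch.shape}")
        if self.context_patch.shape != (CONTEXT_PATCH_SIZE, CONTEXT_PATCH_SIZE):
            raise FormatError(
                f"context patch must be 128x128, got {self.context_patch.shape}"
            )


# ---------------------------------------------------------------------------
# NIfTI round-trip
# ---------------------------------------------------------------------------


def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_dce_series(series: DceSeries, path: str | Path) -> Path:
    """Write a series as a single 4-D NIfTI file (frames along the 4th axis)."""
    path = Path(path)
    data = np.moveaxis(series.volumes, 0, -1)  # (nz, ny, nx, 5)
    img = nib.Nifti1Image(data.astype(np.float32), _affine(series.voxel_spacing))
    zooms = (*series.voxel_spacing, 1.0)
    img.header.set_zooms(zooms)
    nib.save(img, path)
    return path


def write_mask(annotation: LesionAnnotation, spacing, path: str | Path) -> Path:
    """Write a 2-D annotation mask as NIfTI (uint8)."""
    path = Path(path)
    img = nib.Nifti1Image(
        annotation.mask.astype(np.uint8), _affine((spacing[1], spacing[2], 1.0))
    )
    nib.save(img, path)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    mask = np.asarray(nib.load(str(path)).dataobj)
    return mask.astype(bool)


def read_dce_series(
    paths: str | Path | Sequence[str | Path],
    acquisition_times: tuple[float, ...] = DEFAULT_ACQUISITION_TIMES,
) -> DceSeries:
    """Load a series from one 4-D NIfTI file or 5 per-time-point files.

    The two layouts yield identical :class:`DceSeries` objects. Shapes and
    voxel spacings must agree across files.
    """
    if isinstance(paths, (str, Path)):
        img = nib.load(str(paths))
        data = np.asarray(img.dataobj, dtype=np.float32)
        if data.ndim != 4 or data.shape[-1] != N_TIME_POINTS:
            raise FormatError(
                f"4-D series file must have {N_TIME_POINTS} frames, got shape {data.shape}"
            )
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        volumes = np.moveaxis(data, -1, 0)
        return DceSeries(volumes, spacing, acquisition_times)

    paths = list(paths)
    if len(paths) != N_TIME_POINTS:
        raise FormatError(f"expected {N_TIME_POINTS} volume files, got {len(paths)}")
    volumes, spacings, shapes = [], [], []
    for p in paths:
        img = nib.load(str(p))
        arr = np.asarray(img.dataobj, dtype=np.float32)
        if arr.ndim != 3:
            raise FormatError(f"{p}: expected a 3-D volume, got shape {arr.shape}")
        volumes.append(arr)
        spacings.append(tuple(float(z) for z in img.header.get_zooms()[:3]))
        shapes.append(arr.shape)
    if len(set(shapes)) != 1:
        raise FormatError(f"time-point shapes differ: {shapes}")
    if len(set(spacings)) != 1:
        raise FormatError(f"time-point spacings differ: {spacings}")
    return DceSeries(np.stack(volumes), spacings[0], acquisition_times)


# ---------------------------------------------------------------------------
# Subtraction & ROI curves
# ---------------------------------------------------------------------------


def compute_subtraction(
    series: DceSeries, baseline_index: int = 0, post_index: int = 2
) -> SubtractionImage:
    """Voxelwise signed difference volumes[post] - volumes[baseline].

    The default pairs the pre-contrast volume with the 2nd post-contrast
    time point (series index 2), the standard sub-DCE image.
    """
    n = series.volumes.shape[0]
    for idx in (baseline_index, post_index):
        if not (0 <= idx < n):
            raise ParameterError(f"time-point index {idx} out of range [0, {n})")
    if baseline_index == post_index:
        raise ParameterError("baseline and post indices must differ")
    data = series.volumes[post_index] - series.volumes[baseline_index]
    return SubtractionImage(data, series.voxel_spacing, baseline_index, post_index)


def roi_time_curve(series: DceSeries, annotation: LesionAnnotation) -> TimeIntensityCurve:
    """ROI-mean raw signal at the pre, 1st and 4th post-contrast points.

    The same 2-D central-slice mask is applied to every time point; the full
    5-point curve is kept on ``all_points``.
    """
    nz, ny, nx = series.shape
    if not (0 <= annotation.central_slice_index < nz):
        raise AnnotationError(
            f"central slice {annotation.central_slice_index} outside volume of {nz} slices"
        )
    if annotation.mask.shape != (ny, nx):
        raise AnnotationError(
            f"mask shape {annotation.mask.shape} does not match slice grid {(ny, nx)}"
        )
    sl = series.volumes[:, annotation.central_slice_index]  # (5, ny, nx)
    means = sl[:, annotation.mask].mean(axis=1)
    return TimeIntensityCurve(
        se_pre=float(means[0]),
        se_post1=float(means[1]),
        se_post4=float(means[4]),
        all_points=tuple(float(m) for m in means),
    )


# ---------------------------------------------------------------------------
# Patch extraction
# ---------------------------------------------------------------------------


def background_reference_scale(
    sub: SubtractionImage,
    annotation: LesionAnnotation | None = None,
    percentile: float = 99.0,
    margin_factor: float = 2.0,
) -> float:
    """Background intensity reference: a high percentile of the subtraction
    volume, excluding the column around the annotated lesion.

    Without the exclusion a large lesion can occupy more than 1% of a
    reduced-resolution volume and capture the percentile itself, which would
    self-normalize away exactly the lesion-to-background contrast the
    classifier needs. The excluded region is the mask bounding box expanded
    by ``margin_factor`` per side, across all slices.
    """
    data = sub.data
    if annotation is not None:
        rows, cols = np.nonzero(annotation.mask)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        mr = int(round(margin_factor * (r1 - r0)))
        mc = int(round(margin_factor * (c1 - c0)))
        keep = np.ones(data.shape[1:], dtype=bool)
        keep[max(r0 - mr, 0) : r1 + mr, max(c0 - mc, 0) : c1 + mc] = False
        if keep.any():
            data = data[:, keep]
    scale = float(np.percentile(data, percentile))
    if scale <= 0:
        scale = float(np.abs(data).max()) or 1.0
    return scale


def normalize_subtraction(
    sub: SubtractionImage,
    percentile: float = 99.0,
    clip: float = 2.0,
    annotation: LesionAnnotation | None = None,
) -> np.ndarray:
    """Scale-standardize a subtraction volume for the classifier.

    The volume is divided by its background reference (the
    ``percentile``-th intensity percentile, lesion column excluded when an
    annotation is given) and clipped to ``[-clip, clip]``. Negative
    subtraction values are preserved.
    """
    scale = background_reference_scale(sub, annotation, percentile)
    return np.clip(sub.data / scale, -clip, clip).astype(np.float32)


def _crop_padded(image: np.ndarray, center: tuple[int, int], size: int) -> np.ndarray:
    """Fixed-size crop centered on ``center``, zero-padded past image bounds."""
    out = np.zeros((size, size), dtype=image.dtype)
    half = size // 2
    r0, c0 = center[0] - half, center[1] - half
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r0 + size, image.shape[0]), min(c0 + size, image.shape[1])
    if rs < re and cs < ce:
        out[rs - r0 : re - r0, cs - c0 : ce - c0] = image[rs:re, cs:ce]
    return out


def extract_patch_pair(
    sub: SubtractionImage,
    annotation: LesionAnnotation,
    margin: float = 0.2,
    normalized: np.ndarray | None = None,
) -> PatchPair:
    """Cut the classifier's local (24x24) and context (128x128) patches.

    The local patch is the mask bounding box expanded by ``margin`` per side,
    cropped from the central slice and bilinearly resampled to 24x24. The
    context patch is a native-resolution 128x128 crop centered on the mask
    centroid, zero-padded where it exceeds the image. Both come from the same
    (intensity-normalized) subtraction slice.
    """
    data = (
        normalized
        if normalized is not None
        else normalize_subtraction(sub, annotation=annotation)
    )
    nz = data.shape[0]
    if not (0 <= annotation.central_slice_index < nz):
        raise AnnotationError("annotation slice outside subtraction volume")
    plane = data[annotation.central_slice_index]
    rows, cols = np.nonzero(annotation.mask)

    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    mr = int(round(margin * (r1 - r0)))
    mc = int(round(margin * (c1 - c0)))
    r0, r1 = max(r0 - mr, 0), min(r1 + mr, plane.shape[0])
    c0, c1 = max(c0 - mc, 0), min(c1 + mc, plane.shape[1])
    crop = plane[r0:r1, c0:c1]
    if crop.shape == (LOCAL_PATCH_SIZE, LOCAL_PATCH_SIZE):
        local = crop.astype(np.float32)
    else:
        local = resize(
            crop.astype(np.float64),
            (LOCAL_PATCH_SIZE, LOCAL_PATCH_SIZE),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        ).astype(np.float32)

    centroid = (int(round(rows.mean())), int(round(cols.mean())))
    context = _crop_padded(plane, centroid, CONTEXT_PATCH_SIZE).astype(np.float32)
    return PatchPair(local, context)


# ---------------------------------------------------------------------------
# Diameter
# ---------------------------------------------------------------------------


def measure_diameter(annotation: LesionAnnotation, spacing: Sequence[float]) -> float:
    """Largest in-plane diameter (max Feret) of a mask, in mm.

    Maximum pairwise center-to-center distance between boundary pixels, using
    the in-plane pixel spacing ``(row_mm, col_mm)``. A single pixel has
    diameter 0.
    """
    mask = annotation.mask
    if not mask.any():  # pragma: no cover - constructor already guards
        raise AnnotationError("annotation mask is empty")
    # boundary = pixels with at least one 4-neighbour outside the mask
    padded = np.pad(mask, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = mask & ~interior
    pts = np.argwhere(boundary).astype(np.float64)
    if len(pts) < 2:
        return 0.0
    pts[:, 0] *= spacing[0]
    pts[:, 1] *= spacing[1]
    if len(pts) > 400:
        # reduce to convex hull vertices; the max Feret is attained there
        from scipy.spatial import ConvexHull

        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass
    return float(pdist(pts).max())
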