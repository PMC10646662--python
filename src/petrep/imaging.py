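"""Image ingestion, SUV normalisation, segmentation and resampling.

The processing chain mirrors clinical PET lesion workflows: activity
concentration volumes are converted to body-weight standardised uptake
values (SUV_bw), candidate lesions are found by a global SUV threshold,
contours below a minimum volume are discarded, test and retest lesions are
matched, and images/masks are resampled to an isotropic grid before
texture analysis.

Conventions
-----------
* Arrays are indexed ``(x, y, z)``; ``spacing_mm`` and ``origin_mm`` follow
  the same axis order, in millimetres.
* The voxel grid is corner-anchored: voxel ``(i, j, k)`` has its centre at
  ``origin + (i + 0.5) * spacing`` is *not* used -- voxel centres sit at
  ``origin + index * spacing``, matching a diagonal NIfTI affine.
* Masks are boolean arrays on the same grid as their image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

log = logging.getLogger("petrep")

#: voxel connectivity used for connected components (3-D, 26-neighbourhood)
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageVolume:
    """A 3-D scalar volume with physical geometry.

    ``values`` are SUV_bw for PET inputs; filtered volumes reuse the type
    and may be negative (e.g. Laplacian-of-Gaussian responses), so
    non-negativity is not enforced here.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError(f"expected a 3-D volume, got shape {self.values.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("volume contains non-finite values")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.values.copy(), self.spacing_mm, self.origin_mm)


@dataclass
class LesionMask:
    """Binary lesion support aligned to an :class:`ImageVolume`."""

    support: np.ndarray
    lesion_id: str
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support).astype(bool)
        if self.support.ndim != 3:
            raise ValidationError("mask must be 3-D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def voxel_count(self) -> int:
        return int(self.support.sum())

    def volume_mm3(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing_mm))

    def volume_ml(self) -> float:
        return self.volume_mm3() / 1000.0

    def centroid_mm(self) -> np.ndarray:
        idx = np.argwhere(self.support)
        if idx.size == 0:
            raise ValidationError(f"mask {self.lesion_id!r} is empty")
        return np.asarray(self.origin_mm) + idx.mean(axis=0) * np.asarray(self.spacing_mm)


@dataclass
class LesionPair:
    """A matched test-retest lesion with both images and masks."""

    subject_id: str
    lesion_id: str
    test_image: ImageVolume
    test_mask: LesionMask
    retest_image: ImageVolume
    retest_mask: LesionMask
    group_label: str = ""


# ---------------------------------------------------------------------------
# SUV conversion
# ---------------------------------------------------------------------------


def convert_to_suv(
    activity_volume: ImageVolume,
    injected_activity_mbq: float,
    body_weight_kg: float,
) -> ImageVolume:
    """Convert an activity-concentration volume (kBq/mL) to SUV_bw.

    SUV_bw = concentration / (injected activity / body weight), with the
    body weight expressed as an equivalent distribution volume (1 g ~ 1 mL):

        SUV_bw = c[kBq/mL] * weight[g] / injected[kBq]

    A uniform concentration equal to ``injected_kBq / weight_g`` therefore
    maps to SUV 1 everywhere.
    """
    if injected_activity_mbq <= 0:
        raise ValidationError(f"injected activity must be > 0 MBq, got {injected_activity_mbq}")
    if body_weight_kg <= 0:
        raise ValidationError(f"body weight must be > 0 kg, got {body_weight_kg}")
    injected_kbq = injected_activity_mbq * 1000.0
    weight_g = body_weight_kg * 1000.0
    suv = activity_volume.values * (weight_g / injected_kbq)
    return ImageVolume(suv, activity_volume.spacing_mm, activity_volume.origin_mm)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def threshold_segment(image: ImageVolume, suv_threshold: float = 3.0) -> list[LesionMask]:
    """Segment candidate lesions as connected components of {SUV >= threshold}.

    The threshold is inclusive and components use 26-connectivity. Each
    component becomes one candidate lesion mask; an empty list is a valid
    result for images with no uptake above threshold.
    """
    fg = image.values >= suv_threshold
    labels, n = ndimage.label(fg, structure=CONNECTIVITY_26)
    masks = []
    for k in range(1, n + 1):
        masks.append(
            LesionMask(labels == k, lesion_id=f"c{k:03d}", spacing_mm=image.spacing_mm,
                       origin_mm=image.origin_mm)
        )
    return masks


def filter_small_lesions(
    components: Sequence[LesionMask], min_volume_cm3: float = 1.5
) -> list[LesionMask]:
    """Drop components whose voxel volume is below ``min_volume_cm3``.

    Volume is voxel count x voxel volume; the cut is inclusive
    (volume >= 1.5 cm^3 is kept). Exclusions are logged.
    """
    kept: list[LesionMask] = []
    for m in components:
        vol_cm3 = m.volume_mm3() / 1000.0
        if vol_cm3 >= min_volume_cm3:
            kept.append(m)
        else:
            log.info("excluding lesion %s: volume %.3f cm^3 < %.2f cm^3",
                     m.lesion_id, vol_cm3, min_volume_cm3)
    return kept


# ---------------------------------------------------------------------------
# lesion matching
# ---------------------------------------------------------------------------


@dataclass
class ExclusionRecord:
    lesion_id: str
    scan: Literal["test", "retest"]
    reason: str


def match_lesions(
    test_components: Sequence[LesionMask],
    retest_components: Sequence[LesionMask],
    strategy: Literal["by_id", "centroid"] = "centroid",
    max_distance_mm: float = 20.0,
) -> tuple[list[tuple[LesionMask, LesionMask]], list[ExclusionRecord]]:
    """Pair test and retest lesion masks.

    ``by_id`` pairs masks with identical ``lesion_id``. ``centroid`` pairs
    mutually nearest centroids within ``max_distance_mm``; an exact tie in
    nearest-neighbour distance between candidate partners is ambiguous and
    raises. Unmatched lesions on either side are excluded and reported --
    the analysis only keeps lesions visible on both scans.
    """
    pairs: list[tuple[LesionMask, LesionMask]] = []
    exclusions: list[ExclusionRecord] = []

    if strategy == "by_id":
        retest_by_id = {m.lesion_id: m for m in retest_components}
        matched_retest = set()
        for t in test_components:
            r = retest_by_id.get(t.lesion_id)
            if r is None:
                exclusions.append(ExclusionRecord(t.lesion_id, "test", "no retest lesion with this id"))
            else:
                pairs.append((t, r))
                matched_retest.add(t.lesion_id)
        for r in retest_components:
            if r.lesion_id not in matched_retest:
                exclusions.append(ExclusionRecord(r.lesion_id, "retest", "no test lesion with this id"))
        return pairs, exclusions

    if strategy != "centroid":
        raise ValidationError(f"unknown matching strategy {strategy!r}")

    if not test_components or not retest_components:
        for t in test_components:
            exclusions.append(ExclusionRecord(t.lesion_id, "test", "no retest lesions"))
        for r in retest_components:
            exclusions.append(ExclusionRecord(r.lesion_id, "retest", "no test lesions"))
        return pairs, exclusions

    tc = np.array([m.centroid_mm() for m in test_components])
    rc = np.array([m.centroid_mm() for m in retest_components])
    dist = np.linalg.norm(tc[:, None, :] - rc[None, :, :], axis=2)

    matched_t: set[int] = set()
    matched_r: set[int] = set()
    for i, t in enumerate(test_components):
        row = dist[i]
        j = int(np.argmin(row))
        ties = np.flatnonzero(np.isclose(row, row[j], rtol=0, atol=1e-9))
        if len(ties) > 1:
            names = ", ".join(retest_components[k].lesion_id for k in ties)
            raise ValidationError(
                f"ambiguous centroid match for test lesion {t.lesion_id!r}: "
                f"equidistant retest lesions {names}"
            )
        # mutual nearest neighbour within the cap
        if row[j] <= max_distance_mm and int(np.argmin(dist[:, j])) == i:
            pairs.append((t, retest_components[j]))
            matched_t.add(i)
            matched_r.add(j)
    for i, t in enumerate(test_components):
        if i not in matched_t:
            exclusions.append(ExclusionRecord(t.lesion_id, "test", "no mutual nearest retest lesion within cap"))
    for j, r in enumerate(retest_components):
        if j not in matched_r:
            exclusions.append(ExclusionRecord(r.lesion_id, "retest", "no mutual nearest test lesion within cap"))
    return pairs, exclusions


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def _target_grid(image_shape: tuple[int, ...], spacing: tuple[float, ...],
                 target_mm: float) -> tuple[int, ...]:
    """Output voxel counts covering the input physical extent at target spacing."""
    extent = np.asarray(image_shape) * np.asarray(spacing)
    return tuple(int(np.ceil(e / target_mm - 1e-9)) for e in extent)


def resample_isotropic(
    image: ImageVolume, target_mm: float = 2.0, interpolation: str = "bspline"
) -> ImageVolume:
    """Resample a volume to isotropic ``target_mm`` spacing.

    Cubic B-spline interpolation (interpolating spline, prefiltered) for
    images, so constants and linear ramps are reproduced exactly away from
    borders. The output origin equals the input origin and the output grid
    covers the input physical extent. An input already on the target grid
    is returned value-identical.
    """
    order = {"bspline": 3, "linear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValidationError(f"unknown interpolation {interpolation!r}")
    spacing = image.spacing_mm
    if all(abs(s - target_mm) < 1e-12 for s in spacing):
        return image.copy()
    out_shape = _target_grid(image.shape, spacing, target_mm)
    # physical coordinate of output voxel i is origin + i*target; map to
    # fractional input index (coord - origin)/spacing = i*target/spacing
    grids = np.meshgrid(
        *[np.arange(n) * target_mm / spacing[ax] for ax, n in enumerate(out_shape)],
        indexing="ij",
    )
    coords = np.stack(grids)
    out = ndimage.map_coordinates(image.values, coords, order=order, mode="nearest")
    return ImageVolume(out.reshape(out_shape), (target_mm,) * 3, image.origin_mm)


def resample_mask_isotropic(mask: LesionMask, target_mm: float = 2.0) -> LesionMask:
    """Nearest-neighbour companion resampler for binary masks (stays binary)."""
    as_img = ImageVolume(mask.support.astype(np.float64), mask.spacing_mm, mask.origin_mm)
    res = resample_isotropic(as_img, target_mm, interpolation="nearest")
    out = res.values > 0.5
    return LesionMask(out, mask.lesion_id, res.spacing_mm, res.origin_mm)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def save_nifti(image: ImageVolume, path: str | Path) -> None:
    affine = np.diag(list(image.spacing_mm) + [1.0])
    affine[:3, 3] = image.origin_mm
    nib.save(nib.Nifti1Image(image.values.astype(np.float32), affine), str(path))


def load_nifti(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    affine = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(o) for o in affine[:3, 3])
    return ImageVolume(data, spacing, origin)


def save_mask_nifti(mask: LesionMask, path: str | Path) -> None:
    affine = np.diag(list(mask.spacing_mm) + [1.0])
    affine[:3, 3] = mask.origin_mm
    nib.save(nib.Nifti1Image(mask.support.astype(np.uint8), affine), str(path))


def load_mask_nifti(path: str | Path, lesion_id: str | None = None) -> LesionMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0
    affine = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(o) for o in affine[:3, 3])
    return LesionMask(data, lesion_id or Path(path).stem, spacing, origin)
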