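"""Conventional PET metrics and the 107-feature radiomics catalogue.

The catalogue follows the public feature definitions of the widely used
open-source radiomics tooling, which closely aligns with the Image
Biomarker Standardisation Initiative (IBSI): 14 shape, 18 first-order,
24 GLCM, 14 GLDM, 16 GLRLM, 16 GLSZM and 5 NGTDM features (107 total on
the unfiltered image). A bank of 16 image filters (exponential, logarithm,
square, square root, Laplacian-of-Gaussian at sigma = 2, 3, 4, 5 mm, and
the 8 subbands of a one-level undecimated 3-D wavelet transform) adds
93 non-shape features each: 1488 additional features per lesion.

Conventions (documented because the source publications leave them open):

* Discretisation uses a fixed bin width with edges anchored at multiples
  of the bin width (absolute SUV bins): level(v) = floor(v/w) -
  floor(min/w) + 1.
* Texture matrices use a 26-voxel neighbourhood at distance 1 and are
  direction-merged before feature computation (IBSI "merged" strategy).
* GLDM dependence size j counts the centre voxel plus its dependent
  neighbours (j >= 1); the dependence criterion is |level difference| <=
  alpha with alpha = 0.
* Degenerate (uniform-region) denominators: contrast-like features return
  0, uniformity/correlation-like features return 1; NGTDM coarseness with
  a zero denominator returns 1e6.
* Wavelet basis Coiflet-1 with symmetric boundary extension; subband
  letters (L/H per axis) follow array axis order (x, y, z).
* Intensity transforms are monotone and range-preserving: with
  M = max|SUV| over the image, square maps x -> x^2/M, square root maps
  x -> sign(x) sqrt(|x| M), logarithm maps x -> sign(x) M log(|x|+1)/
  log(M+1), exponential maps x -> exp(x log(M)/M).
* The Laplacian of Gaussian is computed in physical units (sigma in mm,
  response in SUV/mm^2), without scale normalisation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pywt
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .imaging import CONNECTIVITY_26, ImageVolume, LesionMask, ValidationError

log = logging.getLogger("petrep")

EPS = np.spacing(1.0)

#: 13 unique direction vectors of the 26-neighbourhood (one per +/- pair)
DIRECTIONS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
assert len(DIRECTIONS_13) == 13

FAMILY_SIZES = {
    "shape": 14, "firstorder": 18, "glcm": 24, "gldm": 14,
    "glrlm": 16, "glszm": 16, "ngtdm": 5,
}
N_ORIGINAL_FEATURES = sum(FAMILY_SIZES.values())          # 107
N_PER_FILTER = N_ORIGINAL_FEATURES - FAMILY_SIZES["shape"]  # 93


# ---------------------------------------------------------------------------
# conventional metrics
# ---------------------------------------------------------------------------


@dataclass
class ConventionalMetrics:
    """SUVmax, SUVmean, SUVtotal (= SUVmean x volume) and volume in mL."""

    suv_max: float
    suv_mean: float
    suv_total: float
    volume_ml: float

    def as_dict(self) -> dict[str, float]:
        return {"suv_max": self.suv_max, "suv_mean": self.suv_mean,
                "suv_total": self.suv_total, "volume_ml": self.volume_ml}


def conventional_metrics(image: ImageVolume, mask: LesionMask) -> ConventionalMetrics:
    """Lesion-level conventional metrics on the original (unresampled) grid."""
    vox = image.values[mask.support]
    if vox.size == 0:
        raise ValidationError(f"mask {mask.lesion_id!r} is empty")
    volume_ml = vox.size * image.voxel_volume_mm3 / 1000.0
    mean = float(vox.mean())
    return ConventionalMetrics(
        suv_max=float(vox.max()),
        suv_mean=mean,
        suv_total=mean * volume_ml,
        volume_ml=volume_ml,
    )


# ---------------------------------------------------------------------------
# discretisation
# ---------------------------------------------------------------------------


@dataclass
class DiscretisationSpec:
    bin_width: float = 0.2
    edge_anchor: str = "zero"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be > 0")
        if self.edge_anchor != "zero":
            raise ValidationError("only zero-anchored bin edges are supported")


def discretise(
    image: ImageVolume | np.ndarray,
    mask: LesionMask | np.ndarray,
    spec: DiscretisationSpec | None = None,
) -> tuple[np.ndarray, int]:
    """Fixed-bin-width grey-level discretisation of the masked voxels.

    Bin edges sit at integer multiples of ``bin_width``, so the bins are
    absolute on the SUV scale and shifting all values by exactly one bin
    width leaves the level map unchanged. Levels are
    ``floor(v/w) - floor(min/w) + 1`` -- positive integers starting at 1;
    voxels outside the mask get level 0. Returns the level volume and the
    number of levels (maximum level).
    """
    spec = spec or DiscretisationSpec()
    values = image.values if isinstance(image, ImageVolume) else np.asarray(image)
    support = mask.support if isinstance(mask, LesionMask) else np.asarray(mask, bool)
    if not support.any():
        raise ValidationError("cannot discretise an empty mask")
    w = spec.bin_width
    binned = np.floor(values / w).astype(np.int64)
    base = binned[support].min()
    levels = np.zeros(values.shape, dtype=np.int64)
    levels[support] = binned[support] - base + 1
    return levels, int(levels[support].max())


# ---------------------------------------------------------------------------
# texture matrices (26-neighbourhood, distance 1, direction-merged)
# ---------------------------------------------------------------------------


def _shifted_views(a: np.ndarray, offset: tuple[int, int, int]):
    """Return aligned views (centre, neighbour) of `a` for an offset."""
    sl_c, sl_n = [], []
    for o in offset:
        if o == 0:
            sl_c.append(slice(None)); sl_n.append(slice(None))
        elif o > 0:
            sl_c.append(slice(None, -o)); sl_n.append(slice(o, None))
        else:
            sl_c.append(slice(-o, None)); sl_n.append(slice(None, o))
    return a[tuple(sl_c)], a[tuple(sl_n)]


def glcm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric grey-level co-occurrence matrix merged over 13 directions."""
    P = np.zeros((n_levels, n_levels), dtype=np.float64)
    for off in DIRECTIONS_13:
        c, n = _shifted_views(levels, off)
        valid = (c > 0) & (n > 0)
        ci, ni = c[valid] - 1, n[valid] - 1
        np.add.at(P, (ci, ni), 1.0)
        np.add.at(P, (ni, ci), 1.0)
    return P


def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Grey-level dependence matrix.

    Column j = (number of 26-neighbours with |level difference| <= alpha)
    + 1, counting the centre voxel as dependent on itself.
    """
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in DIRECTIONS_13:
        for sgn in (1, -1):
            o = tuple(sgn * v for v in off)
            c, n = _shifted_views(levels, o)
            add = np.zeros(levels.shape, dtype=np.int64)
            cc, nn = _shifted_views(add, o)
            mask = (c > 0) & (n > 0) & (np.abs(c - n) <= alpha)
            cc += mask
            dep += add
    inside = levels > 0
    dmax = int(dep[inside].max()) + 1 if inside.any() else 1
    P = np.zeros((n_levels, dmax), dtype=np.float64)
    np.add.at(P, (levels[inside] - 1, dep[inside]), 1.0)
    return P


def glrlm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Grey-level run-length matrix merged over 13 directions.

    A run is a maximal collinear sequence of equal non-zero levels; runs
    from all directions accumulate into one matrix.
    """
    inside = levels > 0
    max_run = int(max(levels.shape))
    # diagonal runs can exceed any single axis length
    max_run = int(np.ceil(np.sqrt(3) * max_run)) + 1
    P = np.zeros((n_levels, max_run), dtype=np.float64)
    shape = levels.shape
    for off in DIRECTIONS_13:
        # run starts: voxel whose predecessor along -off is outside the
        # array, outside the mask, or a different level
        pred = np.zeros(shape, dtype=np.int64)
        c, n = _shifted_views(pred, off)            # c at x, n at x+off
        cl, nl = _shifted_views(levels, off)
        # mark, at position x+off, the level of its predecessor x
        n += cl  # pred[x+off] = levels[x]; borders keep 0
        starts = inside & (pred != levels)
        coords = np.argwhere(starts)
        if coords.size == 0:
            continue
        offv = np.asarray(off)
        run_len = np.ones(len(coords), dtype=np.int64)
        lev = levels[tuple(coords.T)]
        active = np.ones(len(coords), dtype=bool)
        pos = coords.copy()
        while active.any():
            pos[active] += offv
            idx = np.flatnonzero(active)
            nxt = pos[idx]
            inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
            cont = np.zeros(len(idx), dtype=bool)
            if inb.any():
                sub = nxt[inb]
                cont[inb] = levels[tuple(sub.T)] == lev[idx[inb]]
            run_len[idx[cont]] += 1
            active[idx[~cont]] = False
        np.add.at(P, (lev - 1, run_len - 1), 1.0)
    used = int(np.max(np.nonzero(P.sum(axis=0))[0])) + 1 if P.any() else 1
    return P[:, :used]


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Grey-level size-zone matrix (26-connected zones of equal level)."""
    sizes_per_level: list[tuple[int, np.ndarray]] = []
    max_size = 1
    for g in range(1, n_levels + 1):
        lab, nz = ndimage.label(levels == g, structure=CONNECTIVITY_26)
        if nz:
            counts = np.bincount(lab.ravel())[1:]
            sizes_per_level.append((g, counts))
            max_size = max(max_size, int(counts.max()))
    P = np.zeros((n_levels, max_size), dtype=np.float64)
    for g, counts in sizes_per_level:
        for s in counts:
            P[g - 1, s - 1] += 1.0
    return P


def ngtdm_matrix(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Neighbourhood grey-tone difference matrix.

    Returns (s, n, Nv): per-level summed absolute difference from the
    26-neighbourhood mean, per-level voxel counts, and the number of
    contributing voxels (those with at least one in-mask neighbour).
    """
    inside = levels > 0
    nsum = np.zeros(levels.shape, dtype=np.float64)
    ncnt = np.zeros(levels.shape, dtype=np.int64)
    for off in DIRECTIONS_13:
        for sgn in (1, -1):
            o = tuple(sgn * v for v in off)
            acc_s = np.zeros(levels.shape); acc_c = np.zeros(levels.shape, dtype=np.int64)
            c, n = _shifted_views(levels, o)
            s_c, _ = _shifted_views(acc_s, o)
            c_c, _ = _shifted_views(acc_c, o)
            valid = (c > 0) & (n > 0)
            s_c += np.where(valid, n, 0)
            c_c += valid
            nsum += acc_s
            ncnt += acc_c
    contrib = inside & (ncnt > 0)
    mean_nb = np.zeros(levels.shape)
    mean_nb[contrib] = nsum[contrib] / ncnt[contrib]
    diff = np.abs(levels - mean_nb)
    s = np.zeros(n_levels)
    n_i = np.zeros(n_levels, dtype=np.int64)
    lv = levels[contrib]
    np.add.at(s, lv - 1, diff[contrib])
    np.add.at(n_i, lv - 1, 1)
    return s, n_i, int(contrib.sum())


def texture_matrices(levels: np.ndarray, n_levels: int, family: str):
    """Dispatch to one of the five texture-matrix constructors."""
    builders = {
        "glcm": glcm_matrix, "gldm": gldm_matrix,
        "glrlm": glrlm_matrix, "glszm": glszm_matrix, "ngtdm": ngtdm_matrix,
    }
    if family not in builders:
        raise ValidationError(f"unknown texture family {family!r}")
    return builders[family](levels, n_levels)


# ---------------------------------------------------------------------------
# first-order features
# ---------------------------------------------------------------------------


def firstorder_features(
    image: ImageVolume | np.ndarray,
    mask: LesionMask | np.ndarray,
    spec: DiscretisationSpec | None = None,
    voxel_volume_mm3: float | None = None,
) -> dict[str, float]:
    values = image.values if isinstance(image, ImageVolume) else np.asarray(image)
    support = mask.support if isinstance(mask, LesionMask) else np.asarray(mask, bool)
    if voxel_volume_mm3 is None:
        voxel_volume_mm3 = (image.voxel_volume_mm3 if isinstance(image, ImageVolume) else 1.0)
    x = values[support].astype(np.float64)
    if x.size == 0:
        raise ValidationError("empty mask")
    npx = x.size
    mean = x.mean()
    var = x.var()          # population variance
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    levels, n_levels = discretise(values, support, spec)
    counts = np.bincount(levels[support], minlength=n_levels + 1)[1:]
    p = counts / counts.sum()
    p_nz = p[p > 0]
    m2 = var
    skew = float(np.mean((x - mean) ** 3) / sd**3) if sd > 0 else 0.0
    kurt = float(np.mean((x - mean) ** 4) / m2**2) if m2 > 0 else 0.0
    return {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(voxel_volume_mm3 * np.sum(x**2)),
        "Entropy": float(-np.sum(p_nz * np.log2(p_nz + EPS))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": (
            float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(var),
        "Uniformity": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# texture features
# ---------------------------------------------------------------------------


def glcm_features(P: np.ndarray) -> dict[str, float]:
    total = P.sum()
    if total == 0:
        raise ValidationError("empty GLCM (single-voxel region?)")
    p = P / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)                       # symmetric: px == py
    mu = float(np.sum(i * px))
    sig2 = float(np.sum(px * (i - mu) ** 2))
    # diagonal/cross-diagonal distributions
    k_diff = np.arange(0, ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj - 2).ravel(), p.ravel())

    hxy = float(-np.sum(p * np.log2(p + EPS)))
    pxpy = np.outer(px, px)
    hxy1 = float(-np.sum(p * np.log2(pxpy + EPS)))
    hxy2 = float(-np.sum(pxpy * np.log2(pxpy + EPS)))
    hx = float(-np.sum(px * np.log2(px + EPS)))
    max_h = max(hx, hx)
    imc1 = (hxy - hxy1) / max_h if max_h > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    autoc = float(np.sum(p * ii * jj))
    corr = (autoc - mu * mu) / sig2 if sig2 > 0 else 1.0

    da = float(np.sum(k_diff * p_diff))
    present = px > 0
    if present.sum() > 1:
        pp = p[np.ix_(present, present)]
        pxp = px[present]
        Q = (pp[:, None, :] * pp[None, :, :] / (pxp[:, None, None] * pxp[None, None, :])).sum(axis=2)
        eig = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, eig[-2])))
    else:
        mcc = 1.0

    nz = (ii != jj)
    return {
        "Autocorrelation": autoc,
        "ClusterProminence": float(np.sum(p * (ii + jj - 2 * mu) ** 4)),
        "ClusterShade": float(np.sum(p * (ii + jj - 2 * mu) ** 3)),
        "ClusterTendency": float(np.sum(p * (ii + jj - 2 * mu) ** 2)),
        "Contrast": float(np.sum(p * (ii - jj) ** 2)),
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-np.sum(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0] + EPS))),
        "DifferenceVariance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float(np.sum(p[nz] / (ii[nz] - jj[nz]) ** 2.0)),
        "JointAverage": mu,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": float(-np.sum(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0] + EPS))),
        "SumSquares": sig2,
    }


def _size_weighted_features(P: np.ndarray, n_voxels: int, prefix: dict[str, str],
                            n_dirs: int = 1) -> dict[str, float]:
    """Shared GLRLM/GLSZM feature machinery.

    ``prefix`` maps the generic names onto family naming (run vs zone/area).
    """
    N = P.sum()
    if N == 0:
        raise ValidationError("empty size/run matrix")
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)
    s = np.arange(1, P.shape[1] + 1, dtype=np.float64)
    ii, ss = np.meshgrid(i, s, indexing="ij")
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    p = P / N
    mu_g = np.sum(i * pg / N)
    mu_s = np.sum(s * ps / N)
    pn = p[p > 0]
    out = {
        prefix["SE"]: float(np.sum(P / ss**2) / N),
        prefix["LE"]: float(np.sum(P * ss**2) / N),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / N),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2) / N**2),
        prefix["NU"]: float(np.sum(ps**2) / N),
        prefix["NUN"]: float(np.sum(ps**2) / N**2),
        prefix["P"]: float(N / (n_voxels * n_dirs)),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_g) ** 2)),
        prefix["V"]: float(np.sum(p * (ss - mu_s) ** 2)),
        prefix["ENT"]: float(-np.sum(pn * np.log2(pn + EPS))),
        "LowGrayLevelEmphasis": float(np.sum(P / ii**2) / N),
        "HighGrayLevelEmphasis": float(np.sum(P * ii**2) / N),
        prefix["SLGL"]: float(np.sum(P / (ii**2 * ss**2)) / N),
        prefix["SHGL"]: float(np.sum(P * ii**2 / ss**2) / N),
        prefix["LLGL"]: float(np.sum(P * ss**2 / ii**2) / N),
        prefix["LHGL"]: float(np.sum(P * ii**2 * ss**2) / N),
    }
    return out


def glrlm_features(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    raw = _size_weighted_features(
        P, n_voxels, n_dirs=len(DIRECTIONS_13),
        prefix={"SE": "ShortRunEmphasis", "LE": "LongRunEmphasis",
                "NU": "RunLengthNonUniformity", "NUN": "RunLengthNonUniformityNormalized",
                "P": "RunPercentage", "V": "RunVariance", "ENT": "RunEntropy",
                "SLGL": "ShortRunLowGrayLevelEmphasis", "SHGL": "ShortRunHighGrayLevelEmphasis",
                "LLGL": "LongRunLowGrayLevelEmphasis", "LHGL": "LongRunHighGrayLevelEmphasis"})
    raw["LowGrayLevelRunEmphasis"] = raw.pop("LowGrayLevelEmphasis")
    raw["HighGrayLevelRunEmphasis"] = raw.pop("HighGrayLevelEmphasis")
    return raw


def glszm_features(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    raw = _size_weighted_features(
        P, n_voxels,
        prefix={"SE": "SmallAreaEmphasis", "LE": "LargeAreaEmphasis",
                "NU": "SizeZoneNonUniformity", "NUN": "SizeZoneNonUniformityNormalized",
                "P": "ZonePercentage", "V": "ZoneVariance", "ENT": "ZoneEntropy",
                "SLGL": "SmallAreaLowGrayLevelEmphasis", "SHGL": "SmallAreaHighGrayLevelEmphasis",
                "LLGL": "LargeAreaLowGrayLevelEmphasis", "LHGL": "LargeAreaHighGrayLevelEmphasis"})
    raw["LowGrayLevelZoneEmphasis"] = raw.pop("LowGrayLevelEmphasis")
    raw["HighGrayLevelZoneEmphasis"] = raw.pop("HighGrayLevelEmphasis")
    return raw


def gldm_features(P: np.ndarray) -> dict[str, float]:
    N = P.sum()
    if N == 0:
        raise ValidationError("empty GLDM")
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, P.shape[1] + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    p = P / N
    mu_g = np.sum(i * pg / N)
    mu_d = np.sum(j * pd / N)
    pn = p[p > 0]
    return {
        "SmallDependenceEmphasis": float(np.sum(P / jj**2) / N),
        "LargeDependenceEmphasis": float(np.sum(P * jj**2) / N),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / N),
        "DependenceNonUniformity": float(np.sum(pd**2) / N),
        "DependenceNonUniformityNormalized": float(np.sum(pd**2) / N**2),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_g) ** 2)),
        "DependenceVariance": float(np.sum(p * (jj - mu_d) ** 2)),
        "DependenceEntropy": float(-np.sum(pn * np.log2(pn + EPS))),
        "LowGrayLevelEmphasis": float(np.sum(P / ii**2) / N),
        "HighGrayLevelEmphasis": float(np.sum(P * ii**2) / N),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(P / (ii**2 * jj**2)) / N),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(P * ii**2 / jj**2) / N),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(P * jj**2 / ii**2) / N),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(P * ii**2 * jj**2) / N),
    }


def ngtdm_features(s: np.ndarray, n_i: np.ndarray, n_valid: int) -> dict[str, float]:
    if n_valid == 0:
        raise ValidationError("no voxel has an in-mask neighbour")
    i = np.arange(1, len(s) + 1, dtype=np.float64)
    p = n_i / n_valid
    present = p > 0
    ngp = int(present.sum())
    ip, pp, sp = i[present], p[present], s[present]
    coarse_den = float(np.sum(pp * sp))
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6
    if ngp > 1:
        di = ip[:, None] - ip[None, :]
        contrast = (float(np.sum(pp[:, None] * pp[None, :] * di**2))
                    / (ngp * (ngp - 1)) * float(s.sum()) / n_valid)
        busy_den = float(np.sum(np.abs((ip * pp)[:, None] - (ip * pp)[None, :])))
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        num = np.abs(di) * ((pp * sp)[:, None] + (pp * sp)[None, :]) / (pp[:, None] + pp[None, :])
        complexity = float(np.sum(num)) / n_valid
        s_sum = float(sp.sum())
        strength = (float(np.sum((pp[:, None] + pp[None, :]) * di**2)) / s_sum
                    if s_sum > 0 else 0.0)
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# shape features
# ---------------------------------------------------------------------------


def shape_features(mask: LesionMask) -> dict[str, float]:
    """Mesh- and PCA-based 3-D shape descriptors of the binary lesion support."""
    from skimage.measure import marching_cubes, mesh_surface_area

    support = mask.support
    if not support.any():
        raise ValidationError("empty mask")
    spacing = np.asarray(mask.spacing_mm)
    voxel_volume = float(np.prod(spacing))
    n = int(support.sum())

    padded = np.pad(support.astype(np.float64), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    mesh_volume = float(abs(np.sum(np.einsum("ij,ij->i", v0, np.cross(v1, v2)))) / 6.0)
    area = float(mesh_surface_area(verts, faces))
    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / area

    hull_pts = verts[ConvexHull(verts).vertices] if len(verts) >= 5 else verts
    max3d = float(pdist(hull_pts).max()) if len(hull_pts) > 1 else 0.0

    coords = np.argwhere(support) * spacing
    if n > 1:
        cov = np.cov(coords.T)
        eig = np.sort(np.maximum(np.linalg.eigvalsh(cov), 0.0))[::-1]
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elong = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    flat = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0

    def plane_diameter(drop_axis: int) -> float:
        best = 0.0
        keep = [a for a in range(3) if a != drop_axis]
        idx = np.argwhere(_surface_voxels(support))
        for sl in np.unique(idx[:, drop_axis]):
            pts = idx[idx[:, drop_axis] == sl][:, keep] * spacing[keep]
            if len(pts) > 1:
                best = max(best, float(pdist(pts).max()))
        return best

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": n * voxel_volume,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / mesh_volume,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": plane_diameter(2),   # in-plane (x, y)
        "Maximum2DDiameterColumn": plane_diameter(1),  # (x, z)
        "Maximum2DDiameterRow": plane_diameter(0),     # (y, z)
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": elong,
        "Flatness": flat,
    }


def _surface_voxels(support: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(support)
    return support & ~eroded


# ---------------------------------------------------------------------------
# filter bank
# ---------------------------------------------------------------------------

WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
LOG_SIGMAS_MM = (2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class FilterSpec:
    kind: str                     # original | exponential | logarithm | square
    #                             # | square_root | log_sigma | wavelet_subband
    sigma_mm: float | None = None
    subband: str | None = None

    @property
    def label(self) -> str:
        if self.kind == "log_sigma":
            s = f"{self.sigma_mm:g}".replace(".", "-")
            return f"log-sigma-{s}-mm"
        if self.kind == "wavelet_subband":
            return f"wavelet-{self.subband}"
        return {"square_root": "squareroot"}.get(self.kind, self.kind)


ORIGINAL = FilterSpec("original")


def filter_bank() -> list[FilterSpec]:
    """The 16 non-original filter specs: 4 intensity transforms, 4 LoG
    scales and 8 wavelet subbands."""
    bank = [FilterSpec(k) for k in ("exponential", "logarithm", "square", "square_root")]
    bank += [FilterSpec("log_sigma", sigma_mm=s) for s in LOG_SIGMAS_MM]
    bank += [FilterSpec("wavelet_subband", subband=b) for b in WAVELET_SUBBANDS]
    return bank


def apply_filter(image: ImageVolume, f: FilterSpec, wavelet: str = "coif1") -> ImageVolume:
    """Apply one bank filter; see the module docstring for the conventions."""
    v = image.values
    if f.kind == "original":
        return image.copy()
    if f.kind in ("exponential", "logarithm", "square", "square_root"):
        M = float(np.abs(v).max())
        if M == 0:
            return image.copy()
        if f.kind == "square":
            out = v**2 / M
        elif f.kind == "square_root":
            out = np.sign(v) * np.sqrt(np.abs(v) * M)
        elif f.kind == "logarithm":
            out = np.sign(v) * M * np.log1p(np.abs(v)) / np.log1p(M)
        else:  # exponential
            out = np.exp(v * np.log(M) / M) if M != 1.0 else np.exp(v - 1.0)
        return ImageVolume(out, image.spacing_mm, image.origin_mm)
    if f.kind == "log_sigma":
        spacing = image.spacing_mm
        if abs(spacing[0] - spacing[1]) > 1e-9 or abs(spacing[0] - spacing[2]) > 1e-9:
            raise ValidationError("LoG filtering requires an isotropic grid")
        s = spacing[0]
        if f.sigma_mm < s:
            warnings.warn(
                f"LoG sigma {f.sigma_mm} mm is below the voxel spacing {s} mm",
                stacklevel=2)
        out = ndimage.gaussian_laplace(v, sigma=f.sigma_mm / s, mode="nearest") / s**2
        return ImageVolume(out, image.spacing_mm, image.origin_mm)
    if f.kind == "wavelet_subband":
        pads = [(0, n % 2) for n in v.shape]
        padded = np.pad(v, pads, mode="symmetric")
        coeffs = pywt.swtn(padded, wavelet, level=1)[0]
        key = "".join("a" if c == "L" else "d" for c in f.subband)
        out = coeffs[key][tuple(slice(0, n) for n in v.shape)]
        return ImageVolume(out, image.spacing_mm, image.origin_mm)
    raise ValidationError(f"unknown filter kind {f.kind!r}")


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------


def texture_features(
    image: ImageVolume | np.ndarray,
    mask: LesionMask | np.ndarray,
    spec: DiscretisationSpec | None = None,
) -> dict[str, float]:
    """All 75 texture features (GLCM+GLDM+GLRLM+GLSZM+NGTDM) of one region."""
    support = mask.support if isinstance(mask, LesionMask) else np.asarray(mask, bool)
    levels, ng = discretise(image, support, spec)
    # crop to the mask bounding box: matrices only depend on in-mask voxels
    idx = np.argwhere(support)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    lv = levels[box]
    n_vox = int(support.sum())
    out: dict[str, float] = {}
    if n_vox == 1:
        # single voxel: no voxel pairs exist; every family degenerates to
        # the uniform-region conventions
        lv3 = lv.reshape(1, 1, 1)
        for name, val in gldm_features(gldm_matrix(lv3, ng)).items():
            out[f"gldm_{name}"] = val
        for fam in ("glcm", "glrlm", "glszm", "ngtdm"):
            for name in _FAMILY_NAMES[fam]:
                out[f"{fam}_{name}"] = 0.0
        return out
    for name, val in glcm_features(glcm_matrix(lv, ng)).items():
        out[f"glcm_{name}"] = val
    for name, val in gldm_features(gldm_matrix(lv, ng)).items():
        out[f"gldm_{name}"] = val
    for name, val in glrlm_features(glrlm_matrix(lv, ng), n_vox).items():
        out[f"glrlm_{name}"] = val
    for name, val in glszm_features(glszm_matrix(lv, ng), n_vox).items():
        out[f"glszm_{name}"] = val
    s, n_i, n_valid = ngtdm_matrix(lv, ng)
    for name, val in ngtdm_features(s, n_i, n_valid).items():
        out[f"ngtdm_{name}"] = val
    return out


_FAMILY_NAMES = {
    "glcm": list(glcm_features(np.array([[1.0, 1.0], [1.0, 1.0]])).keys()),
    "gldm": list(gldm_features(np.array([[1.0, 1.0], [1.0, 1.0]])).keys()),
    "glrlm": list(glrlm_features(np.array([[1.0, 1.0], [1.0, 1.0]]), 4).keys()),
    "glszm": list(glszm_features(np.array([[1.0, 1.0], [1.0, 1.0]]), 4).keys()),
    "ngtdm": list(ngtdm_features(np.array([1.0, 1.0]), np.array([2, 2]), 4).keys()),
}


def compute_features(
    image: ImageVolume,
    mask: LesionMask,
    spec: DiscretisationSpec | None = None,
    filters: Sequence[FilterSpec] = (),
) -> dict[str, float]:
    """Extract the named feature vector of one lesion.

    Shape features are computed once from the unfiltered mask geometry
    (filters do not alter shape); first-order and texture features are
    computed on the original image and on every requested filtered image.
    Keys are namespaced ``<filter>_<family>_<name>``, e.g.
    ``original_glcm_JointEntropy`` or ``wavelet-HLL_firstorder_Mean``.
    """
    spec = spec or DiscretisationSpec()
    out: dict[str, float] = {}
    for name, val in shape_features(mask).items():
        out[f"original_shape_{name}"] = val
    for fspec in [ORIGINAL, *filters]:
        filtered = apply_filter(image, fspec)
        lbl = fspec.label
        for name, val in firstorder_features(filtered, mask, spec).items():
            out[f"{lbl}_firstorder_{name}"] = val
        for name, val in texture_features(filtered, mask, spec).items():
            out[f"{lbl}_{name}"] = val
    return out
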