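"""Synthetic paired test-retest PET phantom generator.

Emulates the structure of a lesion-level PSMA-PET repeatability study:
per-subject volumes on a 4.07 x 4.07 x 2 mm grid, 6 mm FWHM Gaussian
post-smoothing, low soft-tissue background, and ellipsoidal lesions
(>= 1.5 cm^3) with heterogeneous, strictly positive uptake modelled as a
log-normal spatially correlated texture field.

The retest scan carries a *known* within-subject variability: each lesion's
uptake is multiplied by a per-lesion factor constructed so that the
pair-mean relative difference d_i = 100*(y_r - y_t)/((y_t + y_r)/2) is an
exact draw from N(0, 2*wcv^2) -- the theoretical within-subject CV of the
pairs is then exactly ``wcv_true_pct``. An optional multiplicative bias
emulates a systematic intertracer shift; with zero variability the mean
relative difference has the closed form B = bias/(1 + bias/200) (in %).

Setting ``texture_correlation_length_mm = 0`` or ``texture_log_sigma = 0``
disables heterogeneity (texture field identically 1), which the degenerate
test cases rely on.
"""

from __future__ import annotations

import csv
import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .imaging import ImageVolume, LesionMask, ValidationError, save_nifti, save_mask_nifti

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 0.42466

GROUP_LABELS = ("intratracer_A", "intratracer_B", "intertracer")
DEFAULT_INTERTRACER_BIAS_PCT = 10.0


@dataclass
class PhantomConfig:
    """Geometry and intensity parameters of one synthetic subject."""

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: tuple[float, float, float] = (4.07, 4.07, 2.0)
    background_suv: float = 0.5
    n_lesions: int = 3
    lesion_radius_range_mm: tuple[float, float] = (8.0, 15.0)
    lesion_mean_suv_range: tuple[float, float] = (5.0, 12.0)
    texture_correlation_length_mm: float = 8.0
    texture_log_sigma: float = 0.3
    psf_fwhm_mm: float = 6.0
    noise_sd_suv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError("spacing must be strictly positive")
        if self.background_suv < 0 or self.noise_sd_suv < 0 or self.psf_fwhm_mm < 0:
            raise ValidationError("background, noise SD and PSF FWHM must be >= 0")
        if self.texture_correlation_length_mm < 0:
            raise ValidationError("texture correlation length must be >= 0")
        if self.n_lesions < 0:
            raise ValidationError("n_lesions must be >= 0")
        for name in ("lesion_radius_range_mm", "lesion_mean_suv_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name}: low {lo} > high {hi}")
        if self.n_lesions > 0:
            r_lo = self.lesion_radius_range_mm[0]
            if 4.0 / 3.0 * np.pi * r_lo**3 < 1500.0:
                raise ValidationError(
                    "minimum lesion radius gives volume < 1.5 cm^3; lesions would be "
                    "excluded by the analysis (need radius >= 7.1 mm for spheres)"
                )


@dataclass
class RetestConfig:
    """Injected within-subject variability and systematic bias for the retest."""

    wcv_true_pct: float = 10.0
    bias_pct: float = 0.0
    redraw_noise: bool = True
    seed: int = 1

    def __post_init__(self) -> None:
        if self.wcv_true_pct < 0:
            raise ValidationError("wcv_true_pct must be >= 0")


@dataclass
class LesionTruth:
    lesion_id: str
    centroid_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    volume_ml: float            # analytic ellipsoid volume
    mean_suv: float             # nominal lesion-mean uptake on the test scan
    retest_factor: float = 1.0  # filled by generate_retest


@dataclass
class GroundTruth:
    lesions: list[LesionTruth]
    wcv_true_pct: float = 0.0
    bias_pct: float = 0.0
    # internal reconstruction state (not serialised): pre-blur scene and the
    # test-scan noise realisation, needed to synthesise a matched retest
    preblur: np.ndarray | None = field(default=None, repr=False, compare=False)
    noise: np.ndarray | None = field(default=None, repr=False, compare=False)

    def to_jsonable(self) -> dict:
        return {
            "wcv_true_pct": self.wcv_true_pct,
            "bias_pct": self.bias_pct,
            "lesions": [asdict(l) for l in self.lesions],
        }


# ---------------------------------------------------------------------------
# subject generation
# ---------------------------------------------------------------------------


def _texture_field(shape, spacing, corr_mm, log_sigma, rng) -> np.ndarray:
    """Positive log-normal texture with Gaussian-kernel spatial correlation."""
    if corr_mm <= 0 or log_sigma <= 0:
        return np.ones(shape)
    g = rng.standard_normal(shape)
    sigma_vox = [corr_mm / s for s in spacing]
    g = ndimage.gaussian_filter(g, sigma=sigma_vox, mode="wrap")
    sd = g.std()
    if sd > 0:
        g = (g - g.mean()) / sd
    return np.exp(log_sigma * g - 0.5 * log_sigma**2)


def _place_lesions(config: PhantomConfig, rng, max_attempts: int = 1000):
    """Rejection-sample non-overlapping ellipsoid centres and semi-axes."""
    shape = np.asarray(config.grid_shape, dtype=float)
    spacing = np.asarray(config.spacing_mm)
    extent = shape * spacing
    placed: list[tuple[np.ndarray, np.ndarray]] = []  # (centre_mm, semi_axes_mm)
    for _ in range(config.n_lesions):
        for attempt in range(max_attempts):
            axes = rng.uniform(*config.lesion_radius_range_mm, size=3)
            margin = axes.max() + 2.0
            if np.any(extent - 2 * margin <= 0):
                raise ValidationError("grid too small for the requested lesion radii")
            centre = rng.uniform(margin, extent - margin)
            ok = all(
                np.linalg.norm(centre - c0) > axes.max() + a0.max() + 2.0
                for c0, a0 in placed
            )
            if ok:
                placed.append((centre, axes))
                break
        else:
            raise ValidationError(
                f"could not place {config.n_lesions} non-overlapping lesions "
                f"after {max_attempts} attempts"
            )
    return placed


def generate_subject(
    config: PhantomConfig,
) -> tuple[ImageVolume, list[LesionMask], GroundTruth]:
    """Generate one subject's test scan, lesion masks and ground truth.

    Lesions are non-overlapping ellipsoids whose interior uptake is
    ``mean_suv * texture``; the scene is blurred by the PSF and corrupted by
    additive Gaussian noise truncated at 0. Masks are the pre-blur
    ellipsoid supports. Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    spacing = np.asarray(config.spacing_mm)
    shape = config.grid_shape

    texture = _texture_field(shape, config.spacing_mm,
                             config.texture_correlation_length_mm,
                             config.texture_log_sigma, rng)
    placed = _place_lesions(config, rng)

    coords = np.meshgrid(*[np.arange(n) * spacing[ax] for ax, n in enumerate(shape)],
                         indexing="ij")
    scene = np.full(shape, float(config.background_suv))
    masks: list[LesionMask] = []
    truths: list[LesionTruth] = []
    for k, (centre, axes) in enumerate(placed, start=1):
        d2 = sum(((coords[ax] - centre[ax]) / axes[ax]) ** 2 for ax in range(3))
        support = d2 <= 1.0
        mean_suv = rng.uniform(*config.lesion_mean_suv_range)
        scene[support] = mean_suv * texture[support]
        lesion_id = f"les{k:03d}"
        masks.append(LesionMask(support, lesion_id, config.spacing_mm))
        truths.append(
            LesionTruth(
                lesion_id=lesion_id,
                centroid_mm=tuple(float(c) for c in centre),
                semi_axes_mm=tuple(float(a) for a in axes),
                volume_ml=float(4.0 / 3.0 * np.pi * np.prod(axes) / 1000.0),
                mean_suv=float(mean_suv),
            )
        )

    blurred = _apply_psf(scene, config)
    noise = (rng.standard_normal(shape) * config.noise_sd_suv
             if config.noise_sd_suv > 0 else np.zeros(shape))
    values = np.maximum(blurred + noise, 0.0)
    image = ImageVolume(values, config.spacing_mm)
    truth = GroundTruth(lesions=truths, preblur=scene, noise=noise)
    return image, masks, truth


def _apply_psf(scene: np.ndarray, config: PhantomConfig) -> np.ndarray:
    if config.psf_fwhm_mm <= 0:
        return scene.copy()
    sigma_vox = [config.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in config.spacing_mm]
    return ndimage.gaussian_filter(scene, sigma=sigma_vox, mode="nearest")


# ---------------------------------------------------------------------------
# retest generation
# ---------------------------------------------------------------------------


def retest_factors(n: int, rconfig: RetestConfig) -> np.ndarray:
    """Per-lesion multiplicative retest factors.

    d ~ N(0, 2*wcv^2) is the *exact* pair-mean relative difference the
    factor induces: f = (200 + d)/(200 - d) gives
    200*(f-1)/(f+1) = d identically. The systematic bias multiplies on top.
    Draws are clipped to |d| < 190 to keep factors positive.
    """
    rng = np.random.default_rng(rconfig.seed)
    d = rng.standard_normal(n) * np.sqrt(2.0) * rconfig.wcv_true_pct
    d = np.clip(d, -190.0, 190.0)
    f = (200.0 + d) / (200.0 - d)
    return f * (1.0 + rconfig.bias_pct / 100.0)


def generate_retest(
    image: ImageVolume,
    masks: list[LesionMask],
    truth: GroundTruth,
    rconfig: RetestConfig,
    config: PhantomConfig | None = None,
) -> ImageVolume:
    """Synthesise the retest scan matched to a generated test scan.

    Each lesion's pre-blur uptake is scaled by its retest factor; the scene
    is re-blurred and noise is either redrawn (``redraw_noise``) or the test
    scan's noise realisation is reused. With ``wcv_true_pct = 0``,
    ``bias_pct = 0`` and ``redraw_noise = False`` the retest is identical to
    the test scan. Deterministic for a fixed ``rconfig.seed``.
    """
    if truth.preblur is None:
        raise ValidationError("truth lacks the pre-blur scene; regenerate the subject")
    if config is None:
        config = PhantomConfig()
    factors = retest_factors(len(masks), rconfig)
    scene = truth.preblur.copy()
    for mask, f, lt in zip(masks, factors, truth.lesions):
        scene[mask.support] *= f
        lt.retest_factor = float(f)
    truth.wcv_true_pct = rconfig.wcv_true_pct
    truth.bias_pct = rconfig.bias_pct

    blurred = _apply_psf(scene, config)
    if rconfig.redraw_noise and config.noise_sd_suv > 0:
        rng = np.random.default_rng(rconfig.seed + 1)
        noise = rng.standard_normal(scene.shape) * config.noise_sd_suv
    else:
        noise = truth.noise if truth.noise is not None else np.zeros(scene.shape)
    return ImageVolume(np.maximum(blurred + noise, 0.0), image.spacing_mm, image.origin_mm)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(
    n_subjects: int,
    group_label: str,
    config: PhantomConfig,
    rconfig: RetestConfig | None = None,
    out_dir: str | Path = "cohort",
    lesion_count_range: tuple[int, int] | None = None,
    force: bool = False,
) -> Path:
    """Write a paired phantom cohort to disk.

    Layout: ``<out>/sub-XXX/{image_test,image_retest,lesion_<id>}.nii.gz``
    plus a top-level ``pairing.csv`` (subject_id, lesion_id, test_path,
    retest_path, mask_path), ``truth.json`` and ``config.yaml``. The
    intertracer group defaults to a non-zero systematic bias; intratracer
    groups default to none. Refuses to overwrite unless ``force``.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    if group_label not in GROUP_LABELS:
        raise ValidationError(f"group_label must be one of {GROUP_LABELS}")
    if rconfig is None:
        bias = DEFAULT_INTERTRACER_BIAS_PCT if group_label == "intertracer" else 0.0
        rconfig = RetestConfig(bias_pct=bias, seed=config.seed + 1)

    out = Path(out_dir)
    if out.exists():
        if not force:
            raise ValidationError(f"output directory {out} exists; pass force=True to overwrite")
        shutil.rmtree(out)
    out.mkdir(parents=True)

    ss = np.random.SeedSequence(config.seed)
    subject_seeds = ss.generate_state(2 * n_subjects) % (2**31 - 1)
    count_rng = np.random.default_rng(subject_seeds[-1] + 7)

    rows = []
    truth_all: dict[str, dict] = {}
    for s in range(n_subjects):
        subject_id = f"sub-{s + 1:03d}"
        sdir = out / subject_id
        sdir.mkdir()
        n_les = (config.n_lesions if lesion_count_range is None
                 else int(count_rng.integers(lesion_count_range[0], lesion_count_range[1] + 1)))
        scfg = PhantomConfig(**{**asdict(config),
                                "n_lesions": n_les,
                                "seed": int(subject_seeds[2 * s])})
        srcfg = RetestConfig(wcv_true_pct=rconfig.wcv_true_pct,
                             bias_pct=rconfig.bias_pct,
                             redraw_noise=rconfig.redraw_noise,
                             seed=int(subject_seeds[2 * s + 1]))
        image, masks, truth = generate_subject(scfg)
        retest = generate_retest(image, masks, truth, srcfg, scfg)
        save_nifti(image, sdir / "image_test.nii.gz")
        save_nifti(retest, sdir / "image_retest.nii.gz")
        for mask in masks:
            save_mask_nifti(mask, sdir / f"lesion_{mask.lesion_id}.nii.gz")
            rows.append({
                "subject_id": subject_id,
                "lesion_id": mask.lesion_id,
                "test_path": f"{subject_id}/image_test.nii.gz",
                "retest_path": f"{subject_id}/image_retest.nii.gz",
                "mask_path": f"{subject_id}/lesion_{mask.lesion_id}.nii.gz",
            })
        truth_all[subject_id] = truth.to_jsonable()

    with open(out / "pairing.csv", "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["subject_id", "lesion_id", "test_path", "retest_path", "mask_path"])
        writer.writeheader()
        writer.writerows(rows)
    with open(out / "truth.json", "w") as fh:
        json.dump({"group_label": group_label, "subjects": truth_all}, fh, indent=1, sort_keys=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({"group_label": group_label,
                        "phantom": asdict(config),
                        "retest": asdict(rconfig)}, fh, sort_keys=True)
    return out
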