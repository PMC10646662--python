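"""Cohort-level orchestration and secondary analyses.

Runs the full chain on a paired dataset (synthetic or user NIfTI + pairing
CSV): conventional metrics on the original grid, optional radiomics on the
2 mm resampled grid under any subset of the filter bank, per-feature
repeatability records, reliability-classification summaries, per-filter
Wilcoxon signed-rank comparison of ICC distributions (Bonferroni
corrected), and volume-redundancy screening by absolute Spearman rank
correlation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import features as ft
from . import repstats as rs
from .imaging import (ImageVolume, LesionMask, ValidationError,
                      filter_small_lesions, load_mask_nifti, load_nifti,
                      resample_isotropic, resample_mask_isotropic)

log = logging.getLogger("petrep")

CLASSES = ("excellent", "good", "moderate", "poor")
CONVENTIONAL = ("suv_max", "suv_mean", "suv_total", "volume_ml")


@dataclass
class PipelineConfig:
    """Knobs of the end-to-end analysis (defaults follow the study design)."""

    radiomics: bool = True
    filters: str | Sequence[str] = "none"   # "none" | "all" | subset of labels
    bin_width: float = 0.2
    resample_mm: float = 2.0
    min_volume_cm3: float = 1.5
    denominator: str = "pair_mean"

    def filter_specs(self) -> list[ft.FilterSpec]:
        bank = ft.filter_bank()
        if self.filters == "none" or not self.filters:
            return []
        if self.filters == "all":
            return bank
        by_label = {f.label: f for f in bank}
        out = []
        for lbl in self.filters:
            if lbl not in by_label:
                raise ValidationError(f"unknown filter label {lbl!r}")
            out.append(by_label[lbl])
        return out


@dataclass
class GroupResult:
    group_label: str
    records: dict[str, rs.RepeatabilityRecord]
    classification: dict = field(default_factory=dict)
    filter_comparison: pd.DataFrame | None = None
    volume_correlation: pd.DataFrame | None = None
    feature_table: pd.DataFrame | None = None
    exclusions: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# feature extraction over a cohort
# ---------------------------------------------------------------------------


def extract_cohort_features(
    dataset_dir: str | Path, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(subject, lesion, scan) feature table for a paired dataset.

    Expects the layout written by :func:`petrep.synthetic.generate_cohort`:
    a ``pairing.csv`` with subject_id, lesion_id, test_path, retest_path,
    mask_path. Lesions below the volume threshold are excluded and
    reported, mirroring the study's < 1.5 cm^3 rule. Returns
    (feature table, exclusion report).
    """
    root = Path(dataset_dir)
    pairing = pd.read_csv(root / "pairing.csv")
    specs = config.filter_specs() if config.radiomics else []
    dspec = ft.DiscretisationSpec(bin_width=config.bin_width)

    image_cache: dict[str, ImageVolume] = {}

    def load(path: str) -> ImageVolume:
        if path not in image_cache:
            image_cache[path] = load_nifti(root / path)
        return image_cache[path]

    rows, exclusions = [], []
    for _, r in pairing.iterrows():
        mask = load_mask_nifti(root / r.mask_path, lesion_id=str(r.lesion_id))
        kept = filter_small_lesions([mask], config.min_volume_cm3)
        if not kept:
            exclusions.append({"subject_id": r.subject_id, "lesion_id": r.lesion_id,
                               "reason": f"volume < {config.min_volume_cm3} cm^3"})
            continue
        for scan, path in (("test", r.test_path), ("retest", r.retest_path)):
            image = load(path)
            if image.shape != mask.support.shape:
                raise ValidationError(
                    f"grid mismatch between {path} and mask {r.mask_path}")
            row: dict[str, object] = {"subject_id": r.subject_id,
                                      "lesion_id": r.lesion_id, "scan": scan}
            row.update(ft.conventional_metrics(image, mask).as_dict())
            if config.radiomics:
                cimg, cmask = _crop_to_lesion(image, mask)
                rimg = resample_isotropic(cimg, config.resample_mm)
                rmask = resample_mask_isotropic(cmask, config.resample_mm)
                row.update(ft.compute_features(rimg, rmask, dspec, specs))
            rows.append(row)
    if not rows:
        raise ValidationError(f"no includable lesions found in {root}")
    table = pd.DataFrame(rows)
    excl = pd.DataFrame(exclusions, columns=["subject_id", "lesion_id", "reason"])
    return table, excl


def _crop_to_lesion(image: ImageVolume, mask: LesionMask,
                    margin_voxels: int = 6) -> tuple[ImageVolume, LesionMask]:
    """Crop image and mask to the lesion bounding box plus a margin.

    Radiomics only depends on in-mask voxels; the margin keeps the cubic
    B-spline interpolation at the mask border identical to a full-grid
    resample to well below feature precision.
    """
    idx = np.argwhere(mask.support)
    lo = np.maximum(idx.min(axis=0) - margin_voxels, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin_voxels, mask.support.shape)
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    origin = tuple(o + l * s for o, l, s in zip(image.origin_mm, lo, image.spacing_mm))
    cimg = ImageVolume(image.values[box].copy(), image.spacing_mm, origin)
    cmask = LesionMask(mask.support[box].copy(), mask.lesion_id,
                       mask.spacing_mm, origin)
    return cimg, cmask


# ---------------------------------------------------------------------------
# repeatability over a feature table
# ---------------------------------------------------------------------------


def repeatability_records(
    table: pd.DataFrame, denominator: str = "pair_mean"
) -> dict[str, rs.RepeatabilityRecord]:
    """One repeatability record per feature column of a paired table."""
    key = ["subject_id", "lesion_id"]
    test = table[table["scan"] == "test"].set_index(key).sort_index()
    retest = table[table["scan"] == "retest"].set_index(key).sort_index()
    common = test.index.intersection(retest.index)
    if len(common) < 2:
        raise ValidationError("need at least 2 paired lesions")
    if len(common) < len(test) or len(common) < len(retest):
        log.info("dropping %d unpaired lesion rows",
                 len(test) + len(retest) - 2 * len(common))
    lesion_ids = [f"{s}/{l}" for s, l in common]
    out = {}
    for col in test.columns:
        if col == "scan":
            continue
        out[col] = rs.repeatability_record(
            col, test.loc[common, col].to_numpy(float),
            retest.loc[common, col].to_numpy(float),
            denominator=denominator, lesion_ids=lesion_ids)
    return out


def records_to_frame(records: dict[str, rs.RepeatabilityRecord],
                     group_label: str = "") -> pd.DataFrame:
    rows = []
    for rec in records.values():
        rows.append({"feature": rec.feature_name, "group": group_label, "n": rec.n,
                     "wcv_pct": rec.wcv_pct, "rc_pct": rec.rc_pct, "b_pct": rec.b_pct,
                     "loa_low_pct": rec.loa_low_pct, "loa_high_pct": rec.loa_high_pct,
                     "icc": rec.icc, "icc_ci_low": rec.icc_ci_low,
                     "icc_ci_high": rec.icc_ci_high,
                     "reliability_class": rec.reliability_class, "flags": rec.flags})
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> dict[str, rs.RepeatabilityRecord]:
    out = {}
    for _, r in df.iterrows():
        out[r.feature] = rs.RepeatabilityRecord(
            feature_name=r.feature, n=int(r.n), wcv_pct=r.wcv_pct, rc_pct=r.rc_pct,
            b_pct=r.b_pct, loa_low_pct=r.loa_low_pct, loa_high_pct=r.loa_high_pct,
            icc=r.icc, icc_ci_low=r.icc_ci_low, icc_ci_high=r.icc_ci_high,
            reliability_class=r.reliability_class,
            flags="" if pd.isna(r.flags) else str(r.flags))
    return out


# ---------------------------------------------------------------------------
# secondary analyses
# ---------------------------------------------------------------------------


def _feature_family(name: str) -> str:
    parts = name.split("_")
    return parts[1] if len(parts) >= 3 else "conventional"


def classification_summary(
    records: dict[str, rs.RepeatabilityRecord], by_family: bool = True
) -> dict:
    """Counts and percentages per reliability class, overall and per family."""
    if not records:
        raise ValidationError("no records to summarise")
    classes = [r.reliability_class for r in records.values()]
    total = len(classes)
    overall = {c: classes.count(c) for c in (*CLASSES, "undefined")}
    out = {
        "n_features": total,
        "counts": overall,
        "percent": {c: 100.0 * v / total for c, v in overall.items()},
        "good_or_excellent_percent":
            100.0 * (overall["excellent"] + overall["good"]) / total,
    }
    if by_family:
        fam: dict[str, dict[str, int]] = {}
        for name, rec in records.items():
            f = _feature_family(name)
            fam.setdefault(f, {c: 0 for c in (*CLASSES, "undefined")})
            fam[f][rec.reliability_class] += 1
        out["by_family"] = fam
    return out


def compare_filters(icc_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-filter Wilcoxon signed-rank test of ICCs against the original.

    ``icc_table``: features x filters, with a column named ``original``.
    Exact null distribution for n <= 25 pairs without zeros, otherwise the
    normal approximation with Pratt handling of zero differences.
    Bonferroni correction uses m = number of non-original filters.
    """
    if "original" not in icc_table.columns:
        raise ValidationError("icc_table must contain an 'original' column")
    orig = icc_table["original"].to_numpy(float)
    filters = [c for c in icc_table.columns if c != "original"]
    m = len(filters)
    rows = []
    for col in filters:
        vals = icc_table[col].to_numpy(float)
        ok = np.isfinite(vals) & np.isfinite(orig)
        diffs = vals[ok] - orig[ok]
        tie_flag = bool(np.all(diffs == 0))
        if tie_flag:
            p, w = 1.0, 0.0
        else:
            n = diffs.size
            method = "exact" if (n <= 25 and np.all(diffs != 0)) else "approx"
            res = stats.wilcoxon(diffs, zero_method="pratt", method=method)
            w, p = float(res.statistic), float(res.pvalue)
        p_adj = min(1.0, m * p)
        rows.append({"filter": col, "n": int(ok.sum()), "statistic": w,
                     "p_value": p, "p_adjusted": p_adj,
                     "significant": bool(p_adj < alpha), "all_ties": tie_flag})
    return pd.DataFrame(rows)


def volume_redundancy(
    feature_table: pd.DataFrame, volumes: np.ndarray | pd.Series
) -> pd.DataFrame:
    """|Spearman r_s| of each texture feature against lesion volume."""
    vol = np.asarray(volumes, float)
    if vol.size < 3:
        raise ValidationError("need at least 3 lesions for a rank correlation")
    rows = []
    for col in feature_table.columns:
        x = feature_table[col].to_numpy(float)
        if np.all(x == x[0]):
            rows.append({"feature": col, "abs_spearman_r": float("nan"),
                         "flag": "constant"})
            continue
        r, _ = stats.spearmanr(x, vol)
        rows.append({"feature": col, "abs_spearman_r": abs(float(r)), "flag": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    dataset_dir: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    group_label: str | None = None,
) -> GroupResult:
    """Run the whole analysis on one paired dataset.

    Persists ``features.csv``, ``repeatability.csv``, ``classification.json``,
    ``volume_correlation.csv``, ``exclusions.csv`` and (when more than one
    filter ran) ``filter_comparison.csv`` under ``out_dir``. Deterministic
    given the data and config.
    """
    config = config or PipelineConfig()
    root = Path(dataset_dir)
    if group_label is None:
        group_label = _dataset_group_label(root)

    table, exclusions = extract_cohort_features(root, config)
    records = repeatability_records(table, config.denominator)
    summary = classification_summary(records)

    texture_cols = [c for c in table.columns
                    if _feature_family(c) in ("glcm", "gldm", "glrlm", "glszm", "ngtdm")
                    and c.startswith("original_")]
    test_rows = table[table["scan"] == "test"]
    vol_corr = (volume_redundancy(test_rows[texture_cols],
                                  test_rows["volume_ml"].to_numpy(float))
                if texture_cols and len(test_rows) >= 3 else None)

    filt = None
    specs = config.filter_specs() if config.radiomics else []
    if specs:
        filt = compare_filters(_icc_by_filter(records))

    result = GroupResult(group_label=group_label, records=records,
                         classification=summary, filter_comparison=filt,
                         volume_correlation=vol_corr, feature_table=table,
                         exclusions=exclusions)
    if out_dir is not None:
        write_reports(result, out_dir)
    return result


def _dataset_group_label(root: Path) -> str:
    truth = root / "truth.json"
    if truth.exists():
        with open(truth) as fh:
            return json.load(fh).get("group_label", "unknown")
    return "unknown"


def _icc_by_filter(records: dict[str, rs.RepeatabilityRecord]) -> pd.DataFrame:
    """Pivot records into a features x filter-label ICC table.

    Rows are the 93 non-shape feature names; columns are filter labels
    (including ``original``); shape and conventional features are excluded
    since filters cannot affect them.
    """
    cells: dict[str, dict[str, float]] = {}
    for name, rec in records.items():
        parts = name.split("_", 2)
        if len(parts) < 3 or parts[1] == "shape":
            continue
        lbl, rest = parts[0], f"{parts[1]}_{parts[2]}"
        cells.setdefault(rest, {})[lbl] = rec.icc
    return pd.DataFrame.from_dict(cells, orient="index").sort_index()


def write_reports(result: GroupResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if result.feature_table is not None:
        result.feature_table.to_csv(out / "features.csv", index=False)
    records_to_frame(result.records, result.group_label).to_csv(
        out / "repeatability.csv", index=False)
    with open(out / "classification.json", "w") as fh:
        json.dump({"group_label": result.group_label, **result.classification},
                  fh, indent=1, sort_keys=True)
    if result.volume_correlation is not None:
        result.volume_correlation.to_csv(out / "volume_correlation.csv", index=False)
    if result.filter_comparison is not None:
        result.filter_comparison.to_csv(out / "filter_comparison.csv", index=False)
    if result.exclusions is not None:
        result.exclusions.to_csv(out / "exclusions.csv", index=False)


def read_repeatability_report(path: str | Path) -> dict[str, rs.RepeatabilityRecord]:
    """Inverse of the repeatability CSV writer (exact round-trip)."""
    return frame_to_records(pd.read_csv(path))
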