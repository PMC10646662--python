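"""Per-feature test-retest repeatability statistics.

The unit of replication is the lesion. For a feature measured on n paired
lesions (y_test, y_retest):

* relative differences (Bland-Altman convention, pair-mean denominator):
  d_i = 100 * (y_retest_i - y_test_i) / ((y_test_i + y_retest_i)/2)
* within-subject coefficient of variation: wCV = sqrt(sum d_i^2 / (2n))
* repeatability coefficient: RC = 1.96 * sqrt(2) * wCV -- the symmetric
  threshold containing 95% of test-retest variability
* 95% limits of agreement: [B - RC, B + RC] with B = mean(d)
* ICC(A,1): two-way mixed-effects model, absolute agreement, single
  measurement, with an exact F-based 95% confidence interval
  (McGraw & Wong); reliability is classified on the CI *lower bound*
  (Koo & Li): >= 0.90 excellent, [0.75, 0.90) good, [0.50, 0.75) moderate,
  < 0.50 poor.

The pair-mean denominator is the single most consequential formula choice
(the alternative normalises by the test value alone); it is switchable via
``denominator=``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .imaging import ValidationError

RC_FACTOR = 1.96 * np.sqrt(2.0)  # 2.7719


@dataclass
class RepeatabilityRecord:
    """One feature's repeatability summary (all percentages on the % scale)."""

    feature_name: str
    n: int
    wcv_pct: float
    rc_pct: float
    b_pct: float
    loa_low_pct: float
    loa_high_pct: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    reliability_class: str
    flags: str = ""


def relative_differences(
    y_test: np.ndarray,
    y_retest: np.ndarray,
    denominator: str = "pair_mean",
    lesion_ids: list[str] | None = None,
) -> np.ndarray:
    """Paired relative differences in percent.

    Pairs whose values are exactly equal yield d = 0 regardless of sign;
    otherwise a non-positive denominator is an error naming the lesion
    (relative differences are not meaningful for sign-crossing quantities).
    """
    y_test = np.asarray(y_test, dtype=np.float64)
    y_retest = np.asarray(y_retest, dtype=np.float64)
    if y_test.shape != y_retest.shape:
        raise ValidationError("test/retest vectors differ in length")
    if not (np.all(np.isfinite(y_test)) and np.all(np.isfinite(y_retest))):
        raise ValidationError("non-finite measurement values")
    if denominator == "pair_mean":
        den = (y_test + y_retest) / 2.0
    elif denominator == "test_value":
        den = y_test.copy()
    else:
        raise ValidationError(f"unknown denominator {denominator!r}")
    diff = y_retest - y_test
    equal = diff == 0
    bad = (den <= 0) & ~equal
    if np.any(bad):
        k = int(np.flatnonzero(bad)[0])
        name = lesion_ids[k] if lesion_ids else f"index {k}"
        raise ValidationError(
            f"non-positive denominator for lesion {name}: "
            f"test={y_test[k]:g}, retest={y_retest[k]:g}")
    d = np.zeros_like(diff)
    d[~equal] = 100.0 * diff[~equal] / den[~equal]
    return d


def wcv(d: np.ndarray) -> float:
    """Within-subject CV (%) from paired relative differences."""
    d = np.asarray(d, dtype=np.float64)
    if d.size == 0:
        raise ValidationError("wCV needs at least one pair")
    return float(np.sqrt(np.sum(d**2) / (2.0 * d.size)))


def repeatability_coefficient(wcv_pct: float) -> float:
    """RC = 1.96 * sqrt(2) * wCV."""
    if wcv_pct < 0:
        raise ValidationError("wCV must be >= 0")
    return RC_FACTOR * wcv_pct


def limits_of_agreement(b_pct: float, rc_pct: float) -> tuple[float, float]:
    """95% limits of agreement [B - RC, B + RC]."""
    if rc_pct < 0:
        raise ValidationError("RC must be >= 0")
    return (b_pct - rc_pct, b_pct + rc_pct)


def icc_a1(
    y_test: np.ndarray, y_retest: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """ICC(A,1): two-way model, absolute agreement, single measurement.

    Computed from the two-way ANOVA mean squares with k = 2 raters
    (scans) and n subjects (lesions):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    The 95% CI follows the F-distribution method of McGraw & Wong with a
    Satterthwaite degrees-of-freedom approximation. Exact test-retest
    agreement on non-constant data returns (1, 1, 1); zero between-subject
    variance without exact agreement is undefined and raises.
    """
    y = np.column_stack([np.asarray(y_test, float), np.asarray(y_retest, float)])
    n, k = y.shape
    if n < 2:
        raise ValidationError("ICC needs at least 2 subjects")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    if np.array_equal(y[:, 0], y[:, 1]):
        if msr == 0:
            raise ValidationError("ICC undefined: zero between-subject variance")
        return 1.0, 1.0, 1.0
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom <= 0 or msr == 0:
        raise ValidationError("ICC undefined: zero between-subject variance")
    icc = (msr - mse) / denom

    # McGraw & Wong CI for ICC(A,1)
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0)))
        f1 = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
        f2 = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
        lower = (n * (msr - f1 * mse)
                 ) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = (n * (f2 * msr - mse)
                 ) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    else:
        lower = upper = icc
    lower = float(np.clip(lower, -1.0, icc))
    upper = float(np.clip(upper, icc, 1.0))
    return float(icc), lower, upper


def icc_c1(y_test: np.ndarray, y_retest: np.ndarray) -> float:
    """Consistency-type ICC(C,1) (no CI): insensitive to systematic offsets.

    Used in tests to demonstrate that only the absolute-agreement ICC
    penalises an intertracer bias.
    """
    y = np.column_stack([np.asarray(y_test, float), np.asarray(y_retest, float)])
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    sse = np.sum((y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    if msr + (k - 1) * mse == 0:
        raise ValidationError("ICC undefined: zero variance")
    return float((msr - mse) / (msr + (k - 1) * mse))


def classify_icc(ci_low: float) -> str:
    """Koo-Li reliability class from the ICC 95% CI lower bound."""
    if not -1.0 - 1e-12 <= ci_low <= 1.0 + 1e-12:
        raise ValidationError(f"CI lower bound {ci_low} outside [-1, 1]")
    if ci_low >= 0.9:
        return "excellent"
    if ci_low >= 0.75:
        return "good"
    if ci_low >= 0.5:
        return "moderate"
    return "poor"


def repeatability_record(
    feature_name: str,
    y_test: np.ndarray,
    y_retest: np.ndarray,
    denominator: str = "pair_mean",
    lesion_ids: list[str] | None = None,
) -> RepeatabilityRecord:
    """Full repeatability summary of one feature over paired lesions.

    Features with a non-positive pair mean and non-zero difference (sign-
    crossing quantities for which a relative difference is undefined) get
    NaN wCV/RC/B/LOA and the flag ``sign_degenerate``; the ICC is still
    computed. A constant feature (zero between-subject variance) gets the
    flag ``icc_undefined`` and class ``undefined``.
    """
    y_test = np.asarray(y_test, float)
    y_retest = np.asarray(y_retest, float)
    flags = []
    try:
        d = relative_differences(y_test, y_retest, denominator, lesion_ids)
        w = wcv(d)
        rc = repeatability_coefficient(w)
        b = float(d.mean())
        lo, hi = limits_of_agreement(b, rc)
    except ValidationError:
        flags.append("sign_degenerate")
        w = rc = b = lo = hi = float("nan")
    try:
        icc, ci_lo, ci_hi = icc_a1(y_test, y_retest)
        cls = classify_icc(ci_lo)
    except ValidationError:
        flags.append("icc_undefined")
        icc = ci_lo = ci_hi = float("nan")
        cls = "undefined"
    return RepeatabilityRecord(
        feature_name=feature_name, n=int(y_test.size),
        wcv_pct=w, rc_pct=rc, b_pct=b, loa_low_pct=lo, loa_high_pct=hi,
        icc=icc, icc_ci_low=ci_lo, icc_ci_high=ci_hi,
        reliability_class=cls, flags=";".join(flags))
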