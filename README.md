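# petrep

Lesion-level test–retest repeatability analysis of quantitative PET
biomarkers — conventional SUV/volume metrics and a 107-feature radiomics
catalogue with a 16-filter image bank — plus a synthetic paired-phantom
generator so the whole chain can be validated against known ground truth.

## The problem

Quantitative PET biomarkers (SUVmax, SUVmean, SUVtotal, lesion volume,
and high-throughput radiomics texture descriptors) are only useful for
response assessment if their measurement variability is known: a change
smaller than the test–retest variability of the metric is noise, not
biology. In PSMA-PET of metastatic prostate cancer this question is
sharpened by the coexistence of two routinely used tracers
([68Ga]Ga-PSMA-11 and [18F]F-PSMA-1007): scans repeated with the *same*
tracer probe pure measurement repeatability, while scans repeated with
*different* tracers add a systematic intertracer shift.

`petrep` implements the statistical machinery of such a study at the
lesion level, for paired (test, retest) SUV volumes with binary lesion
masks:

* **relative differences** (Bland–Altman, pair-mean denominator)
  `d_i = 100 · (y_retest − y_test) / ((y_test + y_retest)/2)`;
* **within-subject coefficient of variation**
  `wCV = √(Σ d_i² / 2n)`;
* **repeatability coefficient** `RC = 1.96·√2·wCV`, the symmetric
  threshold containing 95 % of test–retest variability;
* **95 % limits of agreement** `[B − RC, B + RC]`, `B = mean(d)`;
* **ICC(A,1)** — two-way mixed-effects, absolute-agreement, single
  measurement — with an exact F-based 95 % CI, classified on the CI
  *lower bound* (≥ 0.90 excellent, ≥ 0.75 good, ≥ 0.50 moderate,
  else poor).

Secondary analyses mirror a full study: per-family reliability
classification summaries, per-filter Wilcoxon signed-rank comparison of
ICC distributions (Bonferroni corrected), and volume-redundancy screening
of texture features by absolute Spearman correlation.

The radiomics catalogue (14 shape, 18 first-order, 24 GLCM, 14 GLDM,
16 GLRLM, 16 GLSZM, 5 NGTDM = 107 features; fixed bin width 0.2 SUV;
26-neighbourhood, direction-merged matrices) and the filter bank
(exponential, logarithm, square, square root, LoG at σ = 2–5 mm, eight
wavelet subbands; + 93 features each = 1488) are implemented in
`petrep.features` and verified against independent brute-force
enumerators in the test suite.

## Worked example

```python
from petrep import (PhantomConfig, RetestConfig, PipelineConfig,
                    generate_cohort, run_pipeline)

cfg = PhantomConfig(n_lesions=3, seed=7)                    # 4.07x4.07x2 mm grid, 6 mm PSF
rcfg = RetestConfig(wcv_true_pct=10.0, bias_pct=0.0, seed=8)  # injected wCV = 10 %
data = generate_cohort(5, "intratracer_A", cfg, rcfg, out_dir="demo_cohort")

result = run_pipeline(data, PipelineConfig(radiomics=False), out_dir="demo_results")
for name, rec in result.records.items():
    print(f"{name:10s} wCV={rec.wcv_pct:5.1f}%  RC={rec.rc_pct:5.1f}%  "
          f"LOA=[{rec.loa_low_pct:+6.1f}, {rec.loa_high_pct:+6.1f}]  "
          f"ICC={rec.icc:.3f} [{rec.icc_ci_low:.3f}, {rec.icc_ci_high:.3f}]  "
          f"{rec.reliability_class}")
```

prints

```
suv_max    wCV= 11.0%  RC= 30.4%  LOA=[ -24.1,  +36.6]  ICC=0.852 [0.611, 0.948]  moderate
suv_mean   wCV= 10.6%  RC= 29.4%  LOA=[ -23.1,  +35.6]  ICC=0.840 [0.581, 0.943]  moderate
suv_total  wCV= 10.6%  RC= 29.4%  LOA=[ -23.1,  +35.6]  ICC=0.904 [0.739, 0.967]  moderate
volume_ml  wCV=  0.0%  RC=  0.0%  LOA=[  +0.0,   +0.0]  ICC=1.000 [1.000, 1.000]  excellent
```

The 15 lesion pairs carry an injected within-subject CV of 10 %, and the
estimated SUVmean wCV lands at 10.6 % with RC ≈ 29 % — a change smaller
than that is within measurement noise. Lesion volume is perfectly
repeatable here because the phantom reuses one mask per lesion pair; the
reliability classes come from the ICC CI lower bound, which is wide at
n = 15. The same pipeline runs with `radiomics=True` (and
`filters="all"`) to score all 107 / 1595 features per lesion, writing
`features.csv`, `repeatability.csv`, `classification.json`,
`volume_correlation.csv` and `filter_comparison.csv`.

A CLI mirrors the library:

```sh
petrep simulate --out cohort --subjects 5 --group intertracer --seed 1
petrep extract --data cohort --out features.csv --filters all
petrep repeatability --features features.csv --out repeatability.csv --group intertracer
petrep report --data cohort --out results/
```

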