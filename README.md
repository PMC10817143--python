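# gwgcharts

Tools for building gestational-weight-gain (GWG) reference charts for
pregnant adolescents from multi-country longitudinal antenatal records.

Creating a GWG chart from routinely collected data requires far more than
curve fitting: visit records from different countries must be harmonized
and cleaned (eligibility rules, biologically implausible weight
trajectories), the sites must be shown to be poolable (standardized site
differences), the chronic lack of first-trimester weight measurements —
driven by late entry into prenatal care, a missing-not-at-random
mechanism — must be imputed, and only then can smooth centile curves be
estimated per pre-pregnancy BMI category. `gwgcharts` implements that
whole pipeline as a library, a CLI and a synthetic-cohort generator, so
every stage is testable without access to confidential patient data.

## The statistics inside

- **LMS z-scores.** Anthropometric classification uses the LMS method:
  a reference gives age-indexed curves L (Box-Cox power), M (median) and
  S (coefficient of variation), and `z = ((y/M)^L − 1)/(L·S)` (log limit
  as L → 0). WHO-style bands classify pre-pregnancy BMI-for-age
  (underweight < −2 SD; normal −2 to +1; overweight > +1 to ≤ +2; obesity
  > +2) and height-for-age < −2 SD defines stunting.
- **Eligibility and trajectory QC.** Completed age 10–19 at conception,
  visits in both the second (14–27 wk) and third (28–42 wk) trimesters,
  term birth (37–42 wk), birth weight 2,500–4,000 g, disease-free, not
  stunted, maximal cumulative GWG < 30 kg, complete analysis variables.
  Implausible weight records are flagged by an iterative repeated-median
  (Siegel) line fit: the largest-residual visit is removed when its
  residual exceeds 4 kg or an adjacent weight-change rate leaves
  [−1, +3] kg/week. Exclusions are accounted in a fixed-order flowchart
  ledger.
- **Standardized Site Differences (SSD).** Within each BMI-category ×
  gestational-age-bin cell (bins 0–7, 8–14, 15–21, 22–28, 29–35, 36–42
  weeks), `SSD = (site mean − pooled mean)/pooled SD`; |SSD| ≤ 0.5 is
  taken as homogeneity, with 0.2/0.5/0.8 the conventional
  small/acceptable/large magnitudes, and a sensitivity variant drops
  sites contributing < 10 records to a cell.
- **MNAR imputation with Rubin's rules.** Subjects with no weight in
  weeks 5–13 get a uniformly random week in that window and m = 5
  imputed weights from a normal-linear-model-with-bootstrap imputer
  ("norm.boot": least-squares coefficients and residual SD are taken
  from a bootstrap resample of the complete cases). Estimates are pooled
  as Q̄ with total variance `T = Ū + (1 + 1/m)·B`. A predictive-mean-
  matching imputer is available as a comparator.
- **BCCG/LMS centile curves.** GWG given gestational age is modelled
  with the Box-Cox Cole–Green distribution (μ, σ, ν curves on spline or
  polynomial bases), fitted by blockwise backfitting of the deviance,
  with GAIC(k) = deviance + k·edf for model selection and normalized
  quantile residuals, per-centile coverage, normality and
  homoscedasticity statistics as diagnostics. Because GWG may be
  negative, fitting uses a fixed +10 kg support shift, removed on
  output.

## Worked example

```python
from gwgcharts import (CohortConfig, generate_cohort, derive_subject_fields,
                       derive_visit_fields, apply_eligibility,
                       default_height_reference, default_bmi_reference,
                       compute_ssd, rubin_pool)

cfg = CohortConfig(n_sites=9, subjects_per_site=240, seed=1)
subjects, visits, truth = generate_cohort(cfg)
subjects = derive_subject_fields(subjects, default_height_reference(),
                                 default_bmi_reference())
visits = derive_visit_fields(visits, subjects)
subj, vis, ledger = apply_eligibility(subjects, visits)
print(ledger.to_text())
```

prints the flowchart accounting for the simulated nine-site cohort:

```
Initial: 2160 subjects, 16597 visits
  - age: removed 25 subjects, 190 visits
  - visit_coverage: removed 0 subjects, 0 visits
  - term_birth: removed 88 subjects, 598 visits
  - birth_weight: removed 87 subjects, 667 visits
  - diseases: removed 50 subjects, 395 visits
  - stunting: removed 83 subjects, 669 visits
  - gwg_ge_30: removed 0 subjects, 0 visits
  - implausible_trajectory: removed 2 subjects, 336 visits
  - completeness: removed 19 subjects, 146 visits
Final: 1806 subjects, 13596 visits
```

i.e. 1,806 of 2,160 simulated subjects survive cleaning with 13,596
weight records. The worked SSD example

```python
cells = compute_ssd({"A": [1, 2, 3], "B": [3, 4, 5]})
print([round(c.ssd, 4) for c in cells])   # [-0.7071, 0.7071]
```

standardizes two site means against the pooled mean 3 and pooled sample
SD √2 — both sites sit 0.71 SD from the pool, hence "heterogeneous"
under the ±0.5 rule. Rubin pooling of m = 3 estimates:

```python
est = rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
print(est.Qbar, round(est.T, 4))          # 2.0 2.3333
```

The full chain (simulate → clean → describe → SSD → impute →
fit-centiles, with a SHA-256 manifest of every artifact) runs as

```bash
gwgcharts run --seed 1 --out results/run1
```

## Layout

- `src/gwgcharts/synthetic.py` — multi-site cohort generator + ground truth
- `src/gwgcharts/reference.py` — LMS references, z-scores, classifications
- `src/gwgcharts/harmonize.py` — derived variables, trajectory QC, eligibility
- `src/gwgcharts/heterogeneity.py` — SSD, homogeneity rule, sensitivity
- `src/gwgcharts/imputation.py` — norm.boot / PMM imputers, Rubin pooling
- `src/gwgcharts/centiles.py` — BCCG distribution, backfitting, diagnostics
- `src/gwgcharts/report.py`, `pipeline.py`, `cli.py` — tables, orchestration
- `docs/methods.md` — modelling assumptions and numerical choices
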