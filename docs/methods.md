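# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `gwgcharts`, in the order the pipeline runs.

## Synthetic cohorts: what they emulate and what they do not

The generator (`synthetic.py`) produces the data structure the analysis
assumes: several sites (default 9) with 240 subjects each, small
site-level shifts in height (SD 1.5 cm) and in GWG at term (SD 0.5 kg),
a pre-pregnancy BMI-for-age mix of 1.5 / 71.8 / 21.4 / 5.3 % for
underweight / normal / overweight / obesity, visit schedules roughly
every 4 weeks, and integer gestational ages in completed weeks. The
default size (≈2,160 subjects, ≈16,500 records before cleaning, ≈7.5
records per subject) was chosen so that every downstream stage — down to
per-category centile fitting — has realistic sample sizes while a full
run completes in seconds; larger cohorts are one config field away.

**Trajectories.** Mean cumulative GWG per BMI category is a monotone
piecewise-quadratic in gestational week: near-flat through week 13
(0.05 kg/week, matching low observed early-pregnancy medians), then
`m(13) + 0.15·u + accel·u²` with `u = week − 13`, with the acceleration
set so the week-40 totals descend across categories (15 / 11 / 9 / 7 kg).
Most gain therefore falls in the third trimester, the pattern reported
for pregnant adolescents. Individual curves are the category mean times
a subject factor ~ N(1, 0.15) (truncated at 0.4), plus the site shift
ramped proportionally to week/40, plus visit-level noise N(0, 0.8 kg).
Negative early GWG arises naturally from the noise.

**MNAR missingness.** Each subject has a latent care-entry week drawn
from a distribution over weeks 2–20 whose mass beyond week 13 is 0.10.
Scheduled visits before the entry week never happened; a subject
entering at week ≤ 13 has their first visit at the entry week itself, so
exactly the late entrants (entry > 13) lack any week-5–13 weight. The
deletion depends only on the latent entry week, never on an observed
variable — genuinely missing not at random. Deleted rows and their
pre-deletion weights are kept as ground truth.

**Implausible records.** With probability 0.02 an interior visit weight
is shifted by ±10 kg, producing the isolated jumps the QC stage must
catch; injected indices are ground truth for sensitivity/false-positive
checks.

**What the generator does not emulate:** real covariate structure
(socio-economics, parity, smoking), measurement rounding heterogeneity
across sites, height growth during pregnancy, or non-ignorable
missingness in variables other than first-trimester weight. Passing
tests therefore demonstrate the correctness and calibration of the
*methods*, not properties of any real population.

**Bundled references.** The height-for-age and BMI-for-age tables in
`synthetic.py` are smooth synthetic stand-ins laid out like the WHO 2007
adolescent tables (ages 10–21 y, female); real WHO tables are a
user-supplied input file with the same `age, L, M, S` layout.

## Derived variables and cleaning

Conception is LMP + 14 days (or EDD − 266 days, or a known GA anchored
at a date); maternal age is completed years at conception. Age for
z-scoring is exact years (days/365.25); both months- and years-indexed
reference tables are supported, with ages outside the table an error,
never an extrapolation. L, M, S are interpolated linearly in age, the
convention of the LMS literature.

The eligibility filters run in a fixed order (age → trimester coverage →
term birth → birth weight → diseases → stunting → GWG ≥ 30 kg →
trajectory QC → completeness) so ledger counts are comparable across
runs. Interpretations that the source rules leave open, fixed here: the
GWG cap applies to the *maximal* observed cumulative GWG and is
inclusive at exactly 30.0 kg; trimester windows are 0–13 / 14–27 / 28–42
completed weeks (config); a subject who loses second/third-trimester
coverage through QC visit removal is removed at the QC step.

Trajectory QC codifies what is usually a manual graph inspection: an
iterative repeated-median (Siegel) line fit per subject, flagging the
largest-|residual| visit when the residual exceeds 4 kg or an adjacent
inter-visit rate leaves [−1, +3] kg/week, then refitting. The bounds
reflect that sustained gain above 3 kg/week or loss beyond 1 kg/week is
biologically implausible; 4 kg is roughly five visit-level noise SDs.
Duplicate (subject, week) records with discordant weights are all
flagged; with fewer than three distinct-age visits nothing is flagged.
On cohorts with ±10 kg injected jumps and ≤1 kg noise the rule attains
≥95 % sensitivity with ≤2 % false flags.

## Standardized Site Differences

The pooled SD in `SSD = (site mean − pooled mean)/pooled SD` is the
sample SD (n−1) of the *individual* observations in the cell, not the SD
of site means — the site mean is standardized against the pooled
distribution. This convention is explicit because sources often leave it
undefined; it is swappable only by editing one function. |SSD| ≤ 0.5 is
homogeneous; magnitude bands are half-open (|SSD| < 0.2 small, < 0.8
acceptable, ≥ 0.8 large). The sensitivity analysis drops sites with
`n_site < min_n` (default 10, strict less-than; descriptions of this
rule vary between "fewer than ten" and "n ≤ 10", which is why `min_n`
is a parameter) and recomputes pooled statistics from the remainder.
Height-for-age SSDs use completed-year age bins. Identities that hold by
construction and are tested: Σ n_site·SSD_site = 0 per cell, and scale
invariance.

## First-trimester imputation

Missing subjects (no visit in weeks 5–13) receive one uniformly random
integer week in 5–13, fixed per subject and shared by all m = 5
imputations (whether the week should be re-drawn per imputation is
undocumented in the sources this design follows; fixing it keeps the m
completed datasets comparable at the subject level). The imputed
quantity is the *weight* at that week; GWG is derived afterwards by the
same rule as observed visits.

The norm.boot imputer draws a bootstrap sample of complete cases, takes
OLS coefficients and the residual SD (denominator n − p) from it, and
simulates `X β* + N(0, σ*²)` — parameter uncertainty enters through the
bootstrap, not a posterior. Rank-deficient resamples are redrawn (max
100). The `iterations` knob (default 50) exists for interface fidelity
with chained-equations software but is a no-op for this univariate
single-block problem. Default predictors are the assigned/observed
first-trimester week and the subject's number of antenatal visits; a
subject identifier is *not* usable as a numeric covariate and is
excluded. Pre-pregnancy weight is excluded by default (the method is
defined as not using the subject's other weight information) but can be
added via `ImputationSpec.predictors` — note that without any
subject-level weight anchor the imputed weights carry the full
between-subject weight variance, so derived GWG values are wide; with
pre-pregnancy weight added, imputed GWG stays inside the observed
first-trimester envelope. Both behaviours are tested. Imputation runs
only for the toggled categories (default: underweight and overweight,
the sparse ones); a toggled category with no complete cases is an error
at the library level and a logged skip in the orchestrated pipeline.

Rubin's rules: Q̄ = mean(Q), Ū = mean(U), B = sample variance of Q,
T = Ū + (1 + 1/m)·B, df = (m−1)(1 + Ū/((1+1/m)B))², infinite at B = 0.

## BCCG centile fitting

The response distribution is BCCG (Box-Cox Cole–Green), the three-
parameter family underlying the LMS chart method; the choice of family
is an assumption (the four-parameter BCT/BCPE extensions are out of
scope). The density is used untruncated, as in standard growth-chart
practice — the truncation mass Φ(−1/(σ|ν|)) is negligible at fitted σ.
GWG can be negative, so a fixed support shift (default +10 kg, recorded
in the model, config) is added before fitting and removed on output;
records at or below −shift cannot enter a fit and are dropped with a
logged count by the pipeline.

Parameter curves use log links for μ and σ (positivity) and identity
for ν, on constant/linear/polynomial/cubic-B-spline bases over the
observed week range (default: B-spline df 4 for μ, linear σ, constant
ν). Fitting is blockwise backfitting: BFGS on one curve's coefficients
at a time, accepting a block update only if the penalized deviance
decreases, cycling until the relative deviance change is below 1e-6 or
200 cycles (then the best iterate is returned with `converged_ =
False`). Initialization — ν = 1, μ from a running mean, σ from a
running CV — matters for distributional regression and is therefore
fixed and documented. edf is the coefficient count (the optional
second-difference ridge penalty defaults to 0); GAIC(k) = deviance +
k·edf, with GAIC(2) ≡ AIC, and df selection over a small grid (3, 4, 5,
6) at k = 3 when requested. Evaluation outside the training week range
clips to the range rather than extrapolating.

Diagnostics: normalized quantile residuals (exactly the Box-Cox z under
this family), per-centile empirical coverage, Shapiro–Wilk on the
residuals (subsampled at 4,999 for large n), and the |residual|-vs-week
Pearson correlation as a homoscedasticity check. Centile curves cannot
cross by construction (monotone in the normal quantile).

For the m completed datasets, the chart is fitted per dataset and the
(μ, σ, ν) curves averaged pointwise — Rubin-style pooling applied to
curves; per-dataset fits are reported alongside.

## Reporting and reproducibility

Descriptive tables use linear-interpolation quantiles (stated in each
table footer); "third-trimester weight" is the last observed weight at
weeks 28–42, switchable to the maximum. The orchestrated run writes
only delimited text plus a JSON manifest of SHA-256 hashes, and every
random draw descends from the single config seed, so identical
config + seed gives byte-identical manifests.

## Known limitations

- The default-predictor imputation yields wide GWG draws (above); this
  is a faithful property of the method definition, not a bug.
- SSD verdicts in very small cells are noisy; the sensitivity filter is
  the intended remedy, and homogeneity shares should be read from the
  filtered table.
- The BCCG fitter uses numerical gradients; at a few thousand
  observations and single-digit dfs this is seconds per fit, but it is
  not built for df ≫ 10 smooths.
- ν is fitted as a constant by default; strongly week-varying skewness
  would require a richer ν basis (supported but untested at scale).
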