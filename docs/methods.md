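# Methods notes

This note records the statistical models, the defaults and the design
decisions behind them, in the order the pipeline runs.

## Analyte catalog and ratio registry

The registry (`data/steroid_catalog.tsv`) is a declarative text file rather
than code so that panel membership can be audited line by line. It carries
81 analytes (46 unconjugated, 35 conjugated) with their reporting units
(pM/nM/µM) and ~190 named molar ratios grouped into 15 enzyme panels.
Conventions:

* A ratio is Σ numerator / Σ denominator evaluated **per subject** on the
  common nM scale — never a ratio of group summaries. Mixed units cancel by
  construction, and evaluation is invariant to the unit each analyte is
  declared in.
* Ratio names ending in ", C" replace every constituent that has a measured
  conjugated counterpart by that conjugate; constituents without a measured
  conjugate (e.g. progesterone, androstenedione, testosterone) stay free.
* "3α/β" shorthand expands to both epimers as a summed term.
* A missing constituent or a zero denominator makes the ratio missing for
  that subject (warning, no exception, no imputation — there is no
  defensible imputation rule for censored steroid panels).
* Two source-level ambiguities are carried explicitly and flagged in the
  `note` column: the conjugated epipregnanolone entry (printed under the
  same abbreviation as conjugated pregnanolone) is keyed separately, and two
  ratios naming an unmeasured free epietiocholanolone use the conjugate
  instead. One ratio row of the CYP17A1 hydroxylase+lyase panel is printed
  with no label at all in the source table and cannot be encoded; that panel
  therefore carries 22 ratios.
* Printed group medians of ratios are medians **of** per-subject ratios;
  they need not equal ratios of group medians, so display scales in the
  registry affect presentation only.

## Power transformation

Concentrations and ratios are positive and right-skewed; each variable is
Box-Cox transformed, y = (x^λ − 1)/λ with λ = 0 meaning log, an optional
additive shift rescuing non-positive inputs. λ is chosen by exhaustive grid
search on [−3, 3] in steps of 0.01 (deterministic, reproducible) maximizing
a normality criterion of the transformed values: Shapiro–Wilk W for n ≤ 50
and the negated Anderson–Darling statistic for larger samples, where W
saturates. The transform is fitted on patients and controls pooled — fitting
per group would build the group difference into the scale being tested.
After transformation, variables are standardized to mean 0, sd 1 (the input
contract of the discriminant model). The transform is monotone for every λ,
so rank-based statistics are unaffected; the inverse map is exact to 1e-9
relative, which the tests exercise.

Identifiability caveat: for data that are already Gaussian with a small
coefficient of variation, the criterion is nearly flat in λ and the argmax
is noisy; the recovery tests therefore use samples with appreciable relative
spread and summarize over replicates.

## Univariate screen

Per variable, a main-effects linear model with factors status
(patient/control) and age dichotomized at 38 years (the cohort median; the
cut absorbs the age dependence of many steroids without spending degrees of
freedom on a slope). The status sum of squares is the Type-III drop-one SS,
valid for unbalanced designs; η²ₚ = SS_MS/(SS_MS + SS_res). No interaction
term is fitted. If one age level is empty the model degrades to a one-way
ANOVA with a warning. Severity correlations (EDSS, T25FWT, HPT9_R, HPT9_L)
are Pearson on the transformed (Gaussianized) scale, patients only, with a
Spearman switch; fewer than 5 complete pairs yields a flagged missing
result.

Significance for direction coding is two-sided α = 0.05 with **no**
multiplicity correction — deliberately: the per-variable codes are not the
inference, the panel-level trend statistic below is.

## Trend meta-statistic

For a panel of results coded +1/0/−1, the one-sample Wilcoxon signed-rank
test with:

* **Pratt zeros** — zeros are ranked with everything else (they occupy the
  lowest ranks), then dropped from the rank sums;
* **Cureton variance** — σ² loses m(m+1)(2m+1)/24 for the zero block and
  Σ(t³−t)/48 over tie groups of the non-zero magnitudes (a single group of
  size k for code vectors);
* **continuity correction** — |W⁺ − μ| reduced by ½ before standardization,
  z clamped to 0 when |W⁺ − μ| ≤ ½;
* two-sided normal approximation.

This exact recipe is pinned by the published triplet→p pairs the acceptance
suite asserts; in particular (0/4/3) → 0.102 discriminates Pratt ranking
from dropping zeros before ranking (which gives 0.149). The closed form for
triplets is proven against the general signed-rank routine on expanded code
vectors over an exhaustive grid (u, d ≤ 25, m ≤ 70). An exact
sign-permutation mode (binomial for a single tie group, full enumeration for
k ≤ 20 in the general routine) exists behind a flag for methodological
comparison only — the published values match the normal approximation even
at k = 2, so that is the default everywhere.

The statistic treats the panel's codes as exchangeable; strongly correlated
variables in a panel effectively shrink the number of independent codes.
The full-pipeline null calibration (below) shows the panel-level false
positive rate staying below nominal under the generator's correlated
blocks, because the discreteness of small triplets dominates.

## OPLS discriminant model

One predictive plus one orthogonal component (fixed; requesting more is an
error): w ∝ Xᵀy_c; the orthogonal weight is the part of the X-loading not
collinear with w; the orthogonal score/loading pair is deflated from X and
the predictive component refitted on the filtered matrix. The response is
the ±1 group code, centered (which handles the 25/15 imbalance); the
predictive direction is oriented so patients score positive.

Two structural facts the tests rely on:

* the predictive **weight** equals the one-component PLS weight exactly
  (the orthogonal score is uncorrelated with the centered response by
  construction), so OPLS does not change *which* linear combination is
  predictive — it cleans the predictive **score** T_p of within-pathway
  variation, improving fit, cross-validation and score-plot diagnostics;
* the fitted model collapses to multiple regression: llr = Xb + b₀
  reproduces the per-subject predictions to 1e-8, which is the bridge to
  the "regression coefficient" column of the model summary.

The response equation is y = T_p c + f with a scalar response loading c
estimated by least squares on the predictive score (the standard OPLS
response equation; a source formulation reusing the X-side loading in the
response equation is a notational slip and is not implemented).

**LLR link.** The linear prediction ŷ is mapped to a log-likelihood ratio by
a one-dimensional equal-variance Gaussian discriminant on ŷ:
llr = (μ̂₁ − μ̂₀)/s² · (ŷ − (μ̂₁ + μ̂₀)/2), so the training decision point maps
to llr 0 and probability = e^llr/(1 + e^llr); a subject is labelled a
patient iff probability > 0.5. No prior-odds term is added — the decision
point, not the prevalence, anchors zero.

**VIP.** With one predictive component and unit-norm weights,
VIP_j = √p·|w_j|, hence mean VIP² = 1 identically. Selection drops
variables with VIP < 1.0 (configurable) and refits **once**; re-applying
the cut after refitting would shave the panel indefinitely because VIPs are
renormalized on every fit, so a second round is the permitted maximum.

**Homogeneity.** Hotelling's T² on the (T_p, T_o) score pair against the
F-ellipse at level 0.95; the pipeline removes flagged subjects and refits,
at most twice. Level 1 disables flagging.

**Cross-validation.** Venetian-blind folds (subject i in fold i mod 7 by
default; deterministic). Q²·100 = 100(1 − PRESS/SS_tot). If a training
split would lose a class, one deterministic reshuffle (fixed permutation) is
attempted, then it is an error. Explained variability is reported as
fit % and cross-validated %; the optimism inequality (CV ≤ fit) is asserted
per run in the tests.

**Operating characteristics.** In-sample sensitivity/specificity after
outlier removal, with 95% Wald intervals p̂ ± 1.96·√(p̂(1−p̂)/n) clipped to
[0, 1]. Wald (not Wilson/exact) is deliberate: it is the arithmetic behind
the reference values the package reproduces (e.g. 0.875 on 24 subjects →
lower bound 0.743).

**Model summary export.** Per variable: loading expressed as the correlation
with the predictive score (bounded in [−1, 1]), a jackknife t statistic of
that loading over the CV folds (the estimator behind published loading
t-statistics is unstated; jackknife over folds is the choice here, flagged),
the llr-scale regression coefficient, and the VIP.

## Synthetic cohorts

What the generator emulates, and what it does not:

* **Marginals**: log-normal, spread sd_log = 0.6 on the log scale (quartile
  ratio ≈ 2.2, matching the order of spread of printed steroid quartiles).
  Baseline medians are tied to the declared unit (150 pM / 5 nM / 1 µM)
  rather than transcribed per analyte — levels are realistic in magnitude
  but not analyte-faithful.
* **Dependence**: one latent factor per steroid class with within-block
  correlation ρ = 0.5 (steroids of a shared pathway are strongly
  correlated in real panels); conjugates are parent × 50 × exp(N(0, 0.3)),
  so conjugate/free ratios have realistic noise; half the analytes get an
  age slope of ±0.15 log-units/decade.
* **Design**: 25 patients / 15 controls, ages ≈ 39 (32, 49).
* **Effects**: by default 5 conjugates shifted up and 15 free steroids down
  by 1·sd_log in patients — the aggregate pattern the pipeline is meant to
  detect. Explicit per-analyte effect maps override this.
* **Severity**: one latent severity per patient drives EDSS (0–7 in 0.5
  steps), T25FWT and both peg tests log-normally, and leaks (γ = 0.4) into
  the down-shifted analytes, centered so group means are untouched.

Not emulated: assay censoring/limits of detection, batch effects,
menstrual-phase or diurnal variation, non-log-normal tails, and real
per-analyte covariance beyond the class blocks. Passing tests on these
simulations therefore validate the statistical machinery, not any clinical
claim about real cohorts.

Determinism: one integer seed drives everything; the same seed yields
byte-identical CSVs.

## Problem sizes and numerical choices

The test suite and calibration studies run the default cohort (n = 40,
81 analytes + 192 ratios); calibration loops use 100–200 replicates and a
coarsened λ grid (step 0.5), since λ enters those checks only through the
monotone transform. Final analyses use the full 0.01 grid. Tolerances:
score orthogonality 1e-8, coefficient/prediction identity 1e-8, transform
round trip 1e-9 relative, VIP normalization 1e-9, exact oracle equivalences
1e-12. Ties in the λ grid resolve to the smallest maximizing λ (first hit
in ascending grid order). Degenerate inputs (constant variables, empty
groups, all-zero code vectors, zero denominators) raise informative errors
or produce flagged missing values as documented per function.

## Known limitations

* The cohort-derived quantities of the original study (fitted loadings,
  medians, η²ₚ, explained variabilities, sensitivities) are not
  reproducible — the underlying data are not deposited — so the
  multivariate machinery is validated by property-based simulation instead.
* The trend statistic's normal approximation is used down to k = 2 non-zero
  codes for fidelity with the published values; the exact mode exists for
  comparison.
* LLR calibration assumes the predictive score is roughly Gaussian with
  equal variance in both groups; for heavily separable data the scale
  parameter is clipped rather than infinite.
* A second VIP elimination round is supported but not default; iterating to
  convergence is deliberately not offered.
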