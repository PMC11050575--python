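# Methods

This note documents the statistical procedures, the modelling assumptions
behind the synthetic cohort generator, and the numerical and design
choices made where conventions genuinely diverge.

## The evaluation problem

A binary phenotypic screen (extracardiac-anomaly status) is evaluated
against a binary outcome (genetic diagnosis identified) in a cohort of
infants with congenital heart disease. After complete-case restriction to
records with non-missing screen and outcome, every quantity in the package
is a function of the 2x2 table (TP, FP, FN, TN), N = TP+FP+FN+TN.

### Screening metric family

Se = TP/(TP+FN), Sp = TN/(TN+FP), accuracy = (TP+TN)/N,
PPV = TP/(TP+FP), NPV = TN/(TN+FN). Derived indices:

- Youden *J* = Se + Sp − 1; number needed to diagnose NND = 1/*J*
  (infinite, with a warning, when *J* ≤ 0).
- Predictive summary index PSI = PPV + NPV − 1 (equivalently PPV minus the
  false-omission rate 1 − NPV); number needed to predict NNP = 1/PSI.
- Clinical utility indices CUI₊ = Se·PPV, CUI₋ = Sp·NPV; summary utility
  index SUI = CUI₊ + CUI₋.

All values are carried at full precision; reports round proportions to 4
decimals and NND/NNP to 2, matching the usual clinical-table presentation.
A metric with a zero denominator is reported as *undefined*, never as
zero, and undefined-ness propagates to its derivatives.

CUI grading uses the published qualitative convention ≥0.81 excellent,
≥0.64 good, ≥0.49 adequate, ≥0.36 poor, <0.36 very poor; the cutpoints
are overridable.

### Association statistics

- **Odds ratio**: cross-product with Woolf log-scale standard error
  √(1/a+1/b+1/c+1/d) and 95% CI using z = 1.959964. A zero cell requires
  the Haldane–Anscombe +0.5 correction (applied to every cell, flagged in
  the result). The plain Woolf form with no correction reproduces all the
  printed study intervals.
- **Pearson χ²**: no Yates continuity correction by default (toggleable);
  the minimum expected cell is reported so callers can fall back to the
  exact test.
- **Fisher exact**: hypergeometric; the two-sided p sums probabilities of
  all tables with the observed margins no more probable than the observed
  one (the "small-p" rule, the most common convention; for sparse rows the
  one-sided and small-p two-sided values coincide).
- **Cochran–Armitage trend**: Z = Σsᵢ(xᵢ − nᵢp̄) / √(p̄(1−p̄)[Σnᵢsᵢ² −
  (Σnᵢsᵢ)²/N]) with default equally spaced scores 0, 1, 2 and no
  continuity correction; one-sided p from the directed normal tail. With
  two groups Z² equals the uncorrected 1-df Pearson χ², which the tests
  assert.
- **Binary-predictor logistic fit**: the saturated model has the closed
  form intercept = logit(FN/(FN+TN)), slope = log OR; Wald χ² =
  (slope/SE)² with the Woolf SE. For a single binary predictor the ROC
  curve has one interior point, so AUC = (Se+Sp)/2, and the Brier score
  reduces to [n₊·PPV(1−PPV) + n₋·NPV(1−NPV)]/N. The closed form is
  cross-checked in the test suite against an iterative maximum-likelihood
  fit (statsmodels) to 1e−6 and against a pairwise rank-statistic AUC
  oracle.
- **Anomaly-type scan**: one row per organ/system label — prevalence,
  diagnosed fraction among exposed, Fisher exact p (exposed vs all
  unexposed), and an odds ratio estimated only for significant rows
  (default α = 0.05). Raw p-values are reported without multiple-testing
  adjustment, matching the source presentation; callers can adjust
  downstream.

### Tetrachoric correlation

The tetrachoric model treats both dichotomies as thresholded coordinates
of a standard bivariate normal. Thresholds are the normal quantiles of the
marginal negative proportions; ρ is the root of
Φ₂(τ_row, τ_col; ρ) = TN/N, which for a 2x2 table coincides with maximum
likelihood. Numerics:

- Φ₂ is computed by reducing to a one-dimensional integral
  ∫_{−∞}^{h} φ(x)Φ((k−ρx)/√(1−ρ²)) dx with adaptive quadrature
  (absolute accuracy ~1e−12; validated against a brute-force double
  integral to 1e−8 and the arcsine closed form at zero thresholds).
- Root-finding by Brent's method on (−0.999, 0.999); a root outside the
  bracket returns the clamped bound with `converged=False` and a warning
  rather than ±1.
- A zero cell triggers the +0.5 correction (flagged); a zero margin is an
  error (ρ unidentified).
- Strength bands: the published edges (±0.3–0.5 fair, ±0.6–0.7 moderate,
  >±0.8 very strong) leave gaps; this package uses the half-open
  intervals [0.3, 0.6) fair, [0.6, 0.8) moderate, [0.8, 1] very strong,
  [0, 0.3) negligible as its documented interpretation.

The anomaly-type × CHD-class matrix estimates one ρ per pair from the
(type present) × (class membership) table, optionally restricted to
diagnosed patients; cells that fail (zero margin, non-convergence) carry a
missing value with the reason.

### Decision curve analysis

Net benefit at risk threshold R weighs true against false positives at
the exchange rate R/(1−R), in the count-fraction convention of the
decision-curve literature:

    NB_model(R) = TP/N − [R/(1−R)]·FP/N
    NB_all(R)   = P − [R/(1−R)]·(1−P),   NB_none(R) = 0.

(The symbolic form "TPR·P − [R/(1−R)]·FPR·(1−P)" is equivalent when TPR
and FPR are read as case-conditional rates multiplied by P and 1−P; only
the count-fraction reading reproduces the observed crossing behaviour, so
it is adopted and stated here rather than silently resolved.)

Setting NB_model = NB_all gives R/(1−R) = FN/TN, i.e. an exact crossing at
R\* = FN/(FN+TN) = 1 − NPV — the residual outcome risk among
screen-negatives. Test-All dominates below R\*, the screen-guided strategy
above; with FN = 0 the screen weakly dominates everywhere and no crossing
is reported. The default grid is 1% steps over (0, 0.50], which is why a
grid-read crossing lands on the nearest percent (14%) while the exact
value (13.4%) is always reported alongside. No smoothing or confidence
bands are applied.

## Synthetic cohort generator

The generator produces patient-level records whose aggregate structure
matches the published cohort tables; it exists so that every pipeline
stage can run and be validated by parameter recovery. Defaults:

- n = 1013; CHD class frequencies, period sizes (313/549/151), sex, age
  group, race/ethnicity and maternal-diabetes rates from the published
  cohort description.
- Outcome: P(diagnosis | screen+) = 0.383 in every period; among
  screen-negatives the per-period rates 0.077/0.156/0.197 (implying a
  marginal ~0.138 and a generating odds ratio of ~3.9).
- Anomaly-type flags: a 26-dimensional latent Gaussian dichotomized at the
  quantiles of the per-type prevalences, so each type's marginal is exact
  in expectation and the pairwise tetrachoric correlation of the flags
  equals the configured latent correlation. The default latent correlation
  is exchangeable at ρ = 0.6: anomalies co-occur in syndromic patients,
  and this value yields ~2.9 types per structurally affected patient with
  an any-type rate of ~0.27, below the screen-positive targets of nearly
  every class. `class_type_shift` adds class-specific enrichment (e.g.
  spleen anomalies in heterotaxy) by shifting the latent mean of one type
  within one class.
- Screen status is true iff ≥1 type flag is present, then topped up by a
  residual "functional anomaly" channel (status positive with no listed
  structural type) whose per-class probability is calibrated against the
  empirical structural rate of the generated sample, so class-conditional
  screen-positive rates converge to the published per-class targets. A
  class whose target lies *below* the structural floor (only APVR at the
  defaults) cannot be calibrated downward; it is logged and left at the
  floor. This additive-only calibration is a deliberate trade-off that
  preserves the exact type marginals and the status-implies-types-or-
  functional invariant.
- Determinism: a single integer seed feeds named substreams (one per
  field, in fixed order) via `numpy.random.SeedSequence.spawn`, so the
  same seed reproduces the cohort bitwise and adding new fields later
  cannot perturb existing draws.

What the generator does **not** emulate: real anomaly co-occurrence is not
exchangeable, outcome risk varies by CHD class and anomaly type (here it
depends only on screen status and period), and no mortality, test
modality, or individual ages beyond group labels are modelled. Passing
parameter-recovery tests therefore demonstrates the correctness of the
estimators under the stated generative model, not the clinical claims
themselves.

The printed aggregate tables (screening 2x2, the 26 anomaly rows, the
period-trend strata) ship as small CSV fixtures with a registry
(`fixture_table`), so the headline analyses can be recomputed without any
synthetic data. The joint distribution across anomaly rows is not
identified by the marginals, so the per-row tables are analysed as
separate 2x2s, exactly as their source does.

## Problem sizes

Law-of-large-numbers and parameter-recovery checks use cohorts of
10⁵ records (conditional rates within 3 binomial standard errors) and
6×10⁴ for latent-correlation recovery; the headline reproductions are
exact count computations at the study size of 1013 and run in
milliseconds.

## Known limitations

- Tetrachoric standard errors are not computed (none are reported in the
  source presentation); only point estimates with convergence flags.
- The bootstrap hooks for predictive-value confidence intervals and
  decision-curve bands are intentionally absent from the default surface.
- The anomaly scan treats each type marginally; co-occurring types are
  not jointly modelled.
- Kruskal–Wallis is provided as a generic utility for continuous
  covariates but is exercised only on synthetic data.
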