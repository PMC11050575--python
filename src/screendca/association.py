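"""Association and trend statistics for cohort contingency data.

Covers the odds ratio with Woolf (log-scale normal) confidence intervals,
Pearson chi-squared and Fisher exact tests, the Cochran-Armitage trend test
for ordered binomial groups, the closed-form binary-predictor logistic fit
(with Wald chi-squared, AUC and Brier score), the organ/system-specific
anomaly association scan, and a generic Kruskal-Wallis utility.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .cohort import (
    Cohort,
    CohortError,
    ContingencyTable,
    ECA_TYPES,
    TrendTable,
    TwoByTwoTable,
    complete_case,
)

#: 97.5% standard-normal quantile used for all 95% confidence intervals.
Z_975 = 1.959964


@dataclass(frozen=True)
class OREstimate:
    """Odds ratio with Woolf standard error and 95% CI on the log scale."""

    or_value: float
    log_or: float
    se_log_or: float
    ci95: tuple[float, float]
    method: str  # "woolf" or "haldane_corrected"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    sidedness: str  # "one" or "two"
    method: str
    df: Optional[int] = None
    min_expected: Optional[float] = None


@dataclass(frozen=True)
class BinaryModelFit:
    """Saturated logistic fit of outcome on a single binary predictor.

    ``intercept`` is the log-odds of the outcome among screen-negatives and
    ``slope`` the log odds ratio.  For a binary predictor the ROC has a
    single interior operating point, so AUC = (Se + Sp)/2, and the Brier
    score has the closed form [n+ PPV(1-PPV) + n- NPV(1-NPV)] / n.
    """

    intercept: float
    slope: float
    se_slope: float
    wald_chi2: float
    wald_p: float
    auc: float
    brier: float


@dataclass(frozen=True)
class EcaScanRow:
    """One anomaly label in the association scan."""

    label: str
    n_exposed: int
    n_total: int
    n_exposed_diagnosed: int
    exact_p: float
    significant: bool
    or_estimate: Optional[OREstimate]

    @property
    def prevalence(self) -> float:
        return self.n_exposed / self.n_total

    @property
    def diagnosed_fraction(self) -> Optional[float]:
        return self.n_exposed_diagnosed / self.n_exposed if self.n_exposed else None


def odds_ratio(table: TwoByTwoTable, correction: bool = False) -> OREstimate:
    """Cross-product odds ratio with Woolf 95% CI.

    With ``correction`` the Haldane-Anscombe 0.5 is added to every cell
    before all computations, which is required when any cell is zero.
    """
    a, b, c, d = (float(x) for x in table.cells())
    if correction:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        method = "haldane_corrected"
    else:
        if min(a, b, c, d) == 0:
            raise CohortError(
                "zero cell in 2x2 table; use correction=True (Haldane-Anscombe)"
            )
        method = "woolf"
    or_value = (a * d) / (b * c)
    log_or = math.log(or_value)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (math.exp(log_or - Z_975 * se), math.exp(log_or + Z_975 * se))
    return OREstimate(or_value, log_or, se, ci, method)


def pearson_chi2(table: ContingencyTable | TwoByTwoTable, correction: bool = False) -> TestResult:
    """Pearson chi-squared test of independence (no Yates correction by default)."""
    counts = table.as_array() if isinstance(table, TwoByTwoTable) else table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise CohortError("chi-squared needs at least a 2x2 table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise CohortError("zero margin in contingency table")
    res = sps.chi2_contingency(counts, correction=correction)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sidedness="two",
        method="pearson_chi2" + ("_yates" if correction else ""),
        df=int(res.dof),
        min_expected=float(np.min(res.expected_freq)),
    )


def fisher_exact(
    table: TwoByTwoTable, sidedness: str = "two", direction: str = "increasing"
) -> TestResult:
    """Fisher exact test on a 2x2 table.

    Two-sided p sums the probabilities of all tables (with the observed
    margins) no more probable than the observed one; one-sided p is the
    hypergeometric tail in ``direction`` ("increasing": positive
    association, odds ratio > 1).
    """
    counts = table.as_array()
    if sidedness == "two":
        alternative = "two-sided"
    elif sidedness == "one":
        alternative = "greater" if direction == "increasing" else "less"
    else:
        raise ValueError(f"sidedness must be 'one' or 'two', got {sidedness!r}")
    res = sps.fisher_exact(counts, alternative=alternative)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        sidedness=sidedness,
        method=f"fisher_exact_{alternative}",
    )


def cochran_armitage(
    trend: TrendTable, sidedness: str = "one", direction: str = "increasing"
) -> TestResult:
    """Cochran-Armitage test for trend in binomial proportions.

    Z = sum_i s_i (x_i - n_i pbar) / sqrt(pbar (1-pbar) [sum n_i s_i^2 -
    (sum n_i s_i)^2 / N]) with pbar the pooled success rate; no continuity
    correction.  One-sided p is the upper normal tail for an increasing
    trend (lower tail for decreasing).
    """
    ns = np.asarray(trend.ns, dtype=float)
    xs = np.asarray(trend.xs, dtype=float)
    s = np.asarray(trend.scores, dtype=float)
    N = ns.sum()
    pbar = xs.sum() / N
    if pbar in (0.0, 1.0):
        warnings.warn(
            "all successes or all failures: trend statistic degenerate", stacklevel=2
        )
        return TestResult(0.0, 1.0, sidedness, "cochran_armitage")
    num = float(np.sum(s * (xs - ns * pbar)))
    var = pbar * (1 - pbar) * (np.sum(ns * s**2) - np.sum(ns * s) ** 2 / N)
    z = num / math.sqrt(var)
    if sidedness == "two":
        p = 2.0 * sps.norm.sf(abs(z))
    elif direction == "increasing":
        p = float(sps.norm.sf(z))
    else:
        p = float(sps.norm.cdf(z))
    return TestResult(z, min(p, 1.0), sidedness, "cochran_armitage")


def binary_logistic(table: TwoByTwoTable) -> BinaryModelFit:
    """Closed-form logistic regression of outcome on the binary screen.

    The saturated fit has intercept logit(FN/(FN+TN)) and slope equal to
    the log odds ratio; the Wald chi-squared is (slope / Woolf SE)^2.
    Requires all cells positive (a zero cell is complete/quasi separation).
    """
    if min(table.cells()) == 0:
        raise CohortError("zero cell: logistic fit is separated")
    ore = odds_ratio(table)
    intercept = math.log(table.fn / table.tn)
    slope = ore.log_or
    wald = (slope / ore.se_log_or) ** 2
    wald_p = float(sps.chi2.sf(wald, df=1))
    se = table.tp / table.n_outcome_pos
    sp = table.tn / table.n_outcome_neg
    ppv = table.tp / table.n_screen_pos
    npv = table.tn / table.n_screen_neg
    auc = (se + sp) / 2.0
    brier = (
        table.n_screen_pos * ppv * (1 - ppv) + table.n_screen_neg * npv * (1 - npv)
    ) / table.n
    return BinaryModelFit(intercept, slope, ore.se_log_or, wald, wald_p, auc, brier)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank test across >=2 groups of continuous values."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    stat, p = sps.kruskal(*groups)
    return TestResult(float(stat), float(p), "two", "kruskal_wallis", df=len(groups) - 1)


def scan_row_from_counts(
    label: str,
    n_exposed: int,
    n_exposed_diagnosed: int,
    n_total: int,
    n_diagnosed: int,
    alpha: float = 0.05,
) -> EcaScanRow:
    """Association of one anomaly label with the outcome from marginal counts.

    Builds the exposed-vs-unexposed 2x2, applies the Fisher exact test and
    estimates the odds ratio only when p < alpha (Haldane-corrected when a
    cell is zero).
    """
    a = n_exposed_diagnosed
    b = n_exposed - n_exposed_diagnosed
    c = n_diagnosed - n_exposed_diagnosed
    d = (n_total - n_exposed) - c
    if n_exposed == 0:
        return EcaScanRow(label, 0, n_total, 0, 1.0, False, None)
    t = TwoByTwoTable(a, b, c, d)
    p = fisher_exact(t, sidedness="two").p_value
    significant = p < alpha
    ore = None
    if significant:
        ore = odds_ratio(t, correction=min(t.cells()) == 0)
    return EcaScanRow(label, n_exposed, n_total, n_exposed_diagnosed, p, significant, ore)


def eca_scan(
    cohort: Cohort,
    alpha: float = 0.05,
    labels: Sequence[str] = ECA_TYPES,
    outcome: str = "diagnosis_identified",
) -> list[EcaScanRow]:
    """Per-anomaly-type association scan across a patient-level cohort.

    For each label: prevalence, diagnosed fraction among exposed, Fisher
    exact p comparing exposed vs all unexposed, and an odds ratio only for
    significant associations.  Raw p-values are reported without
    multiple-testing adjustment (an adjustment column is a caller add-on).
    """
    sub = complete_case(cohort, [outcome])
    n_total = len(sub)
    out = [bool(getattr(r, outcome)) for r in sub]
    n_diagnosed = sum(out)
    rows = []
    for label in labels:
        exposed = [label in r.eca_types for r in sub]
        n_exp = sum(exposed)
        n_exp_dx = sum(1 for e, o in zip(exposed, out) if e and o)
        rows.append(
            scan_row_from_counts(label, n_exp, n_exp_dx, n_total, n_diagnosed, alpha)
        )
    return rows


def scan_to_records(rows: Sequence[EcaScanRow]) -> list[dict]:
    """Flatten scan rows for tabular export."""
    recs = []
    for r in rows:
        recs.append(
            {
                "label": r.label,
                "n_exposed": r.n_exposed,
                "n_total": r.n_total,
                "n_exposed_diagnosed": r.n_exposed_diagnosed,
                "prevalence": r.prevalence,
                "diagnosed_fraction": r.diagnosed_fraction,
                "exact_p": r.exact_p,
                "significant": r.significant,
                "odds_ratio": r.or_estimate.or_value if r.or_estimate else None,
                "ci95_lower": r.or_estimate.ci95[0] if r.or_estimate else None,
                "ci95_upper": r.or_estimate.ci95[1] if r.or_estimate else None,
            }
        )
    return recs
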