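"""Model objects for evaluating a binary phenotypic screen.

:class:`ScreeningModel` is constructed from a patient-level cohort, a data
frame, or directly from a 2x2 count table; :meth:`ScreeningModel.fit`
returns a :class:`ScreeningResults` carrying the screening metric family,
the binary-predictor logistic equivalents (odds ratio, Wald chi-squared,
AUC, Brier score) and the three-strategy decision curve, with a
``summary()`` report.

Example
-------
>>> from screendca import ScreeningModel, TwoByTwoTable
>>> res = ScreeningModel(TwoByTwoTable(166, 267, 78, 502)).fit()
>>> round(res.metrics.sensitivity, 4)
0.6803
>>> round(res.crossing_threshold, 3)
0.134
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from . import __version__ as _pkg_version
from .association import BinaryModelFit, OREstimate, binary_logistic, odds_ratio, pearson_chi2
from .cohort import Cohort, TwoByTwoTable, complete_case, crosstab2x2
from .dca import DEFAULT_GRID, NetBenefitCurve, crossing_threshold, decision_curve
from .metrics import ScreenMetrics, screen_metrics


class ScreeningModel:
    """Evaluation of a binary screen against a binary outcome.

    Parameters
    ----------
    table : TwoByTwoTable
        Screen x outcome counts (rows screen +/-, columns outcome +/-).
    """

    def __init__(self, table: TwoByTwoTable):
        self.table = table
        self.n_dropped: Optional[int] = None

    @classmethod
    def from_cohort(
        cls,
        cohort: Cohort,
        screen: str = "eca_status",
        outcome: str = "diagnosis_identified",
    ) -> "ScreeningModel":
        """Complete-case filter a cohort, then tabulate screen x outcome."""
        sub = complete_case(cohort, [screen, outcome])
        model = cls(crosstab2x2(sub, screen, outcome))
        model.n_dropped = len(cohort) - len(sub)
        return model

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, screen: str, outcome: str
    ) -> "ScreeningModel":
        """Build from a data frame with two boolean-like columns."""
        sub = df[[screen, outcome]].dropna()
        s = sub[screen].astype(bool)
        o = sub[outcome].astype(bool)
        model = cls(
            TwoByTwoTable(
                tp=int((s & o).sum()),
                fp=int((s & ~o).sum()),
                fn=int((~s & o).sum()),
                tn=int((~s & ~o).sum()),
            )
        )
        model.n_dropped = len(df) - len(sub)
        return model

    def fit(self, threshold_grid: Sequence[float] = DEFAULT_GRID) -> "ScreeningResults":
        """Compute metrics, association estimates and the decision curve."""
        t = self.table
        has_all_cells = min(t.cells()) > 0
        return ScreeningResults(
            table=t,
            metrics=screen_metrics(t),
            or_estimate=odds_ratio(t, correction=not has_all_cells),
            model_fit=binary_logistic(t) if has_all_cells else None,
            chi2=pearson_chi2(t) if has_all_cells else None,
            curve=decision_curve(t, threshold_grid),
            n_dropped=self.n_dropped,
        )


@dataclass(frozen=True)
class ScreeningResults:
    """Fitted screening evaluation; see module docstring."""

    table: TwoByTwoTable
    metrics: ScreenMetrics
    or_estimate: OREstimate
    model_fit: Optional[BinaryModelFit]
    chi2: Optional[object]
    curve: NetBenefitCurve
    n_dropped: Optional[int] = None

    @property
    def crossing_threshold(self) -> Optional[float]:
        return self.curve.crossing_threshold

    def to_dict(self) -> dict:
        d = {
            "table": {"tp": self.table.tp, "fp": self.table.fp,
                      "fn": self.table.fn, "tn": self.table.tn},
            "metrics": self.metrics.to_dict(),
            "odds_ratio": {
                "or": self.or_estimate.or_value,
                "ci95": list(self.or_estimate.ci95),
                "method": self.or_estimate.method,
            },
            "crossing_threshold": self.crossing_threshold,
            "prevalence": self.curve.prevalence,
            "version": _pkg_version,
        }
        if self.model_fit is not None:
            d["logistic"] = {
                "intercept": self.model_fit.intercept,
                "slope": self.model_fit.slope,
                "wald_chi2": self.model_fit.wald_chi2,
                "wald_p": self.model_fit.wald_p,
                "auc": self.model_fit.auc,
                "brier": self.model_fit.brier,
            }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def summary(self) -> str:
        """Aligned-text summary of the full evaluation."""
        t = self.table
        lines = [
            "Binary screen evaluation",
            "========================",
            f"N = {t.n}  (screen+ {t.n_screen_pos}, screen- {t.n_screen_neg}; "
            f"outcome prevalence {self.curve.prevalence:.4f})",
            f"2x2 table [TP FP / FN TN]: {t.tp} {t.fp} / {t.fn} {t.tn}",
            "",
            self.metrics.format_table(),
            "",
            f"Odds ratio ({self.or_estimate.method}): "
            f"{self.or_estimate.or_value:.2f} "
            f"[{self.or_estimate.ci95[0]:.2f}, {self.or_estimate.ci95[1]:.2f}]",
        ]
        if self.model_fit is not None:
            m = self.model_fit
            lines.append(
                f"Logistic fit: Wald chi2 {m.wald_chi2:.1f} (p "
                f"{'<0.0001' if m.wald_p < 1e-4 else format(m.wald_p, '.4f')}), "
                f"AUC {m.auc:.3f}, Brier {m.brier:.3f}"
            )
        if self.crossing_threshold is not None:
            lines.append(
                "Decision curve crossing (screen-guided vs Test-All): "
                f"R* = {self.crossing_threshold:.4f} "
                f"({100 * self.crossing_threshold:.1f}%) = 1 - NPV"
            )
        else:
            lines.append(
                "Decision curve: screen-guided strategy weakly dominates "
                "Test-All (no crossing in (0, 1))"
            )
        if self.n_dropped:
            lines.append(f"Complete-case filter dropped {self.n_dropped} record(s)")
        return "\n".join(lines)
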