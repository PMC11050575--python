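"""Screening-performance and clinical-utility metrics for a binary screen.

Given the 2x2 table of screen status against outcome this module computes
the standard diagnostic-test family: sensitivity, specificity, accuracy,
Youden index J = Se + Sp - 1 with its reciprocal the number needed to
diagnose (NND = 1/J), positive and negative predictive values, the
predictive summary index PSI = PPV + NPV - 1 with the number needed to
predict (NNP = 1/PSI), and the clinical utility indices
CUI+ = Se * PPV, CUI- = Sp * NPV, summed into the summary utility index
(SUI).  All values are carried at full precision; rounding happens only in
reports (4 decimals for proportions, 2 for NND/NNP).

A metric whose denominator is zero is explicitly undefined (None), never
silently zero; J <= 0 makes NND infinite, and likewise PSI <= 0 for NNP.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Optional

from .cohort import TwoByTwoTable

#: Clinical-utility grading cutpoints (lower bound of each grade).  The
#: conventional qualitative scale: >=0.81 excellent, >=0.64 good,
#: >=0.49 adequate (utility ~ satisfactory), >=0.36 poor, below very poor.
DEFAULT_CUI_CUTPOINTS: tuple[tuple[float, str], ...] = (
    (0.81, "excellent"),
    (0.64, "good"),
    (0.49, "adequate"),
    (0.36, "poor"),
    (0.0, "very poor"),
)


def grade_utility(cui: float, cutpoints=DEFAULT_CUI_CUTPOINTS) -> str:
    """Qualitative grade for a clinical utility index in [0, 1]."""
    if not (0.0 <= cui <= 1.0):
        raise ValueError(f"CUI must lie in [0, 1], got {cui}")
    for lower, label in cutpoints:
        if cui >= lower:
            return label
    return cutpoints[-1][1]


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def _reciprocal(value: Optional[float], name: str) -> Optional[float]:
    if value is None:
        return None
    if value > 0:
        return 1.0 / value
    warnings.warn(f"{name} is undefined (index <= 0); returning +inf", stacklevel=3)
    return math.inf


@dataclass(frozen=True)
class ScreenMetrics:
    """The full screening metric family computed from one 2x2 table."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    youden_j: Optional[float]
    nnd: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    psi: Optional[float]
    nnp: Optional[float]
    cui_pos: Optional[float]
    cui_neg: Optional[float]
    sui: Optional[float]
    grade_cui_pos: Optional[str]
    grade_cui_neg: Optional[str]

    def to_dict(self, rounded: bool = False) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "youden_j": self.youden_j,
            "nnd": self.nnd,
            "ppv": self.ppv,
            "npv": self.npv,
            "psi": self.psi,
            "nnp": self.nnp,
            "cui_pos": self.cui_pos,
            "cui_neg": self.cui_neg,
            "sui": self.sui,
            "grade_cui_pos": self.grade_cui_pos,
            "grade_cui_neg": self.grade_cui_neg,
        }
        if rounded:
            two = {"nnd", "nnp"}
            for k, v in d.items():
                if isinstance(v, float) and math.isfinite(v):
                    d[k] = round(v, 2 if k in two else 4)
        return d

    def to_json(self, rounded: bool = True) -> str:
        d = self.to_dict(rounded=rounded)
        for k, v in d.items():
            if v is None:
                d[k] = "undefined"
            elif isinstance(v, float) and math.isinf(v):
                d[k] = "infinity"
        return json.dumps(d, indent=2)

    def format_table(self) -> str:
        """Aligned-text report mirroring the clinical screening-table layout."""
        def fmt(v, nd=4):
            if v is None:
                return "undefined"
            if isinstance(v, float) and math.isinf(v):
                return "inf"
            return f"{v:.{nd}f}"

        rows = [
            ("Sensitivity", fmt(self.sensitivity)),
            ("Specificity", fmt(self.specificity)),
            ("Accuracy", fmt(self.accuracy)),
            ("Youden Index (J)", fmt(self.youden_j)),
            ("Number Needed to Diagnose (NND)", fmt(self.nnd, 2)),
            ("PPV", fmt(self.ppv)),
            ("NPV", fmt(self.npv)),
            ("Predictive Summary Index (PSI)", fmt(self.psi)),
            ("Number Needed to Predict (NNP)", fmt(self.nnp, 2)),
            ("CUI(+)", f"{fmt(self.cui_pos)} ({self.grade_cui_pos})"),
            ("CUI(-)", f"{fmt(self.cui_neg)} ({self.grade_cui_neg})"),
            ("Summary Utility Index (SUI)", fmt(self.sui)),
        ]
        width = max(len(name) for name, _ in rows)
        return "\n".join(f"{name:<{width}}  {val}" for name, val in rows)


def screen_metrics(table: TwoByTwoTable, cui_cutpoints=DEFAULT_CUI_CUTPOINTS) -> ScreenMetrics:
    """Compute the screening metric family from a 2x2 table.

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
    (TP+TN)/N, PPV = TP/(TP+FP), NPV = TN/(TN+FN); derived indices follow
    the identities in the class docstring.
    """
    se = _ratio(table.tp, table.n_outcome_pos)
    sp = _ratio(table.tn, table.n_outcome_neg)
    acc = _ratio(table.tp + table.tn, table.n)
    ppv = _ratio(table.tp, table.n_screen_pos)
    npv = _ratio(table.tn, table.n_screen_neg)

    j = se + sp - 1.0 if (se is not None and sp is not None) else None
    psi = ppv + npv - 1.0 if (ppv is not None and npv is not None) else None
    nnd = _reciprocal(j, "NND")
    nnp = _reciprocal(psi, "NNP")
    cui_pos = se * ppv if (se is not None and ppv is not None) else None
    cui_neg = sp * npv if (sp is not None and npv is not None) else None
    sui = cui_pos + cui_neg if (cui_pos is not None and cui_neg is not None) else None

    return ScreenMetrics(
        sensitivity=se,
        specificity=sp,
        accuracy=acc,
        youden_j=j,
        nnd=nnd,
        ppv=ppv,
        npv=npv,
        psi=psi,
        nnp=nnp,
        cui_pos=cui_pos,
        cui_neg=cui_neg,
        sui=sui,
        grade_cui_pos=grade_utility(cui_pos, cui_cutpoints) if cui_pos is not None else None,
        grade_cui_neg=grade_utility(cui_neg, cui_cutpoints) if cui_neg is not None else None,
    )
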