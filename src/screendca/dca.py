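"""Decision curve analysis for a binary screen.

Net benefit at a risk threshold R weighs true positives against false
positives at the exchange rate R/(1-R):

    NB_model(R) = TP/N - [R/(1-R)] FP/N
    NB_all(R)   = P    - [R/(1-R)] (1-P)        (treat everyone)
    NB_none(R)  = 0                              (treat no one)

with P the outcome prevalence.  Counts enter as population fractions
(TP/N, FP/N), the standard convention of the decision-curve literature.
For an informative screen with FN, TN > 0 the model and Test-All curves
cross exactly once, at

    R* = FN / (FN + TN) = 1 - NPV,

i.e. the residual outcome risk among screen-negatives: below R* testing
everyone dominates, above it screen-guided testing does.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import TwoByTwoTable


def _weight(threshold: np.ndarray | float):
    return threshold / (1.0 - threshold)


def net_benefit(table: TwoByTwoTable, threshold: float) -> tuple[float, float, float]:
    """(nb_model, nb_all, nb_none) at one risk threshold in (0, 1)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"risk threshold must lie in (0, 1), got {threshold}")
    n = table.n
    p = table.n_outcome_pos / n
    w = _weight(threshold)
    nb_model = table.tp / n - w * table.fp / n
    nb_all = p - w * (1.0 - p)
    return (nb_model, nb_all, 0.0)


def crossing_threshold(table: TwoByTwoTable) -> Optional[float]:
    """Exact threshold where the screen-guided and Test-All curves cross.

    Closed form R* = FN/(FN+TN) = 1 - NPV, from setting NB_model = NB_all
    and solving R/(1-R) = FN/TN.  Returns None when FN = 0 (the screen
    misses nobody, so its curve weakly dominates Test-All everywhere) or
    TN = 0 (no crossing inside (0, 1)).
    """
    if table.fn == 0 or table.tn == 0:
        return None
    return table.fn / (table.fn + table.tn)


DEFAULT_GRID = tuple(np.round(np.arange(1, 51) * 0.01, 10))


@dataclass(frozen=True)
class NetBenefitCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    prevalence: float
    tpr_fraction: float  # TP/N
    fpr_fraction: float  # FP/N
    crossing_threshold: Optional[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "nb_model": self.nb_model,
                "nb_all": self.nb_all,
                "nb_none": self.nb_none,
            }
        )

    def plot(self, ax=None, path=None):
        """Decision curve: net benefit of the three strategies vs threshold."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            fig, ax = plt.subplots(figsize=(7, 5))
        else:
            fig = ax.figure
        ax.plot(self.thresholds, self.nb_all, label="Test All", color="tab:gray")
        ax.plot(self.thresholds, self.nb_model, label="Screen-guided", color="tab:blue")
        ax.plot(self.thresholds, self.nb_none, label="Test None", color="black", lw=0.8)
        if self.crossing_threshold is not None:
            ax.axvline(self.crossing_threshold, ls="--", color="tab:red", lw=0.8,
                       label=f"crossing R*={self.crossing_threshold:.3f}")
        ax.set_xlabel("Risk threshold R")
        ax.set_ylabel("Net benefit")
        ax.set_ylim(bottom=min(-0.02, float(self.nb_model.min())))
        ax.legend()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return ax


def decision_curve(
    table: TwoByTwoTable, grid: Sequence[float] = DEFAULT_GRID
) -> NetBenefitCurve:
    """Evaluate the three-strategy decision curve on a threshold grid.

    The exact crossing threshold, when it exists and falls inside the open
    unit interval, is appended to the grid so the reported curve always
    contains the point where the strategies exchange dominance.
    """
    grid = np.asarray(sorted(set(float(g) for g in grid)))
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if grid.min() <= 0.0 or grid.max() >= 1.0:
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    rstar = crossing_threshold(table)
    if rstar is not None and rstar not in grid:
        grid = np.sort(np.append(grid, rstar))
    n = table.n
    p = table.n_outcome_pos / n
    w = _weight(grid)
    nb_model = table.tp / n - w * table.fp / n
    nb_all = p - w * (1.0 - p)
    return NetBenefitCurve(
        thresholds=grid,
        nb_model=nb_model,
        nb_all=nb_all,
        nb_none=np.zeros_like(grid),
        prevalence=p,
        tpr_fraction=table.tp / n,
        fpr_fraction=table.fp / n,
        crossing_threshold=rstar,
    )
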