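"""Tetrachoric correlation: latent bivariate-normal association for 2x2 tables.

The tetrachoric model assumes the two observed dichotomies arise by
thresholding a standard bivariate normal (X, Y) with correlation rho at
cutpoints tau_row and tau_col.  The thresholds are identified by the
marginal proportions and rho by the both-negative cell probability, so for
a 2x2 table the maximum-likelihood estimate reduces to a one-parameter
bracketed root search on

    Phi2(tau_row, tau_col; rho) = TN / N.

Strength bands follow the epidemiological convention: |rho| in [0.3, 0.6)
fair, [0.6, 0.8) moderate, >= 0.8 very strong, below 0.3 negligible (the
published band edges leave (0.5, 0.6) and (0.7, 0.8) unassigned; the
half-open intervals here are this package's documented interpretation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .cohort import (
    CHD_CLASSES,
    Cohort,
    CohortError,
    ECA_TYPES,
    TwoByTwoTable,
    complete_case,
)

RHO_MAX_DEFAULT = 0.999

BANDS: tuple[tuple[float, str], ...] = (
    (0.8, "very_strong"),
    (0.6, "moderate"),
    (0.3, "fair"),
    (0.0, "negligible"),
)


def band_of(rho: float) -> str:
    """Qualitative strength band for a correlation coefficient."""
    a = abs(rho)
    for lower, label in BANDS:
        if a >= lower:
            return label
    return "negligible"


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for a standard bivariate normal with correlation rho.

    Uses the reduction to a one-dimensional integral,
    integral_{-inf}^{h} phi(x) Phi((k - rho x)/sqrt(1-rho^2)) dx,
    evaluated by adaptive quadrature to absolute accuracy ~1e-12.
    """
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    if math.isinf(h) and h < 0 or math.isinf(k) and k < 0:
        return 0.0
    if rho == 0.0:
        return float(ndtr(h) * ndtr(k))
    if math.isinf(h):
        return float(ndtr(k))
    if math.isinf(k):
        return float(ndtr(h))
    denom = math.sqrt(1.0 - rho * rho)

    def integrand(x: float) -> float:
        return math.exp(-0.5 * x * x) / math.sqrt(2 * math.pi) * ndtr((k - rho * x) / denom)

    val, _ = integrate.quad(integrand, -np.inf, h, epsabs=1e-13, epsrel=1e-13, limit=200)
    return float(min(max(val, 0.0), 1.0))


@dataclass(frozen=True)
class TetrachoricEstimate:
    rho: float
    tau_row: float
    tau_col: float
    converged: bool
    iterations: int
    band: str
    corrected: bool = False  # True when the 0.5 zero-cell correction was applied


def tetrachoric_rho(
    table: TwoByTwoTable, rho_max: float = RHO_MAX_DEFAULT, tol: float = 1e-10
) -> TetrachoricEstimate:
    """Maximum-likelihood tetrachoric correlation for a 2x2 table.

    Any zero cell triggers the 0.5 continuity correction (flagged).  A zero
    margin leaves rho unidentified and raises.  If the root is not
    bracketed within (-rho_max, rho_max) the estimate is clamped at the
    bound with ``converged=False`` and a warning.
    """
    a, b, c, d = (float(x) for x in table.cells())
    corrected = False
    if min(a, b, c, d) == 0.0:
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            raise CohortError("zero margin: tetrachoric correlation unidentified")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    n = a + b + c + d
    # rows are screen +/- and columns outcome +/-; "negative" proportions
    p_row_neg = (c + d) / n
    p_col_neg = (b + d) / n
    p_both_neg = d / n
    tau_row = float(ndtri(p_row_neg))
    tau_col = float(ndtri(p_col_neg))

    def f(rho: float) -> float:
        return bvn_cdf(tau_row, tau_col, rho) - p_both_neg

    f_lo, f_hi = f(-rho_max), f(rho_max)
    if f_lo == 0.0:
        rho, converged, iters = -rho_max, True, 0
    elif f_hi == 0.0:
        rho, converged, iters = rho_max, True, 0
    elif f_lo * f_hi > 0:
        # observed cell beyond what |rho| <= rho_max can produce
        rho = rho_max if abs(f_hi) < abs(f_lo) else -rho_max
        warnings.warn(
            f"tetrachoric rho pinned at {rho:+.3f} (root outside bound)", stacklevel=2
        )
        converged, iters = False, 0
    else:
        rho, res = brentq(f, -rho_max, rho_max, xtol=1e-12, full_output=True)
        converged = res.converged and abs(f(rho)) <= tol
        iters = res.iterations
    return TetrachoricEstimate(
        rho=float(rho),
        tau_row=tau_row,
        tau_col=tau_col,
        converged=bool(converged),
        iterations=int(iters),
        band=band_of(rho),
        corrected=corrected,
    )


@dataclass(frozen=True)
class CorrelationMatrix:
    """ECA-type x CHD-class tetrachoric correlation grid."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    rho: np.ndarray  # NaN where estimation failed
    n: int
    subset: str  # "all" or "diagnosed_only"
    failures: dict  # (row, col) -> reason

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rho, index=list(self.row_labels), columns=list(self.col_labels))


def correlation_matrix(
    cohort: Cohort,
    subset: str = "all",
    eca_labels=ECA_TYPES,
    chd_classes=CHD_CLASSES,
) -> CorrelationMatrix:
    """Tetrachoric correlation of each anomaly type with each CHD class.

    Each cell dichotomizes the cohort as (anomaly present) x (class
    membership).  ``subset="diagnosed_only"`` first restricts to records
    with the outcome present, mirroring the diagnosed-patient panel.
    """
    if subset not in ("all", "diagnosed_only"):
        raise ValueError(f"subset must be 'all' or 'diagnosed_only', got {subset!r}")
    sub = complete_case(cohort, ["eca_status", "chd_class"])
    if subset == "diagnosed_only":
        recs = tuple(r for r in sub.records if r.diagnosis_identified is True)
        if not recs:
            raise CohortError("diagnosed_only subset is empty")
    else:
        recs = sub.records
    n = len(recs)
    rho = np.full((len(eca_labels), len(chd_classes)), np.nan)
    failures: dict = {}
    for i, label in enumerate(eca_labels):
        exposed = np.array([label in r.eca_types for r in recs])
        for j, cls in enumerate(chd_classes):
            member = np.array([r.chd_class == cls for r in recs])
            tp = int(np.sum(exposed & member))
            fp = int(np.sum(exposed & ~member))
            fn = int(np.sum(~exposed & member))
            tn = int(np.sum(~exposed & ~member))
            if tp + fp == 0 or fn + tn == 0 or tp + fn == 0 or fp + tn == 0:
                failures[(label, cls)] = "zero margin"
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = tetrachoric_rho(TwoByTwoTable(tp, fp, fn, tn))
            if not est.converged:
                failures[(label, cls)] = "not converged (pinned at bound)"
            rho[i, j] = est.rho
    return CorrelationMatrix(tuple(eca_labels), tuple(chd_classes), rho, n, subset, failures)


def plot_correlation_panels(
    matrix_all: CorrelationMatrix,
    matrix_diagnosed: Optional[CorrelationMatrix] = None,
    path=None,
):
    """Heatmap panel(s) of the correlation grid (all vs diagnosed-only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mats = [matrix_all] + ([matrix_diagnosed] if matrix_diagnosed is not None else [])
    fig, axes = plt.subplots(len(mats), 1, figsize=(8, 6 * len(mats)), squeeze=False)
    for ax, m in zip(axes.ravel(), mats):
        im = ax.imshow(m.rho, vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto")
        ax.set_xticks(range(len(m.col_labels)), m.col_labels, rotation=45, ha="right")
        ax.set_yticks(range(len(m.row_labels)), m.row_labels, fontsize=7)
        ax.set_title(f"Tetrachoric correlation ({m.subset}, n={m.n})")
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
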