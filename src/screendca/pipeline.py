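"""End-to-end analysis orchestration.

``run_analysis`` reads (or accepts) a cohort, applies complete-case
filtering, and produces a structured report covering the screening metric
family, the binary-logistic equivalents, the per-anomaly association scan,
the anomaly x CHD-class tetrachoric matrices (cohort-wide and
diagnosed-only), the decision curve, and the period trend tests stratified
by screen status.  Every section is either populated or carries an
explicit skip reason, so a partial input (e.g. counts only, no anomaly
types) still yields a valid report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import __version__ as _pkg_version
from .association import cochran_armitage, eca_scan, scan_to_records
from .cohort import Cohort, CohortError, complete_case, read_cohort, subset, trend_table
from .model import ScreeningModel
from .tetrachoric import correlation_matrix

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_PARTIAL = 3


@dataclass
class AnalysisReport:
    """Structured result of a full pipeline run."""

    sections: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def exit_code(self) -> int:
        return EXIT_PARTIAL if self.skipped else EXIT_OK

    def to_dict(self) -> dict:
        return {
            "sections": self.sections,
            "skipped": self.skipped,
            "metadata": self.metadata,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return [None if np.isnan(v) else float(v) for v in obj.ravel()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_analysis(
    cohort: Cohort | str,
    screen: str = "eca_status",
    outcome: str = "diagnosis_identified",
    alpha: float = 0.05,
) -> AnalysisReport:
    """Run every analysis stage on a cohort (object or file path).

    Deterministic given its inputs.  Stage failures are captured as skip
    reasons rather than aborting the whole run.
    """
    if not isinstance(cohort, Cohort):
        cohort = read_cohort(cohort)
    report = AnalysisReport()
    n_before = len(cohort)
    sub = complete_case(cohort, [screen, outcome])
    report.metadata = {
        "version": _pkg_version,
        "n_records": n_before,
        "n_complete_case": len(sub),
        "n_dropped": n_before - len(sub),
        "screen": screen,
        "outcome": outcome,
    }
    logger.info("complete-case: %d of %d records retained", len(sub), n_before)

    # Screening metrics, logistic equivalents, decision curve.
    try:
        res = ScreeningModel.from_cohort(cohort, screen, outcome).fit()
        report.sections["screening"] = res.to_dict()
        curve = res.curve.to_frame()
        report.sections["decision_curve"] = {
            "threshold": curve["threshold"].tolist(),
            "nb_model": curve["nb_model"].tolist(),
            "nb_all": curve["nb_all"].tolist(),
            "nb_none": curve["nb_none"].tolist(),
            "crossing_threshold": res.crossing_threshold,
        }
    except (CohortError, ValueError) as exc:
        report.skipped["screening"] = str(exc)
        report.skipped["decision_curve"] = str(exc)

    # Per-anomaly association scan.
    if any(r.eca_types for r in sub.records):
        try:
            rows = eca_scan(sub, alpha=alpha, outcome=outcome)
            report.sections["eca_scan"] = scan_to_records(rows)
        except (CohortError, ValueError) as exc:
            report.skipped["eca_scan"] = str(exc)
    else:
        report.skipped["eca_scan"] = "no patient-level ECA types"

    # Tetrachoric anomaly x class matrices.
    has_classes = any(r.chd_class is not None for r in sub.records)
    if has_classes and any(r.eca_types for r in sub.records):
        for key, which in (("correlation_all", "all"), ("correlation_diagnosed", "diagnosed_only")):
            try:
                m = correlation_matrix(sub, subset=which)
                report.sections[key] = {
                    "row_labels": list(m.row_labels),
                    "col_labels": list(m.col_labels),
                    "rho": [
                        [None if np.isnan(v) else float(v) for v in row]
                        for row in m.rho
                    ],
                    "n": m.n,
                    "failures": {f"{a}|{b}": r for (a, b), r in m.failures.items()},
                }
            except (CohortError, ValueError) as exc:
                report.skipped[key] = str(exc)
    else:
        reason = "no patient-level ECA types or CHD classes"
        report.skipped["correlation_all"] = reason
        report.skipped["correlation_diagnosed"] = reason

    # Period trend, stratified by screen status.
    has_periods = any(r.period is not None for r in sub.records)
    if has_periods:
        trends = {}
        for name, flag in (("screen_negative", False), ("screen_positive", True)):
            try:
                stratum = subset(sub, lambda r, f=flag: getattr(r, screen) is f)
                tt = trend_table(stratum, group="period", outcome=outcome)
                tr = cochran_armitage(tt, sidedness="one", direction="increasing")
                trends[name] = {
                    "groups": list(zip(tt.labels, tt.ns, tt.xs)),
                    "rates": list(tt.rates),
                    "statistic": tr.statistic,
                    "p_value": tr.p_value,
                }
            except (CohortError, ValueError) as exc:
                report.skipped[f"trend_{name}"] = str(exc)
        if trends:
            report.sections["trend"] = trends
    else:
        report.skipped["trend"] = "no period information"

    return report
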