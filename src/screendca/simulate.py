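"""Synthetic cohort generator and printed-count fixtures.

No patient-level data accompany the study this package models, so the
generator emulates a cohort with the published aggregate structure: ~43%
screen-positive, outcome prevalence 38.3% among screen-positives and
13.5% among screen-negatives (rising 7.7% -> 15.6% -> 19.7% across the
three program periods), eight CHD classes at the published frequencies,
and 26 organ/system anomaly-type flags drawn by dichotomizing a latent
multivariate normal so tetrachoric recovery is exact in expectation.

Screen status is true iff at least one anomaly-type flag is present, then
topped up to the per-class screen-positive targets by a residual
"functional anomaly" channel (status positive without a listed structural
type).  The residual probability is calibrated per CHD class against the
empirical structural rate in the generated sample, so the class-conditional
screen-positive fractions converge to their targets wherever the structural
floor permits.

The module also registers the printed aggregate tables (the 2x2 screening
table, each anomaly-type row, and the period-trend strata) as named
fixtures backed by small in-repo CSV files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .cohort import (
    CHD_CLASSES,
    Cohort,
    CohortError,
    ECA_TYPES,
    PERIODS,
    PatientRecord,
    TrendTable,
    TwoByTwoTable,
)

logger = logging.getLogger(__name__)

#: Cohort-wide counts behind the fixture tables.
FIXTURE_N_TOTAL = 1013
FIXTURE_N_DIAGNOSED = 244

# Published marginal/conditional frequencies used as generator defaults.
_CHD_COUNTS = {
    "APVR": 28,
    "AVSD": 37,
    "Complex": 132,
    "Conotruncal": 249,
    "Heterotaxy": 73,
    "LVOTO": 260,
    "RVOTO": 98,
    "Septal": 136,
}
_ECA_GIVEN_CLASS = {
    "APVR": 5 / 28,
    "AVSD": 20 / 37,
    "Complex": 61 / 132,
    "Conotruncal": 81 / 249,
    "Heterotaxy": 65 / 73,
    "LVOTO": 73 / 260,
    "RVOTO": 27 / 98,
    "Septal": 101 / 136,
}
_ECA_TYPE_COUNTS = (
    1, 9, 60, 82, 8, 29, 4, 4, 42, 2, 34, 4, 22, 97, 97, 45, 45, 38, 49, 4,
    8, 3, 17, 75, 9, 18,
)
_RACE_PROBS = {
    "Asian/Pacific Island": 25 / 1013,
    "Black/African American": 126 / 1013,
    "Hispanic/Latino": 110 / 1013,
    "Other": 3 / 1013,
    "White": 707 / 1013,
    "Unknown/Declined": 42 / 1013,
}
_CLINICAL_GIVEN_NEG = (526 / 580, 27 / 580, 27 / 580)   # isolated, possibly, confirmed
_CLINICAL_GIVEN_POS = (141 / 433, 215 / 433, 77 / 433)
_DX_TYPE_PROBS = (168 / 245, 70 / 245, 5 / 245, 2 / 245)  # cytogenetic, molecular, both, clinical

#: Default exchangeable latent correlation among anomaly types.  Anomalies
#: cluster in syndromic patients; 0.6 yields ~2.9 types per structurally
#: affected patient and an any-type rate of ~0.27, leaving the residual
#: functional channel room to reach the class screen-positive targets.
DEFAULT_TYPE_LATENT_RHO = 0.6


def _exchangeable(k: int, rho: float) -> np.ndarray:
    m = np.full((k, k), rho)
    np.fill_diagonal(m, 1.0)
    return m


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the published study frequencies."""

    n: int = 1013
    seed: int = 0
    p_screen_pos: float = 433 / 1013
    p_outcome_given_pos: float = 166 / 433
    #: Used only when ``period_trend`` is None.
    p_outcome_given_neg: float = 78 / 580
    chd_class_probs: tuple[float, ...] = tuple(
        _CHD_COUNTS[c] / 1013 for c in CHD_CLASSES
    )
    #: Per-class screen-positive probabilities; None falls back to the
    #: aggregate ``p_screen_pos`` for every class.
    eca_conditional: Optional[tuple[float, ...]] = tuple(
        _ECA_GIVEN_CLASS[c] for c in CHD_CLASSES
    )
    eca_labels: tuple[str, ...] = ECA_TYPES
    eca_marginal_prev: tuple[float, ...] = tuple(
        c / 1013 for c in _ECA_TYPE_COUNTS
    )
    #: Latent correlation among anomaly types; None means exchangeable at
    #: :data:`DEFAULT_TYPE_LATENT_RHO`.
    eca_latent_corr: Optional[np.ndarray] = None
    #: ``{(chd_class, eca_label): latent mean shift}`` adds class-specific
    #: anomaly enrichment (e.g. spleen anomalies in heterotaxy).
    class_type_shift: Mapping[tuple[str, str], float] = field(default_factory=dict)
    period_probs: tuple[float, ...] = (313 / 1013, 549 / 1013, 151 / 1013)
    #: Screen-negative outcome rate per period; overrides
    #: ``p_outcome_given_neg`` when present.
    period_trend: Optional[tuple[float, ...]] = (0.077, 0.156, 0.197)
    sex_female_rate: float = 443 / 1013
    neonate_rate: float = 880 / 1013
    maternal_diabetes_rate: float = 85 / 1013

    def class_screen_targets(self) -> tuple[float, ...]:
        if self.eca_conditional is not None:
            return tuple(self.eca_conditional)
        return tuple(self.p_screen_pos for _ in CHD_CLASSES)

    def implied_p_screen_pos(self) -> float:
        return float(
            np.dot(self.chd_class_probs, self.class_screen_targets())
        )

    def implied_p_outcome_given_neg(self) -> float:
        """Marginal screen-negative outcome rate implied by the period trend."""
        if self.period_trend is None:
            return self.p_outcome_given_neg
        return float(np.dot(self.period_probs, self.period_trend))

    def implied_log_or(self) -> float:
        """Log odds ratio implied by the two conditional outcome rates."""
        p1 = self.p_outcome_given_pos
        p0 = self.implied_p_outcome_given_neg()
        return float(np.log(p1 / (1 - p1) / (p0 / (1 - p0))))

    def latent_corr(self) -> np.ndarray:
        k = len(self.eca_labels)
        corr = (
            _exchangeable(k, DEFAULT_TYPE_LATENT_RHO)
            if self.eca_latent_corr is None
            else np.asarray(self.eca_latent_corr, dtype=float)
        )
        if corr.shape != (k, k):
            raise CohortError(f"latent correlation must be {k}x{k}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise CohortError("latent correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise CohortError("latent correlation matrix must have unit diagonal")
        w, v = np.linalg.eigh(corr)
        if w.min() < -1e-10:
            warnings.warn(
                "latent correlation not positive definite; repairing by "
                "eigenvalue clipping",
                stacklevel=2,
            )
        w = np.clip(w, 1e-8, None)
        repaired = (v * w) @ v.T
        d = np.sqrt(np.diag(repaired))
        return repaired / np.outer(d, d)

    def validate(self) -> None:
        if self.n < 0:
            raise CohortError("n must be nonnegative")
        probs = [
            self.p_screen_pos,
            self.p_outcome_given_pos,
            self.p_outcome_given_neg,
            self.sex_female_rate,
            self.neonate_rate,
            self.maternal_diabetes_rate,
            *self.chd_class_probs,
            *self.eca_marginal_prev,
            *self.period_probs,
            *(self.period_trend or ()),
            *(self.eca_conditional or ()),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise CohortError("all probabilities must lie in [0, 1]")
        if len(self.chd_class_probs) != len(CHD_CLASSES):
            raise CohortError("chd_class_probs must have 8 entries")
        if abs(sum(self.chd_class_probs) - 1.0) > 1e-9:
            raise CohortError("chd_class_probs must sum to 1")
        if abs(sum(self.period_probs) - 1.0) > 1e-9:
            raise CohortError("period_probs must sum to 1")
        if len(self.eca_marginal_prev) != len(self.eca_labels):
            raise CohortError("eca_marginal_prev must match eca_labels")
        for label in self.eca_labels:
            if label not in ECA_TYPES:
                raise CohortError(f"unknown anomaly label {label!r}")
        for cls, label in self.class_type_shift:
            if cls not in CHD_CLASSES or label not in self.eca_labels:
                raise CohortError(f"unknown class_type_shift key {(cls, label)!r}")
        self.latent_corr()


# Fixed field order for the seed substreams: appending new fields later must
# not perturb the draws of earlier ones.
_STREAMS = (
    "chd_class",
    "period",
    "eca_latent",
    "functional_eca",
    "outcome",
    "sex",
    "age_group",
    "age_days",
    "race_ethnicity",
    "maternal_diabetes",
    "clinical_description",
    "diagnosis_type",
)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_STREAMS, children)}


def generate(config: SyntheticConfig) -> Cohort:
    """Generate a synthetic cohort; bitwise-reproducible given the seed."""
    config.validate()
    n = config.n
    if n == 0:
        return Cohort((), provenance=f"synthetic seed={config.seed} n=0")
    rng = _rngs(config.seed)
    k = len(config.eca_labels)

    class_idx = rng["chd_class"].choice(len(CHD_CLASSES), size=n, p=config.chd_class_probs)
    period_idx = rng["period"].choice(len(PERIODS), size=n, p=config.period_probs)

    # Structural anomaly-type flags from the dichotomized latent normal.
    corr = config.latent_corr()
    chol = np.linalg.cholesky(corr)
    z = rng["eca_latent"].standard_normal((n, k)) @ chol.T
    for (cls, label), delta in config.class_type_shift.items():
        ci = CHD_CLASSES.index(cls)
        li = config.eca_labels.index(label)
        z[class_idx == ci, li] += delta
    thresholds = ndtri(1.0 - np.asarray(config.eca_marginal_prev))
    flags = z > thresholds
    structural_any = flags.any(axis=1)

    # Residual functional channel, calibrated per class against the sample.
    targets = config.class_screen_targets()
    u = rng["functional_eca"].random(n)
    functional = np.zeros(n, dtype=bool)
    for ci, target in enumerate(targets):
        mask = class_idx == ci
        if not mask.any():
            continue
        s = structural_any[mask].mean()
        if s > target:
            logger.info(
                "class %s: structural anomaly rate %.3f exceeds screen target "
                "%.3f; residual channel inactive",
                CHD_CLASSES[ci], s, target,
            )
            continue
        q = 0.0 if s >= 1.0 else (target - s) / (1.0 - s)
        functional |= mask & ~structural_any & (u < q)
    screen = structural_any | functional

    # Outcome: conditional on screen status (and period among negatives).
    if config.period_trend is not None:
        p_neg = np.asarray(config.period_trend)[period_idx]
    else:
        p_neg = np.full(n, config.p_outcome_given_neg)
    p_out = np.where(screen, config.p_outcome_given_pos, p_neg)
    outcome = rng["outcome"].random(n) < p_out

    sex = np.where(rng["sex"].random(n) < config.sex_female_rate, "female", "male")
    neonate = rng["age_group"].random(n) < config.neonate_rate
    age_u = rng["age_days"].random(n)
    age_days = np.where(
        neonate, (age_u * 29).astype(int), 29 + (age_u * (365 - 29)).astype(int)
    )
    race = rng["race_ethnicity"].choice(
        list(_RACE_PROBS), size=n, p=list(_RACE_PROBS.values())
    )
    diabetes = rng["maternal_diabetes"].random(n) < config.maternal_diabetes_rate
    cd_u = rng["clinical_description"].random(n)
    dx_idx = rng["diagnosis_type"].choice(4, size=n, p=_DX_TYPE_PROBS)

    width = max(6, len(str(n)))
    records = []
    for i in range(n):
        if screen[i]:
            cd_probs = np.cumsum(_CLINICAL_GIVEN_POS)
        else:
            cd_probs = np.cumsum(_CLINICAL_GIVEN_NEG)
        clinical = ("isolated", "possibly_syndromic", "confirmed_syndrome")[
            int(np.searchsorted(cd_probs, cd_u[i], side="right").clip(0, 2))
        ]
        dx_type = ("cytogenetic", "molecular", "both", "clinical")[dx_idx[i]] if outcome[i] else "none"
        types = tuple(
            label for label, f in zip(config.eca_labels, flags[i]) if f
        )
        records.append(
            PatientRecord(
                patient_id=f"S{i + 1:0{width}d}",
                sex=str(sex[i]),
                age_days=int(age_days[i]),
                age_group="neonate" if age_days[i] <= 28 else "infant",
                race_ethnicity=str(race[i]),
                chd_class=CHD_CLASSES[class_idx[i]],
                eca_status=bool(screen[i]),
                eca_types=types,
                maternal_diabetes=bool(diabetes[i]),
                clinical_description=clinical,
                period=PERIODS[period_idx[i]],
                diagnosis_identified=bool(outcome[i]),
                diagnosis_type=dx_type,
            )
        )
    return Cohort(
        tuple(records), provenance=f"synthetic seed={config.seed} n={n}"
    )


def cohort_from_2x2(table: TwoByTwoTable) -> Cohort:
    """Deterministically expand a 2x2 count table into a minimal cohort.

    Useful for running patient-level operations on printed aggregate
    counts; records carry only screen status and outcome.
    """
    records = []
    i = 0
    for count, scr, out in (
        (table.tp, True, True),
        (table.fp, True, False),
        (table.fn, False, True),
        (table.tn, False, False),
    ):
        for _ in range(count):
            i += 1
            records.append(
                PatientRecord(
                    patient_id=f"X{i:06d}",
                    eca_status=scr,
                    diagnosis_identified=out,
                )
            )
    return Cohort(tuple(records), provenance="expanded from 2x2 counts")


def _fixture_frame(name: str) -> pd.DataFrame:
    with resources.files("screendca.fixtures").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def _table4_frame() -> pd.DataFrame:
    return _fixture_frame("table4_eca_types.csv")


def _fixture_registry() -> dict:
    reg = {}
    reg["table5_2x2"] = lambda: TwoByTwoTable(
        *(int(v) for v in _fixture_frame("table5_2x2.csv").iloc[0])
    )

    def _eca_row(label: str):
        df = _table4_frame()
        row = df[df["label"] == label].iloc[0]
        a = int(row["n_exposed_diagnosed"])
        b = int(row["n_exposed"]) - a
        c = FIXTURE_N_DIAGNOSED - a
        d = (FIXTURE_N_TOTAL - int(row["n_exposed"])) - c
        return TwoByTwoTable(a, b, c, d)

    for label in _table4_frame()["label"]:
        slug = (
            label.lower()
            .replace(" ", "_")
            .replace("-", "_")
            .replace("/", "_")
        )
        reg[f"table4_{slug}"] = (lambda l: (lambda: _eca_row(l)))(label)

    def _trend(stratum: str):
        df = _fixture_frame("fig3_trend.csv")
        sub = df[df["stratum"] == stratum]
        return TrendTable(
            ns=tuple(int(v) for v in sub["n"]),
            xs=tuple(int(v) for v in sub["successes"]),
            scores=tuple(float(i) for i in range(len(sub))),
            labels=tuple(sub["period"]),
        )

    reg["fig3_trend_eca_neg"] = lambda: _trend("eca_negative")
    reg["fig3_trend_eca_pos"] = lambda: _trend("eca_positive")
    return reg


def fixture_names() -> list[str]:
    return sorted(_fixture_registry())


def fixture_table(name: str):
    """Return a registered printed-count fixture by name.

    ``table5_2x2`` is the screening 2x2; ``table4_<type>`` the per-anomaly
    exposure tables; ``fig3_trend_eca_neg``/``_pos`` the period-trend
    strata.  Unknown names raise with the full registry listed.
    """
    reg = _fixture_registry()
    if name not in reg:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(reg))}"
        )
    return reg[name]()


def table4_counts() -> pd.DataFrame:
    """The per-anomaly-type exposure/diagnosis counts as a data frame."""
    return _table4_frame()
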