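"""Patient-level cohort data model, delimited-text I/O and contingency aggregation.

The cohort is a flat table of infants with congenital heart disease (CHD):
one record per patient carrying the binary phenotypic screen (extracardiac
anomaly, ECA, status), the binary outcome (genetic diagnosis identified),
the CHD anatomic class, organ/system-specific ECA-type flags, the program
time period and basic covariates.  Every downstream statistic is computed
from contingency aggregations of these records, so the 2x2 table is the
atom of the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Canonical category dictionaries.  File readers accept alternates through a
# user-supplied column map but never coerce unknown levels silently.
CHD_CLASSES: tuple[str, ...] = (
    "APVR",
    "AVSD",
    "Complex",
    "Conotruncal",
    "Heterotaxy",
    "LVOTO",
    "RVOTO",
    "Septal",
)

#: The 26 organ- or system-specific extracardiac anomaly labels.
ECA_TYPES: tuple[str, ...] = (
    "Skull",
    "Head",
    "Neurological-Brain",
    "Neurological-Functional",
    "Neural Tube Defect",
    "Eye",
    "Ear",
    "Nose",
    "Oral Cavity",
    "Neck",
    "Throat",
    "Chest",
    "Lung",
    "Gastrointestinal",
    "Renal",
    "Liver-Biliary",
    "Spleen",
    "Ribs-Vertebral",
    "Limb-Digit",
    "Skin",
    "Umbilical",
    "Immunologic",
    "Endocrine",
    "Growth-Feeding",
    "Hematologic",
    "Other",
)

#: Program time periods, ordered P1 < P2 < P3 so trend direction is fixed.
PERIODS: tuple[str, ...] = ("P1", "P2", "P3")

SEXES: tuple[str, ...] = ("female", "male")
AGE_GROUPS: tuple[str, ...] = ("neonate", "infant")
CLINICAL_DESCRIPTIONS: tuple[str, ...] = (
    "isolated",
    "possibly_syndromic",
    "confirmed_syndrome",
)
DIAGNOSIS_TYPES: tuple[str, ...] = ("none", "cytogenetic", "molecular", "both", "clinical")

#: Declared level order per categorical field, used by ``crosstab`` so that
#: table layout is deterministic.  Boolean fields list True first to mirror
#: the "Yes" row/column convention of clinical 2x2 tables.
CATEGORY_ORDERS: dict[str, tuple, ] = {
    "sex": SEXES,
    "age_group": AGE_GROUPS,
    "chd_class": CHD_CLASSES,
    "eca_status": (True, False),
    "maternal_diabetes": (True, False),
    "clinical_description": CLINICAL_DESCRIPTIONS,
    "period": PERIODS,
    "diagnosis_identified": (True, False),
    "diagnosis_type": DIAGNOSIS_TYPES,
}


class CohortError(ValueError):
    """Raised for malformed cohort files or invalid records."""


@dataclass(frozen=True)
class PatientRecord:
    """One infant.  All fields except ``patient_id`` may be missing (None)."""

    patient_id: str
    sex: Optional[str] = None
    age_days: Optional[int] = None
    age_group: Optional[str] = None
    race_ethnicity: Optional[str] = None
    chd_class: Optional[str] = None
    eca_status: Optional[bool] = None
    eca_types: tuple[str, ...] = ()
    maternal_diabetes: Optional[bool] = None
    clinical_description: Optional[str] = None
    period: Optional[str] = None
    diagnosis_identified: Optional[bool] = None
    diagnosis_type: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CohortError("patient_id must be a non-empty string")
        _check_level("sex", self.sex, SEXES)
        _check_level("age_group", self.age_group, AGE_GROUPS)
        _check_level("chd_class", self.chd_class, CHD_CLASSES)
        _check_level("clinical_description", self.clinical_description, CLINICAL_DESCRIPTIONS)
        _check_level("period", self.period, PERIODS)
        _check_level("diagnosis_type", self.diagnosis_type, DIAGNOSIS_TYPES)
        for t in self.eca_types:
            _check_level("eca_types", t, ECA_TYPES)
        if self.age_days is not None and self.age_days < 0:
            raise CohortError(f"age_days must be nonnegative, got {self.age_days}")
        # status = "any ECA present"; a non-empty type list forces positive status
        if self.eca_types and self.eca_status is False:
            raise CohortError(
                f"{self.patient_id}: eca_status is False but eca_types is non-empty"
            )
        if self.eca_types and self.eca_status is None:
            object.__setattr__(self, "eca_status", True)
            logger.info(
                "%s: eca_status imputed True from non-empty eca_types", self.patient_id
            )
        if (
            self.diagnosis_type is not None
            and self.diagnosis_type != "none"
            and self.diagnosis_identified is not True
        ):
            raise CohortError(
                f"{self.patient_id}: diagnosis_type={self.diagnosis_type!r} "
                "requires diagnosis_identified=True"
            )
        if self.age_days is not None and self.age_group is not None:
            expected = "neonate" if self.age_days <= 28 else "infant"
            if self.age_group != expected:
                raise CohortError(
                    f"{self.patient_id}: age_group {self.age_group!r} inconsistent "
                    f"with age_days={self.age_days}"
                )


def _check_level(name: str, value, allowed: Sequence) -> None:
    if value is not None and value not in allowed:
        raise CohortError(
            f"unknown {name} level {value!r}; allowed: {', '.join(map(str, allowed))}"
        )


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of patient records with unique ids."""

    records: tuple[PatientRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate patient_id(s): {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def column(self, name: str) -> list:
        """Values of one field across all records, missing as None."""
        return [getattr(r, name) for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = {f: getattr(r, f) for f in _FIELDS}
            d["eca_types"] = ";".join(r.eca_types)
            rows.append(d)
        return pd.DataFrame(rows, columns=list(_FIELDS))


_FIELDS: tuple[str, ...] = (
    "patient_id",
    "sex",
    "age_days",
    "age_group",
    "race_ethnicity",
    "chd_class",
    "eca_status",
    "eca_types",
    "maternal_diabetes",
    "clinical_description",
    "period",
    "diagnosis_identified",
    "diagnosis_type",
)

_BOOL_FIELDS = {"eca_status", "maternal_diabetes", "diagnosis_identified"}
_MISSING_TOKENS = {"", "NA", "NaN", "nan", "None"}
_TRUE_TOKENS = {"true", "yes", "1", "y"}
_FALSE_TOKENS = {"false", "no", "0", "n"}


def _parse_bool(token: str, fieldname: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise CohortError(f"cannot parse {fieldname} value {token!r} as boolean")


def read_cohort(
    path,
    sep: Optional[str] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> Cohort:
    """Read a cohort from delimited text (comma or tab; auto-detected).

    Parameters
    ----------
    path : str or path-like
        UTF-8 file with a header row.
    sep : str, optional
        Field delimiter; sniffed from the header when omitted.
    column_map : mapping, optional
        ``{file column name -> canonical field name}`` for alternate headers.

    Missing cells are the empty string or ``NA`` and become explicit None.
    Malformed rows raise :class:`CohortError` naming the line number.
    """
    df = pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        dtype=str,
        keep_default_na=False,
    )
    if column_map:
        df = df.rename(columns=dict(column_map))
    unknown = [c for c in df.columns if c not in _FIELDS]
    if unknown:
        logger.warning("ignoring unrecognized column(s): %s", unknown)
    if "patient_id" not in df.columns:
        raise CohortError("cohort file must contain a patient_id column")

    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        raw = dict(zip(df.columns, row))
        kwargs: dict = {}
        for f in _FIELDS:
            if f not in raw:
                continue
            token = raw[f].strip() if isinstance(raw[f], str) else raw[f]
            if token in _MISSING_TOKENS:
                continue
            try:
                if f == "eca_types":
                    kwargs[f] = tuple(
                        t.strip() for t in token.split(";") if t.strip()
                    )
                elif f in _BOOL_FIELDS:
                    kwargs[f] = _parse_bool(token, f)
                elif f == "age_days":
                    kwargs[f] = int(token)
                else:
                    kwargs[f] = token
            except CohortError as exc:
                raise CohortError(f"line {line_no}: {exc}") from None
            except ValueError as exc:
                raise CohortError(f"line {line_no}: {exc}") from None
        try:
            records.append(PatientRecord(**kwargs))
        except CohortError as exc:
            raise CohortError(f"line {line_no}: {exc}") from None
        except TypeError as exc:
            raise CohortError(f"line {line_no}: {exc}") from None
    return Cohort(tuple(records), provenance=f"read from {path}")


def write_cohort(cohort: Cohort, path, sep: str = ",") -> None:
    """Write a cohort as delimited text; missing values become empty cells."""
    df = cohort.to_dataframe()
    for f in _BOOL_FIELDS:
        df[f] = df[f].map({True: "true", False: "false"})
    df.to_csv(path, sep=sep, index=False, na_rep="")


def complete_case(cohort: Cohort, variables: Sequence[str]) -> Cohort:
    """Restrict to records with no missing values among ``variables``.

    Mirrors complete-case analysis: the primary analyses use only records
    with non-missing screen status and outcome.  The count of dropped
    records is logged.
    """
    for v in variables:
        if v not in _FIELDS:
            raise CohortError(f"unknown field {v!r}")
    kept = tuple(
        r for r in cohort.records if all(getattr(r, v) is not None for v in variables)
    )
    dropped = len(cohort) - len(kept)
    if dropped:
        logger.info("complete_case: dropped %d of %d records", dropped, len(cohort))
    if not kept:
        raise CohortError("complete_case: no records remain (no analyzable data)")
    return Cohort(kept, provenance=cohort.provenance)


@dataclass(frozen=True)
class TwoByTwoTable:
    """Screen x outcome counts: rows screen +/-, columns outcome +/-.

    ``tp`` screen-positive & outcome-positive, ``fp`` screen-positive &
    outcome-negative, ``fn`` screen-negative & outcome-positive, ``tn``
    screen-negative & outcome-negative.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        cells = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 for c in cells):
            raise CohortError(f"negative cell count in {cells}")
        if sum(cells) == 0:
            raise CohortError("empty 2x2 table")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_screen_pos(self) -> int:
        return self.tp + self.fp

    @property
    def n_screen_neg(self) -> int:
        return self.fn + self.tn

    @property
    def n_outcome_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_outcome_neg(self) -> int:
        return self.fp + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=np.int64)

    def cells(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c count table with labelled margins."""

    counts: np.ndarray
    row_labels: tuple
    col_labels: tuple

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2:
            raise CohortError("contingency table must be 2-dimensional")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise CohortError("label lengths do not match count shape")
        if (counts < 0).any():
            raise CohortError("negative count")
        if counts.sum() == 0:
            raise CohortError("empty contingency table")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))


@dataclass(frozen=True)
class TrendTable:
    """Ordered binomial groups (n_i, x_i) with strictly increasing scores."""

    ns: tuple[int, ...]
    xs: tuple[int, ...]
    scores: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.ns) < 2:
            raise CohortError("trend table needs at least 2 groups")
        if not (len(self.ns) == len(self.xs) == len(self.scores)):
            raise CohortError("group sizes, successes and scores must align")
        for n, x in zip(self.ns, self.xs):
            if not (0 <= x <= n):
                raise CohortError(f"success count {x} outside [0, {n}]")
        if any(b <= a for a, b in zip(self.scores, self.scores[1:])):
            raise CohortError("scores must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.ns)

    @property
    def rates(self) -> tuple[float, ...]:
        return tuple(x / n if n else float("nan") for n, x in zip(self.ns, self.xs))


def _binary_values(values: list, fieldname: str) -> list[bool]:
    out = []
    for v in values:
        if v is None:
            raise CohortError(
                f"{fieldname} contains missing values; apply complete_case first"
            )
        if isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
        else:
            raise CohortError(f"{fieldname} is not binary (found {v!r})")
    return out


def crosstab2x2(cohort: Cohort, screen: str, outcome: str) -> TwoByTwoTable:
    """Aggregate a cohort into the screen x outcome 2x2 table.

    Both fields must be boolean and non-missing; the four cells sum to the
    cohort size by construction.
    """
    if len(cohort) == 0:
        raise CohortError("cannot tabulate an empty cohort")
    s = _binary_values(cohort.column(screen), screen)
    o = _binary_values(cohort.column(outcome), outcome)
    tp = sum(1 for a, b in zip(s, o) if a and b)
    fp = sum(1 for a, b in zip(s, o) if a and not b)
    fn = sum(1 for a, b in zip(s, o) if not a and b)
    tn = sum(1 for a, b in zip(s, o) if not a and not b)
    return TwoByTwoTable(tp, fp, fn, tn)


def crosstab(cohort: Cohort, row: str, col: str) -> ContingencyTable:
    """General r x c cross-tabulation with declared category order."""
    if len(cohort) == 0:
        raise CohortError("cannot tabulate an empty cohort")
    rv = cohort.column(row)
    cv = cohort.column(col)
    pairs = [(a, b) for a, b in zip(rv, cv) if a is not None and b is not None]
    if not pairs:
        raise CohortError("no complete pairs to tabulate")

    def _levels(fieldname, observed):
        declared = CATEGORY_ORDERS.get(fieldname)
        if declared is not None:
            return tuple(l for l in declared if l in observed)
        return tuple(sorted(observed))

    row_levels = _levels(row, {a for a, _ in pairs})
    col_levels = _levels(col, {b for _, b in pairs})
    if len(row_levels) < 2 or len(col_levels) < 2:
        raise CohortError("both margins need at least 2 observed levels")
    counts = np.zeros((len(row_levels), len(col_levels)), dtype=np.int64)
    ri = {l: i for i, l in enumerate(row_levels)}
    ci = {l: i for i, l in enumerate(col_levels)}
    for a, b in pairs:
        counts[ri[a], ci[b]] += 1
    return ContingencyTable(counts, row_levels, col_levels)


def trend_table(
    cohort: Cohort,
    group: str = "period",
    outcome: str = "diagnosis_identified",
    scores: Optional[Sequence[float]] = None,
) -> TrendTable:
    """Build the ordered-group trend input (e.g. period x outcome).

    Groups follow the declared category order; default scores 0, 1, ...
    """
    sub = complete_case(cohort, [group, outcome])
    gv = sub.column(group)
    ov = _binary_values(sub.column(outcome), outcome)
    declared = CATEGORY_ORDERS.get(group)
    observed = set(gv)
    levels = (
        tuple(l for l in declared if l in observed)
        if declared is not None
        else tuple(sorted(observed))
    )
    ns = tuple(sum(1 for g in gv if g == l) for l in levels)
    xs = tuple(
        sum(1 for g, o in zip(gv, ov) if g == l and o) for l in levels
    )
    if scores is None:
        scores = tuple(float(i) for i in range(len(levels)))
    return TrendTable(ns, xs, tuple(float(s) for s in scores), labels=levels)


def subset(cohort: Cohort, predicate) -> Cohort:
    """Records satisfying a predicate, as a new cohort."""
    kept = tuple(r for r in cohort.records if predicate(r))
    if not kept:
        raise CohortError("subset is empty")
    return Cohort(kept, provenance=cohort.provenance)
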