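"""Data model and file I/O for corpora of reported DDM parameter estimates.

A *corpus* is a flat table of parameter estimates extracted from the
literature, one row per reported value, together with the article-level
reporting conventions needed to put every estimate on a common scale:
the diffusion scaling constant ``s`` the authors fixed, the RT
measurement unit, whether the row is an individual-participant or an
aggregated estimate, and which rows share a single constrained
parameter across experimental conditions.

The on-disk format is UTF-8 delimited text (comma by default, tab
accepted) with the fixed header::

    article_id, study_id, condition_id, participant_id, kind, value,
    s_reported, software, rt_unit, reporting_level, constraint_group,
    n_participants, task, population

Empty strings denote unknown/absent values.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "CorpusError",
    "SchemaError",
    "ParseError",
    "ValidationError",
    "ScalingClass",
    "ParameterKind",
    "CANONICAL_KINDS",
    "Software",
    "RTUnit",
    "ReportingLevel",
    "ParameterEstimate",
    "Corpus",
    "PlausibilityFlag",
    "read_corpus",
    "write_corpus",
    "validate_plausibility",
    "CORPUS_COLUMNS",
    "SOFTWARE_DEFAULT_S",
    "SOFTWARE_DEFAULT_UNIT",
]


class CorpusError(Exception):
    """Base class for corpus-related errors."""


class SchemaError(CorpusError):
    """The file header does not match the documented schema."""


class ParseError(CorpusError):
    """A row contains a value that cannot be parsed."""


class ValidationError(CorpusError):
    """The corpus violates a structural invariant."""


class ScalingClass(enum.Enum):
    """How a parameter responds to changes of the diffusion scale / RT unit."""

    ACCUMULATION = "accumulation"  # proportional to s; mixes space and time
    TIME = "time"                  # pure time quantity (seconds)
    DIMENSIONLESS = "dimensionless"


class ParameterKind(enum.Enum):
    """The nine reportable DDM parameters.

    ``z`` and ``s_z`` are absolute-scale variants of the relative
    (boundary-normalized) ``z_r`` and ``s_z_r``; dividing by boundary
    separation ``a`` converts one to the other.
    """

    V = "v"          # drift rate
    A = "a"          # boundary separation
    Z = "z"          # absolute starting point
    Z_R = "zr"       # relative starting point (bias), z/a
    T_ER = "ter"     # non-decision time
    S_V = "sv"       # across-trial SD of drift
    S_Z = "sz"       # across-trial range of starting point
    S_Z_R = "szr"    # s_z / a
    S_T_ER = "ster"  # across-trial range of non-decision time

    @property
    def scaling_class(self) -> ScalingClass:
        if self in _ACCUMULATION:
            return ScalingClass.ACCUMULATION
        if self in _TIME:
            return ScalingClass.TIME
        return ScalingClass.DIMENSIONLESS

    @property
    def is_variability(self) -> bool:
        return self in (ParameterKind.S_V, ParameterKind.S_Z,
                        ParameterKind.S_Z_R, ParameterKind.S_T_ER)


_ACCUMULATION = frozenset({ParameterKind.V, ParameterKind.A, ParameterKind.Z,
                           ParameterKind.S_V, ParameterKind.S_Z})
_TIME = frozenset({ParameterKind.T_ER, ParameterKind.S_T_ER})

#: The seven kinds a fully canonicalized corpus may contain
#: (absolute z / s_z have been converted to their relative forms).
CANONICAL_KINDS = (
    ParameterKind.V,
    ParameterKind.A,
    ParameterKind.Z_R,
    ParameterKind.T_ER,
    ParameterKind.S_V,
    ParameterKind.S_Z_R,
    ParameterKind.S_T_ER,
)


class Software(enum.Enum):
    DMAT = "dmat"
    HDDM = "hddm"
    FASTDM = "fastdm"
    OTHER = "other"
    UNKNOWN = "unknown"


#: Default diffusion scaling constant implied by the estimation software.
SOFTWARE_DEFAULT_S = {
    Software.DMAT: 0.1,
    Software.HDDM: 1.0,
    Software.FASTDM: 1.0,
}


class RTUnit(enum.Enum):
    SECONDS = "seconds"
    MILLISECONDS = "milliseconds"
    UNKNOWN = "unknown"


#: Default measurement unit implied by the estimation software.
SOFTWARE_DEFAULT_UNIT = {
    Software.DMAT: RTUnit.SECONDS,
    Software.HDDM: RTUnit.SECONDS,
    Software.FASTDM: RTUnit.SECONDS,
}


class ReportingLevel(enum.Enum):
    INDIVIDUAL = "individual"
    AGGREGATED = "aggregated"
    GROUP_LEVEL = "group_level"


CORPUS_COLUMNS = (
    "article_id", "study_id", "condition_id", "participant_id", "kind",
    "value", "s_reported", "software", "rt_unit", "reporting_level",
    "constraint_group", "n_participants", "task", "population",
)


@dataclass(frozen=True)
class ParameterEstimate:
    """One reported estimate, on the scale the original article used."""

    article_id: str
    study_id: str
    condition_id: str
    participant_id: Optional[str]
    kind: ParameterKind
    value: float
    s_reported: Optional[float]
    software: Software
    rt_unit: RTUnit
    reporting_level: ReportingLevel
    constraint_group: str
    n_participants: Optional[int] = None
    task: str = ""
    population: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValidationError(
                f"non-finite value {self.value!r} for {self.key()}")
        if self.s_reported is not None and not self.s_reported > 0:
            raise ValidationError(
                f"s_reported must be > 0, got {self.s_reported!r}")
        if self.reporting_level is ReportingLevel.INDIVIDUAL:
            if not self.participant_id:
                raise ValidationError(
                    "individual-level row lacks participant_id: "
                    f"{self.article_id}/{self.condition_id}")
        elif self.participant_id:
            raise ValidationError(
                f"{self.reporting_level.value} row carries participant_id "
                f"{self.participant_id!r}")
        if not self.constraint_group:
            raise ValidationError("constraint_group must be non-empty")
        if self.n_participants is not None and self.n_participants <= 0:
            raise ValidationError("n_participants must be positive")

    def key(self) -> tuple:
        return (self.article_id, self.study_id, self.condition_id,
                self.participant_id, self.kind)


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of estimates plus free-text provenance."""

    estimates: tuple[ParameterEstimate, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "estimates", tuple(self.estimates))
        seen: set = set()
        for est in self.estimates:
            k = est.key()
            if k in seen:
                raise ValidationError(f"duplicate key tuple {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.estimates)

    def __iter__(self):
        return iter(self.estimates)

    def articles(self) -> dict[str, list[ParameterEstimate]]:
        """Group estimates by article, preserving row order."""
        out: dict[str, list[ParameterEstimate]] = {}
        for est in self.estimates:
            out.setdefault(est.article_id, []).append(est)
        return out


def _parse_enum(cls, raw: str, default, row: int, column: str):
    if raw == "":
        return default
    try:
        return cls(raw)
    except ValueError:
        choices = ", ".join(m.value for m in cls)
        raise ParseError(
            f"row {row}: invalid {column} {raw!r} (expected one of {choices})"
        ) from None


def _resolve_sep(path: str, dialect: Optional[str]) -> str:
    if dialect is not None:
        return dialect
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_corpus(path, dialect: Optional[str] = None) -> Corpus:
    """Read a corpus file, validating schema and row contents.

    Parameters
    ----------
    path
        Delimited text file with the documented header.
    dialect
        Field delimiter; defaults to ``","`` (or ``"\\t"`` for ``.tsv``).

    Raises
    ------
    SchemaError
        If a mandatory column is missing.
    ParseError
        If a row holds a non-numeric value, naming the row index.
    ValidationError
        If key tuples are duplicated or row invariants are violated.
    """
    sep = _resolve_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     encoding="utf-8")
    missing = [c for c in CORPUS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in CORPUS_COLUMNS]

    estimates = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        raw_value = rec["value"]
        try:
            value = float(raw_value)
        except ValueError:
            raise ParseError(
                f"row {i}: non-numeric value {raw_value!r}") from None
        s_rep = None
        if rec["s_reported"] != "":
            try:
                s_rep = float(rec["s_reported"])
            except ValueError:
                raise ParseError(
                    f"row {i}: non-numeric s_reported "
                    f"{rec['s_reported']!r}") from None
        n_part = None
        if rec["n_participants"] != "":
            try:
                n_part = int(float(rec["n_participants"]))
            except ValueError:
                raise ParseError(
                    f"row {i}: non-numeric n_participants "
                    f"{rec['n_participants']!r}") from None
        kind = _parse_enum(ParameterKind, rec["kind"], None, i, "kind")
        if kind is None:
            raise ParseError(f"row {i}: empty kind")
        est = ParameterEstimate(
            article_id=rec["article_id"],
            study_id=rec["study_id"],
            condition_id=rec["condition_id"],
            participant_id=rec["participant_id"] or None,
            kind=kind,
            value=value,
            s_reported=s_rep,
            software=_parse_enum(Software, rec["software"],
                                 Software.UNKNOWN, i, "software"),
            rt_unit=_parse_enum(RTUnit, rec["rt_unit"],
                                RTUnit.UNKNOWN, i, "rt_unit"),
            reporting_level=_parse_enum(ReportingLevel, rec["reporting_level"],
                                        ReportingLevel.AGGREGATED, i,
                                        "reporting_level"),
            constraint_group=rec["constraint_group"],
            n_participants=n_part,
            task=rec["task"],
            population=rec["population"],
        )
        estimates.append(est)

    provenance = {"source": str(path)}
    if extra:
        provenance["extra_columns"] = {c: df[c].tolist() for c in extra}
    return Corpus(estimates=tuple(estimates), provenance=provenance)


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(x)
    return str(x)


def write_corpus(corpus: Corpus, path, dialect: Optional[str] = None) -> None:
    """Write a corpus file; ``read_corpus`` reproduces it field-for-field."""
    sep = _resolve_sep(path, dialect)
    rows = []
    for est in corpus:
        rows.append({
            "article_id": est.article_id,
            "study_id": est.study_id,
            "condition_id": est.condition_id,
            "participant_id": est.participant_id or "",
            "kind": est.kind.value,
            "value": _fmt(est.value),
            "s_reported": _fmt(est.s_reported),
            "software": "" if est.software is Software.UNKNOWN
            else est.software.value,
            "rt_unit": "" if est.rt_unit is RTUnit.UNKNOWN
            else est.rt_unit.value,
            "reporting_level": est.reporting_level.value,
            "constraint_group": est.constraint_group,
            "n_participants": _fmt(est.n_participants),
            "task": est.task,
            "population": est.population,
        })
    df = pd.DataFrame(rows, columns=list(CORPUS_COLUMNS))
    df.to_csv(path, sep=sep, index=False, encoding="utf-8")


@dataclass(frozen=True)
class PlausibilityFlag:
    """One plausibility violation; reporting only, never mutates data."""

    article_id: str
    key: tuple
    check: str
    message: str


def validate_plausibility(corpus: Corpus | Sequence,
                          check_units: bool = True) -> list[PlausibilityFlag]:
    """Screen estimates against the theoretical parameter bounds.

    Flags raised (one per violation): non-positive boundary separation,
    negative non-decision time, relative starting point or its
    variability outside [0, 1], negative variability parameters, and —
    when ``check_units`` — a per-article inconsistency between the
    inferred measurement unit of the non-decision parameters and that of
    the remaining parameters (e.g. T_er in milliseconds next to a
    boundary separation in seconds).

    Zero is attainable for non-decision time and the variability
    parameters and is therefore not flagged.
    """
    flags: list[PlausibilityFlag] = []
    ests = list(corpus)
    for est in ests:
        k, v = est.kind, est.value
        if k is ParameterKind.A and v <= 0:
            flags.append(PlausibilityFlag(
                est.article_id, est.key(), "boundary_separation_nonpositive",
                f"boundary separation negative or zero: a = {v}"))
        elif k is ParameterKind.T_ER and v < 0:
            flags.append(PlausibilityFlag(
                est.article_id, est.key(), "nondecision_negative",
                f"non-decision time negative: T_er = {v}"))
        elif k in (ParameterKind.Z_R, ParameterKind.S_Z_R) and not 0 <= v <= 1:
            flags.append(PlausibilityFlag(
                est.article_id, est.key(), "relative_outside_unit_interval",
                f"{k.value} = {v} outside [0, 1]"))
        elif k in (ParameterKind.S_V, ParameterKind.S_Z,
                   ParameterKind.S_T_ER) and v < 0:
            flags.append(PlausibilityFlag(
                est.article_id, est.key(), "variability_negative",
                f"{k.value} = {v} negative"))
        elif k is ParameterKind.Z and v < 0:
            flags.append(PlausibilityFlag(
                est.article_id, est.key(), "starting_point_negative",
                f"z = {v} negative"))
    if check_units:
        from .transforms import infer_rt_units  # late: avoid import cycle
        by_article: dict[str, list] = {}
        for est in ests:
            by_article.setdefault(est.article_id, []).append(est)
        for aid, group in by_article.items():
            inf = infer_rt_units(group)
            if (inf.ter_unit is not None and inf.other_unit is not None
                    and inf.ter_unit is not inf.other_unit):
                flags.append(PlausibilityFlag(
                    aid, (aid,), "mixed_units_within_article",
                    f"T_er inferred {inf.ter_unit.value} but remaining "
                    f"parameters inferred {inf.other_unit.value}"))
    return flags
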