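"""Canonicalization of heterogeneously reported DDM estimates.

Published diffusion-model estimates are not directly comparable across
articles: the diffusion scaling constant ``s`` differs (0.1 vs 1), RT
units differ (seconds vs milliseconds, sometimes differing *within* an
article between the non-decision parameters and the rest), starting
points are reported absolutely or relative to the boundary, drift signs
follow arbitrary response codings, and parameters constrained across
conditions are printed repeatedly. This module puts every estimate on a
single canonical scale — ``s = 1``, seconds, relative starting point,
accuracy-coded (non-negative) drift — deduplicates constrained
parameters, averages individual estimates within studies, and pools the
result into per-parameter samples.

Canonical stage order (each applied stage is appended to the row's
``transform_log``)::

    resolve_s -> infer_units -> to_seconds -> rescale_s
    -> relative_start -> accuracy_code -> plausibility
    -> dedup -> average -> mirror (bias only, at pooling)

Unit conversion of accumulation-scaled parameters follows the diffusion
scaling law with ``s`` held fixed: dividing times by ``k`` multiplies
drift-like quantities by ``sqrt(k)`` and divides distance-like
quantities by ``sqrt(k)``, which leaves the first-passage process (and
hence the expected decision time in the new unit) intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .corpus import (
    CANONICAL_KINDS,
    Corpus,
    CorpusError,
    ParameterEstimate,
    ParameterKind,
    PlausibilityFlag,
    RTUnit,
    ReportingLevel,
    ScalingClass,
    Software,
    SOFTWARE_DEFAULT_S,
    SOFTWARE_DEFAULT_UNIT,
    validate_plausibility,
)

__all__ = [
    "TransformError",
    "UnresolvableScaleError",
    "UnresolvedUnitError",
    "DomainError",
    "EmptySampleError",
    "CanonicalEstimate",
    "PooledSample",
    "UnitInference",
    "CanonicalizationResult",
    "STAGES",
    "rescale_to_unit_s",
    "expected_rt",
    "infer_rt_units",
    "convert_to_seconds",
    "to_relative_start",
    "mirror_bias",
    "accuracy_code_drift",
    "deduplicate_constrained",
    "average_individuals",
    "canonicalize_corpus",
    "pool",
]


class TransformError(CorpusError):
    """Base class for canonicalization errors."""


class UnresolvableScaleError(TransformError):
    """The diffusion scaling constant s could not be determined."""


class UnresolvedUnitError(TransformError):
    """The RT measurement unit could not be determined."""


class DomainError(TransformError):
    """An input lies outside the operation's domain."""


class EmptySampleError(TransformError):
    """Pooling produced no values."""


#: Canonical pipeline stage names, in order.
STAGES = (
    "resolve_s", "infer_units", "to_seconds", "rescale_s",
    "relative_start", "accuracy_code", "plausibility",
    "dedup", "average", "mirror",
)


@dataclass(frozen=True)
class CanonicalEstimate:
    """An estimate on the canonical s = 1, seconds scale.

    Only the seven canonical kinds may occur (absolute z / s_z have been
    converted); ``transform_log`` records every applied stage in order.
    """

    article_id: str
    study_id: str
    condition_id: str
    participant_id: Optional[str]
    kind: ParameterKind
    value: float
    reporting_level: ReportingLevel
    constraint_group: str
    n_participants: Optional[int] = None
    task: str = ""
    population: str = ""
    transform_log: tuple[str, ...] = ()

    def key(self) -> tuple:
        return (self.article_id, self.study_id, self.condition_id,
                self.participant_id, self.kind)


@dataclass(frozen=True)
class PooledSample:
    """Canonicalized, deduplicated values for one parameter kind.

    ``n`` counts the values actually pooled (post-mirroring for bias);
    ``n_pre_mirror`` preserves the pre-mirroring count for bias, since
    both counts are of interest when bias is doubled by mirroring.
    """

    kind: ParameterKind
    values: np.ndarray
    n: int
    empirical_lower: float
    empirical_upper: float
    n_pre_mirror: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if self.n != self.values.size:
            raise TransformError("n must equal the number of values")
        if self.n and not (self.empirical_lower <= self.empirical_upper):
            raise TransformError("empirical bounds out of order")


# ---------------------------------------------------------------------------
# elementary operations


def resolve_s(estimate: ParameterEstimate,
              s01_articles: Iterable[str] = ()) -> Optional[float]:
    """Determine the diffusion scaling constant for one row.

    Resolution order: explicit reported value, then the estimation
    software's default (DMAT 0.1; HDDM and fast-DM 1), then an explicit
    list of article ids known to follow the 0.1 convention. ``None``
    means unresolvable (the row is destined for logged exclusion).
    """
    if estimate.s_reported is not None:
        return estimate.s_reported
    if estimate.software in SOFTWARE_DEFAULT_S:
        return SOFTWARE_DEFAULT_S[estimate.software]
    if estimate.article_id in set(s01_articles):
        return 0.1
    return None


def rescale_to_unit_s(estimate: ParameterEstimate,
                      s_target: float = 1.0) -> ParameterEstimate:
    """Re-scale an estimate to the diffusion scale ``s = s_target``.

    Accumulation-scaled kinds (v, a, z, s_v, s_z) are proportional to s
    and are multiplied by ``s_target / s_reported``; time-only and
    dimensionless kinds are unchanged.
    """
    if estimate.s_reported is None or not estimate.s_reported > 0:
        raise UnresolvableScaleError(
            f"s unknown for {estimate.key()}; cannot re-scale")
    if estimate.kind.scaling_class is ScalingClass.ACCUMULATION:
        value = estimate.value * (s_target / estimate.s_reported)
    else:
        value = estimate.value
    return replace(estimate, value=value, s_reported=s_target)


def expected_rt(a: float, z: float, v: float) -> float:
    """Rough expected decision time E(RT) = (a - z)/v.

    Units follow the inputs; used for inferring the reporting unit.
    """
    if v == 0:
        raise DomainError("E(RT) undefined for v = 0")
    if not a > 0:
        raise DomainError(f"boundary separation must be positive, got {a}")
    if z < 0 or z > a:
        raise DomainError(f"starting point z = {z} outside [0, a = {a}]")
    return (a - z) / v


@dataclass(frozen=True)
class UnitInference:
    """Per-article unit assignment from the two-step magnitude rule."""

    ter_unit: Optional[RTUnit]    # unit of T_er and s_T_er
    other_unit: Optional[RTUnit]  # unit of the remaining parameters
    flags: tuple[str, ...] = ()
    min_e_rt: Optional[float] = None

    def unit_for(self, kind: ParameterKind) -> Optional[RTUnit]:
        if kind.scaling_class is ScalingClass.TIME:
            return self.ter_unit
        return self.other_unit


def infer_rt_units(article_estimates: Sequence[ParameterEstimate],
                   ter_threshold: float = 5.0,
                   e_rt_threshold: float = 10.0) -> UnitInference:
    """Infer the reporting unit of an article's estimates by magnitude.

    Step 1: the non-decision time unit is seconds iff the article's
    smallest reported T_er is below ``ter_threshold`` (default 5),
    milliseconds otherwise. Step 2: the remaining parameters' unit is
    seconds iff the smallest per-condition E(RT) = (a - z)/|v| is below
    ``e_rt_threshold`` (default 10), milliseconds otherwise (z derived
    as z_r * a when only bias is reported). The minimum across
    conditions is used, the conservative choice against misclassifying
    slow-RT studies. Assignments may legitimately differ between the two
    groups within one article.

    Unresolvable steps are flagged and left ``None`` (callers fall back
    to the declared or software-default unit).
    """
    ests = list(article_estimates)
    flags: list[str] = []

    ters = [e.value for e in ests if e.kind is ParameterKind.T_ER]
    if ters:
        ter_unit = (RTUnit.SECONDS if min(ters) < ter_threshold
                    else RTUnit.MILLISECONDS)
    else:
        ter_unit = None
        flags.append("step1_unresolvable_no_ter")

    # representative |value| per (condition, kind), median over rows
    per_cond: dict[str, dict[ParameterKind, list[float]]] = {}
    for e in ests:
        per_cond.setdefault(e.condition_id, {}).setdefault(
            e.kind, []).append(e.value)
    e_rts: list[float] = []
    for cond, kinds in per_cond.items():
        def med(k, absolute=False):
            vals = kinds.get(k)
            if not vals:
                return None
            arr = np.abs(vals) if absolute else np.asarray(vals)
            return float(np.median(arr))
        a = med(ParameterKind.A)
        # drift signs follow arbitrary response codings; magnitude matters
        v = med(ParameterKind.V, absolute=True)
        z = med(ParameterKind.Z)
        if z is None:
            zr = med(ParameterKind.Z_R)
            if zr is not None and a is not None:
                z = zr * a
        if a is None or v is None or v == 0:
            continue
        if z is None:
            z = 0.5 * a  # unbiased default when no starting point reported
        if not (a > 0 and 0 <= z <= a):
            continue
        e_rts.append((a - z) / abs(v))
    if e_rts:
        min_e_rt = min(e_rts)
        other_unit = (RTUnit.SECONDS if min_e_rt < e_rt_threshold
                      else RTUnit.MILLISECONDS)
    else:
        min_e_rt = None
        other_unit = None
        flags.append("step2_unresolvable_no_triple")

    return UnitInference(ter_unit=ter_unit, other_unit=other_unit,
                         flags=tuple(flags), min_e_rt=min_e_rt)


def convert_to_seconds(estimate: ParameterEstimate,
                       unit: RTUnit,
                       k: float = 1000.0) -> ParameterEstimate:
    """Convert one estimate from ``unit`` to seconds.

    For milliseconds (time ratio ``k``, default 1000): pure time
    quantities are divided by k; with the diffusion scale s held fixed,
    drift-like parameters (v, s_v) are multiplied by sqrt(k) and
    distance-like parameters (a, z, s_z) divided by sqrt(k);
    dimensionless kinds are unchanged. E(RT) computed after conversion
    equals E(RT) before conversion divided by k.
    """
    if unit is RTUnit.SECONDS:
        return estimate
    if unit is not RTUnit.MILLISECONDS:
        raise UnresolvedUnitError(
            f"cannot convert {estimate.key()} from unresolved unit")
    if not k > 0:
        raise DomainError("time-unit ratio k must be positive")
    sk = math.sqrt(k)
    kind = estimate.kind
    if kind.scaling_class is ScalingClass.TIME:
        value = estimate.value / k
    elif kind in (ParameterKind.V, ParameterKind.S_V):
        value = estimate.value * sk
    elif kind in (ParameterKind.A, ParameterKind.Z, ParameterKind.S_Z):
        value = estimate.value / sk
    else:  # dimensionless
        value = estimate.value
    return replace(estimate, value=value, rt_unit=RTUnit.SECONDS)


def to_relative_start(z: float, a: float) -> float:
    """Relative starting point (bias) z_r = z/a; also maps s_z to s_z_r."""
    if not a > 0:
        raise DomainError(f"boundary separation must be positive, got {a}")
    if z < 0 or z > a:
        raise DomainError(f"z = {z} outside [0, a = {a}]")
    return z / a


def mirror_bias(values) -> np.ndarray:
    """Mirror a collection of bias values: {x} -> {x} U {1 - x}.

    Because the mapping of response options to boundaries is arbitrary
    across articles, the direction of bias is not commensurable; the
    mirrored multiset removes direction while preserving variability.
    The output interleaves each x with its complement, doubles the size,
    and has mean 0.5. Applies to bias (z_r) only.
    """
    x = np.asarray(list(values), float)
    if x.size == 0:
        return x
    if np.any((x < 0) | (x > 1)):
        raise DomainError("bias values must lie in [0, 1]")
    out = np.empty(2 * x.size, float)
    out[0::2] = x
    out[1::2] = 1.0 - x
    return out


def accuracy_code_drift(values) -> np.ndarray:
    """Absolute values of drift rates (accuracy coding), order preserved."""
    return np.abs(np.asarray(list(values), float))


def _dedup_sort_key(e: CanonicalEstimate) -> tuple:
    return (e.article_id, e.study_id, e.condition_id,
            e.participant_id or "", e.kind.value)


def deduplicate_constrained(
        estimates: Sequence[CanonicalEstimate]) -> list[CanonicalEstimate]:
    """Keep one representative per constrained parameter.

    Rows sharing (study_id, kind, constraint_group) — and, for
    individual rows, participant_id — report a single free parameter
    repeated across conditions; only the first occurrence after a
    deterministic (article, study, condition) sort is retained. Never
    increases the count.
    """
    ordered = sorted(estimates, key=_dedup_sort_key)
    seen: set = set()
    out: list[CanonicalEstimate] = []
    for e in ordered:
        key = (e.study_id, e.kind, e.constraint_group, e.participant_id)
        if key in seen:
            continue
        seen.add(key)
        out.append(replace(e, transform_log=e.transform_log + ("dedup",)))
    return out


def average_individuals(
        estimates: Sequence[CanonicalEstimate]) -> list[CanonicalEstimate]:
    """Average individual estimates within (study, condition, kind).

    Each group of individual-level rows is replaced by one aggregated
    row holding the arithmetic mean; aggregated and group-level rows
    pass through untouched. All rows are weighted equally downstream.
    Never increases the count.
    """
    groups: dict[tuple, list[CanonicalEstimate]] = {}
    out: list[CanonicalEstimate] = []
    order: list[tuple] = []
    for e in estimates:
        if e.reporting_level is ReportingLevel.INDIVIDUAL:
            gk = (e.study_id, e.condition_id, e.kind, e.constraint_group)
            if gk not in groups:
                groups[gk] = []
                order.append(("group", gk))
            groups[gk].append(e)
        else:
            order.append(("row", e))
    for tag, item in order:
        if tag == "row":
            out.append(item)
            continue
        members = groups[item]
        mean = float(np.mean([m.value for m in members]))
        first = members[0]
        out.append(replace(
            first, value=mean, participant_id=None,
            reporting_level=ReportingLevel.AGGREGATED,
            n_participants=first.n_participants or len(members),
            transform_log=first.transform_log + ("average",)))
    return out


# ---------------------------------------------------------------------------
# orchestration


@dataclass(frozen=True)
class ExclusionRecord:
    key: tuple
    stage: str
    reason: str


@dataclass
class CanonicalizationResult:
    """Canonical rows plus the audit trail of what happened to every row."""

    canonical: list[CanonicalEstimate]
    excluded: list[ExclusionRecord]
    flags: list[PlausibilityFlag]
    audit: dict[str, int]
    article_conventions: dict[str, dict]

    def audit_log(self) -> list[str]:
        lines = [f"{stage}: {count}" for stage, count in self.audit.items()]
        lines += [f"excluded[{r.stage}] {r.key}: {r.reason}"
                  for r in self.excluded]
        return lines


def canonicalize_corpus(corpus: Corpus,
                        s01_articles: Iterable[str] = (),
                        k: float = 1000.0,
                        exclude_implausible: bool = True,
                        ) -> CanonicalizationResult:
    """Run the full canonicalization pipeline on a raw corpus.

    Stages, in order: resolve the diffusion scale s per row (rows with
    unresolvable s are excluded, logged); infer per-article RT units by
    the two-step magnitude rule (falling back to declared or
    software-default units); convert to seconds; re-scale to s = 1;
    convert absolute starting points to relative ones using the matched
    boundary separation of the same study/condition; accuracy-code
    drift; screen against theoretical bounds (violations excluded when
    ``exclude_implausible``, always logged); deduplicate constrained
    parameters; average individual estimates.
    """
    excluded: list[ExclusionRecord] = []
    audit: dict[str, int] = {"read": len(corpus)}

    # stage: resolve_s
    resolved: list[ParameterEstimate] = []
    logs: dict[tuple, tuple[str, ...]] = {}
    for est in corpus:
        s = resolve_s(est, s01_articles)
        if s is None:
            excluded.append(ExclusionRecord(
                est.key(), "resolve_s", "scaling constant unresolvable"))
            continue
        resolved.append(replace(est, s_reported=s))
        logs[est.key()] = ("resolve_s",)
    audit["excluded_unknown_s"] = len(corpus) - len(resolved)

    # stage: infer_units (per article, on reported magnitudes)
    by_article: dict[str, list[ParameterEstimate]] = {}
    for est in resolved:
        by_article.setdefault(est.article_id, []).append(est)
    conventions: dict[str, dict] = {}
    unit_of: dict[tuple, RTUnit] = {}
    for aid, group in by_article.items():
        inf = infer_rt_units(group)
        conventions[aid] = {
            "s": {e.key(): e.s_reported for e in group},
            "ter_unit": inf.ter_unit.value if inf.ter_unit else None,
            "other_unit": inf.other_unit.value if inf.other_unit else None,
            "unit_flags": list(inf.flags),
        }
        for est in group:
            unit = inf.unit_for(est.kind)
            if unit is None:
                if est.rt_unit is not RTUnit.UNKNOWN:
                    unit = est.rt_unit
                else:
                    unit = SOFTWARE_DEFAULT_UNIT.get(est.software,
                                                     RTUnit.SECONDS)
            unit_of[est.key()] = unit
            logs[est.key()] += ("infer_units",)

    # stages: to_seconds, rescale_s
    canonical_raw: list[ParameterEstimate] = []
    for est in resolved:
        est2 = convert_to_seconds(est, unit_of[est.key()], k=k)
        est3 = rescale_to_unit_s(est2, 1.0)
        logs[est.key()] += ("to_seconds", "rescale_s")
        canonical_raw.append(est3)

    # stage: relative_start (z -> z_r, s_z -> s_z_r using matched a)
    a_lookup: dict[tuple, float] = {}
    for est in canonical_raw:
        if est.kind is ParameterKind.A:
            a_lookup.setdefault(
                (est.study_id, est.condition_id, est.participant_id),
                est.value)
    converted: list[CanonicalEstimate] = []
    for est in canonical_raw:
        log = logs[est.key()]
        kind, value = est.kind, est.value
        if kind in (ParameterKind.Z, ParameterKind.S_Z):
            a = a_lookup.get(
                (est.study_id, est.condition_id, est.participant_id))
            if a is None:
                a = a_lookup.get((est.study_id, est.condition_id, None))
            if a is None:
                excluded.append(ExclusionRecord(
                    est.key(), "relative_start",
                    "no matching boundary separation for absolute z"))
                continue
            try:
                if kind is ParameterKind.Z:
                    value = to_relative_start(value, a)
                    kind = ParameterKind.Z_R
                else:
                    if not a > 0:
                        raise DomainError("a must be positive")
                    value = value / a
                    kind = ParameterKind.S_Z_R
            except DomainError as err:
                excluded.append(ExclusionRecord(
                    est.key(), "relative_start", str(err)))
                continue
            log += ("relative_start",)
        if kind is ParameterKind.V:
            value = abs(value)
            log += ("accuracy_code",)
        converted.append(CanonicalEstimate(
            article_id=est.article_id, study_id=est.study_id,
            condition_id=est.condition_id,
            participant_id=est.participant_id, kind=kind, value=value,
            reporting_level=est.reporting_level,
            constraint_group=est.constraint_group,
            n_participants=est.n_participants, task=est.task,
            population=est.population, transform_log=log))
    audit["canonical_scale"] = len(converted)

    # stage: plausibility
    flags = [f for f in validate_plausibility(converted, check_units=False)]
    if exclude_implausible:
        flagged_keys = {f.key for f in flags}
        kept = []
        for e in converted:
            if e.key() in flagged_keys:
                excluded.append(ExclusionRecord(
                    e.key(), "plausibility", "outside theoretical bounds"))
            else:
                kept.append(replace(
                    e, transform_log=e.transform_log + ("plausibility",)))
        converted = kept
    audit["excluded_implausible"] = len(
        [r for r in excluded if r.stage == "plausibility"])
    audit["plausible"] = len(converted)

    # stages: dedup, average
    deduped = deduplicate_constrained(converted)
    audit["deduplicated"] = len(deduped)
    averaged = average_individuals(deduped)
    audit["averaged"] = len(averaged)

    return CanonicalizationResult(
        canonical=averaged, excluded=excluded, flags=flags, audit=audit,
        article_conventions=conventions)


def pool(canonical: Sequence[CanonicalEstimate] | CanonicalizationResult,
         kind: ParameterKind,
         task: Optional[str] = None,
         population: Optional[str] = None) -> PooledSample:
    """Pool canonicalized values of one kind into an empirical sample.

    Optional task/population tags restrict rows by equality before
    pooling. Bias (z_r) is mirrored here, doubling the count; the
    pre-mirror count is preserved. Raises ``EmptySampleError`` when
    nothing survives filtering.
    """
    if isinstance(canonical, CanonicalizationResult):
        canonical = canonical.canonical
    rows = [e for e in canonical if e.kind is kind]
    if task is not None:
        rows = [e for e in rows if e.task == task]
    if population is not None:
        rows = [e for e in rows if e.population == population]
    if not rows:
        raise EmptySampleError(
            f"no {kind.value} values after filtering "
            f"(task={task!r}, population={population!r})")
    values = np.array([e.value for e in rows], float)
    n_pre = None
    if kind is ParameterKind.Z_R:
        n_pre = values.size
        values = mirror_bias(values)
    return PooledSample(
        kind=kind, values=values, n=values.size,
        empirical_lower=float(values.min()),
        empirical_upper=float(values.max()),
        n_pre_mirror=n_pre)
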