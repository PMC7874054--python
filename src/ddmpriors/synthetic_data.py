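"""Synthetic corpora of DDM estimates with known ground truth.

The generator draws canonical-scale parameter values (s = 1, seconds,
relative starting point, non-negative drift) from configurable "true"
prior distributions and then *un-canonicalizes* them article by
article, emulating the reporting heterogeneity found in the published
literature: a fraction of articles report on the s = 0.1 scale, a
fraction in milliseconds (including the dialect where only the
non-decision parameters are in milliseconds), a fraction report
individual-participant estimates, some parameters are constrained
across conditions and printed repeatedly, bias is reported with an
arbitrary direction, drift signs follow arbitrary response codings,
and a small outlier fraction is multiplicatively contaminated.

Because every canonical value is recorded in a ground-truth ledger,
the full canonicalization pipeline can be checked end to end: with no
outliers and correctly re-inferred conventions it must recover the
ground truth to floating-point accuracy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np

from .corpus import (
    Corpus,
    ParameterEstimate,
    ParameterKind,
    RTUnit,
    ReportingLevel,
    ScalingClass,
    Software,
)
from .distfit import DistributionSpec, Family, MixtureSpec, Spec
from . import transforms

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "GroundTruth",
    "RoundTripReport",
    "default_true_priors",
    "generate_corpus",
    "round_trip_check",
]


class ConfigError(Exception):
    """Inconsistent generator configuration."""


def default_true_priors() -> dict[ParameterKind, DistributionSpec]:
    """Default generating distributions for the seven canonical kinds.

    These are the informative priors produced by the published-literature
    synthesis: the selected family (dominant mixture component where the
    winner was a mixture) per parameter, on the canonical scale.
    """
    tn = Family.TRUNCATED_NORMAL
    tt = Family.TRUNCATED_T
    inf = math.inf
    return {
        ParameterKind.V: DistributionSpec(
            tn, {"location": 1.76, "scale": 1.51}, 0.0, inf),
        ParameterKind.A: DistributionSpec(
            Family.GAMMA, {"shape": 11.69, "scale": 0.12}, 0.0, inf),
        ParameterKind.Z_R: DistributionSpec(
            tt, {"location": 0.5, "scale": 0.05, "df": 1.85}, 0.0, 1.0),
        ParameterKind.T_ER: DistributionSpec(
            tt, {"location": 0.44, "scale": 0.08, "df": 1.32}, 0.0, inf),
        ParameterKind.S_V: DistributionSpec(
            tn, {"location": 1.36, "scale": 0.69}, 0.0, inf),
        ParameterKind.S_Z_R: DistributionSpec(
            tn, {"location": 0.33, "scale": 0.22}, 0.0, 1.0),
        ParameterKind.S_T_ER: DistributionSpec(
            tt, {"location": 0.17, "scale": 0.04, "df": 0.88}, 0.0, inf),
    }


#: probability that a generated article reports s explicitly
#: (the remainder carry only an estimation-software tag)
EXPLICIT_S_RATE = 0.7
#: probability that an emitted drift value has its sign flipped
#: (response coding with an arbitrary boundary assignment)
DRIFT_SIGN_FLIP_RATE = 0.1

_TASKS = (("lexical decision", 0.2), ("random dot motion", 0.25),
          ("recognition memory", 0.1), ("other", 0.45))
_POPULATIONS = (("non-clinical", 0.8), ("clinical", 0.2))


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Proportions emulate the reporting heterogeneity of the surveyed
    literature; ``true_priors`` maps each canonical kind to its
    generating density (defaults: the published synthesis priors).
    """

    n_articles: int = 158
    conditions_per_study: tuple[int, int] = (1, 4)
    participants_per_study: tuple[int, int] = (10, 40)
    true_priors: Optional[Mapping[ParameterKind, Spec]] = None
    fraction_s01: float = 0.4
    fraction_ms: float = 0.15
    fraction_ter_ms_only: float = 0.10
    fraction_individual: float = 0.05
    constrained_kinds: frozenset = frozenset(
        {ParameterKind.S_V, ParameterKind.S_Z_R, ParameterKind.S_T_ER})
    outlier_rate: float = 0.02
    outlier_scale: float = 3.0
    seed: int = 0
    task_label: Optional[str] = None      # force one task tag on all articles
    article_prefix: str = "A"             # id prefix, for merging corpora

    def __post_init__(self) -> None:
        for name in ("fraction_s01", "fraction_ms", "fraction_ter_ms_only",
                     "fraction_individual", "outlier_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.fraction_ms + self.fraction_ter_ms_only > 1:
            raise ConfigError(
                "fraction_ms + fraction_ter_ms_only must not exceed 1")
        if self.n_articles < 0:
            raise ConfigError("n_articles must be non-negative")
        for name in ("conditions_per_study", "participants_per_study"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ConfigError(f"{name} range {lo}..{hi} is empty")
        self.constrained_kinds = frozenset(
            ParameterKind(k) if isinstance(k, str) else k
            for k in self.constrained_kinds)

    def priors(self) -> Mapping[ParameterKind, Spec]:
        return self.true_priors or default_true_priors()


@dataclass
class GroundTruth:
    """Canonical values and conventions behind a generated corpus.

    ``expected_canonical`` maps ``"study|condition|kind"`` to the value
    the canonicalization pipeline should recover after deduplication and
    averaging (constrained kinds keyed at their first condition).
    """

    conventions: dict[str, dict]
    expected_canonical: dict[str, float]
    contaminated_articles: list[str]
    sign_flipped_rows: list[str]

    @staticmethod
    def key(study_id: str, condition_id: str, kind: ParameterKind) -> str:
        return f"{study_id}|{condition_id}|{kind.value}"

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({
                "conventions": self.conventions,
                "expected_canonical": self.expected_canonical,
                "contaminated_articles": self.contaminated_articles,
                "sign_flipped_rows": self.sign_flipped_rows,
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(**d)


def _choice(rng: np.random.Generator, table) -> str:
    labels = [t[0] for t in table]
    probs = np.array([t[1] for t in table], float)
    return str(rng.choice(labels, p=probs / probs.sum()))


def _inverse_transform(value: float, kind: ParameterKind,
                       in_ms: bool, s01: bool, k: float = 1000.0) -> float:
    """Map a canonical value to the article's reported scale."""
    sk = math.sqrt(k)
    if in_ms:
        if kind.scaling_class is ScalingClass.TIME:
            value *= k
        elif kind in (ParameterKind.V, ParameterKind.S_V):
            value /= sk
        elif kind is ParameterKind.A:
            value *= sk
    if s01 and kind.scaling_class is ScalingClass.ACCUMULATION:
        value *= 0.1
    return value


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus and its ground-truth ledger.

    Deterministic in ``config.seed``: identical configs produce
    byte-identical corpora.
    """
    rng = np.random.default_rng(config.seed)
    priors = config.priors()
    kinds = list(priors)

    rows: list[ParameterEstimate] = []
    conventions: dict[str, dict] = {}
    expected: dict[str, float] = {}
    contaminated: set[str] = set()
    sign_flipped: list[str] = []

    for i in range(config.n_articles):
        aid = f"{config.article_prefix}{i:04d}"
        sid = f"{aid}_s1"
        n_cond = int(rng.integers(config.conditions_per_study[0],
                                  config.conditions_per_study[1] + 1))
        n_part = int(rng.integers(config.participants_per_study[0],
                                  config.participants_per_study[1] + 1))
        u = rng.random()
        if u < config.fraction_ms:
            dialect = "ms"
        elif u < config.fraction_ms + config.fraction_ter_ms_only:
            dialect = "ter_ms"
        else:
            dialect = "s"
        s01 = bool(rng.random() < config.fraction_s01)
        individual = bool(rng.random() < config.fraction_individual)
        explicit_s = bool(rng.random() < EXPLICIT_S_RATE)
        software = Software.DMAT if (s01 and not explicit_s) else (
            Software.HDDM if not explicit_s else Software.OTHER)
        task = config.task_label or _choice(rng, _TASKS)
        population = _choice(rng, _POPULATIONS)
        side_high = bool(rng.random() < 0.5)  # direction of reported bias

        conds = [f"c{j + 1:02d}" for j in range(n_cond)]
        conventions[aid] = {
            "s": 0.1 if s01 else 1.0, "dialect": dialect,
            "individual": individual, "n_conditions": n_cond,
            "n_participants": n_part, "task": task, "population": population}

        n_units = n_part if individual else 1
        for kind in kinds:
            prior = priors[kind]
            constrained = kind in config.constrained_kinds
            n_cells = 1 if constrained else n_cond
            draws = prior.rvs(n_cells * n_units, rng).reshape(
                n_cells, n_units)
            if kind is ParameterKind.Z_R:
                # fold to the study's arbitrarily chosen direction
                folded = 0.5 + np.abs(draws - 0.5)
                draws = folded if side_high else 1.0 - folded
            for ci in range(n_cells):
                cond = conds[0] if constrained else conds[ci]
                expected[GroundTruth.key(sid, cond, kind)] = float(
                    np.mean(draws[ci]))
            group = "g_const" if constrained else None
            for ci in range(n_cells):
                cells = conds if constrained else [conds[ci]]
                for cond in cells:
                    cgroup = group or f"g_{cond}"
                    for pi in range(n_units):
                        canon = float(draws[ci, pi])
                        in_ms = dialect == "ms" or (
                            dialect == "ter_ms"
                            and kind.scaling_class is ScalingClass.TIME)
                        val = _inverse_transform(canon, kind, in_ms, s01)
                        if rng.random() < config.outlier_rate:
                            val *= config.outlier_scale
                            contaminated.add(aid)
                        row_id = f"{sid}|{cond}|{kind.value}|p{pi}"
                        if (kind is ParameterKind.V
                                and rng.random() < DRIFT_SIGN_FLIP_RATE):
                            val = -val
                            sign_flipped.append(row_id)
                        rows.append(ParameterEstimate(
                            article_id=aid, study_id=sid, condition_id=cond,
                            participant_id=(f"p{pi + 1:02d}" if individual
                                            else None),
                            kind=kind, value=val,
                            s_reported=(0.1 if s01 else 1.0) if explicit_s
                            else None,
                            software=software, rt_unit=RTUnit.UNKNOWN,
                            reporting_level=(ReportingLevel.INDIVIDUAL
                                             if individual
                                             else ReportingLevel.AGGREGATED),
                            constraint_group=cgroup, n_participants=n_part,
                            task=task, population=population))

    corpus = Corpus(estimates=tuple(rows),
                    provenance={"generator": "ddmpriors.synthetic_data",
                                "seed": config.seed,
                                "n_articles": config.n_articles})
    truth = GroundTruth(conventions=conventions, expected_canonical=expected,
                        contaminated_articles=sorted(contaminated),
                        sign_flipped_rows=sign_flipped)
    return corpus, truth


@dataclass
class RoundTripReport:
    """Discrepancies between pipeline-recovered values and ground truth.

    ``max_discrepancy`` is taken over articles whose reporting
    conventions were correctly re-inferred and that carry no outlier
    contamination (with no outliers and successful unit inference it is
    zero up to floating tolerance); ``max_discrepancy_all`` ignores the
    conditioning.
    """

    max_discrepancy: float
    max_discrepancy_all: float
    n_compared: int
    n_convention_mismatch: int
    n_contaminated_articles: int
    n_excluded_rows: int


def _conventions_recovered(truth_conv: dict, pipe_conv: dict) -> bool:
    dialect = truth_conv["dialect"]
    want_ter = "milliseconds" if dialect in ("ms", "ter_ms") else "seconds"
    want_other = "milliseconds" if dialect == "ms" else "seconds"
    return (pipe_conv.get("ter_unit") == want_ter
            and pipe_conv.get("other_unit") == want_other)


def round_trip_check(config: GeneratorConfig) -> RoundTripReport:
    """Generate a corpus, canonicalize it, and compare with ground truth."""
    corpus, truth = generate_corpus(config)
    if len(corpus) == 0:
        return RoundTripReport(0.0, 0.0, 0, 0, 0, 0)
    result = transforms.canonicalize_corpus(corpus)
    recovered = {GroundTruth.key(e.study_id, e.condition_id, e.kind): e.value
                 for e in result.canonical}
    mismatched_articles = {
        aid for aid, conv in truth.conventions.items()
        if not _conventions_recovered(conv,
                                      result.article_conventions.get(aid, {}))}
    contaminated = set(truth.contaminated_articles)
    max_clean = 0.0
    max_all = 0.0
    n_compared = 0
    for key, true_val in truth.expected_canonical.items():
        if key not in recovered:
            continue
        diff = abs(recovered[key] - true_val)
        aid = key.split("|")[0].rsplit("_s1", 1)[0]
        max_all = max(max_all, diff)
        if aid not in mismatched_articles and aid not in contaminated:
            n_compared += 1
            max_clean = max(max_clean, diff)
    return RoundTripReport(
        max_discrepancy=max_clean, max_discrepancy_all=max_all,
        n_compared=n_compared,
        n_convention_mismatch=len(mismatched_articles),
        n_contaminated_articles=len(contaminated),
        n_excluded_rows=len(result.excluded))
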