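"""End-to-end orchestration: corpus -> canonicalization -> fitted priors.

``run_review`` executes the whole parameter review on a corpus of
reported estimates: canonicalize to the s = 1, seconds scale, pool each
parameter kind into an empirical distribution, fit the candidate
(truncated/mixture) densities by constrained maximum likelihood, select
per kind by Akaike weight, and assemble a prior table — one proposed
single-family prior per parameter, with truncation bounds, empirical
extrema, sample sizes and a full audit of the exclusion bookkeeping.

Also provided: JSON/CSV serialization of the prior table, sampling from
a fitted prior, and a small prior-predictive first-passage simulator
for sanity-checking that sampled parameter combinations produce
sensible RTs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import CANONICAL_KINDS, Corpus, ParameterKind, read_corpus
from . import transforms
from .transforms import (CanonicalizationResult, EmptySampleError,
                         PooledSample, canonicalize_corpus, pool)
from .distfit import (DistributionSpec, Family, FitResult, MixtureSpec,
                      PriorSpec, SpecError, candidate_set, dominant_component,
                      fit_candidates, select_best)

__all__ = [
    "ReviewOptions",
    "PriorTable",
    "run_review",
    "serialize_priors",
    "load_prior_table",
    "sample_prior",
    "prior_predictive_rt",
    "PredictiveSummary",
    "load_deposited_corpus",
    "PRIOR_CSV_COLUMNS",
]


@dataclass
class ReviewOptions:
    """Tunable settings for one review run."""

    task: Optional[str] = None
    population: Optional[str] = None
    n_starts: int = 10
    seed: int = 0
    min_n: int = 10           # smallest pooled sample worth fitting
    s01_articles: tuple = ()  # article ids following the s = 0.1 convention


@dataclass
class PriorTable:
    """The assembled review output: one prior row per parameter kind.

    ``rows`` maps each canonical kind to its PriorSpec, or to ``None``
    with the reason recorded in ``unfit`` (e.g. too few pooled values).
    ``reports`` holds the full per-kind candidate tables (family,
    parameters, log-likelihood, k, AIC, wAIC, convergence).
    """

    rows: dict[ParameterKind, Optional[PriorSpec]]
    filters: dict
    audit: dict[str, int]
    unfit: dict[ParameterKind, str] = field(default_factory=dict)
    reports: dict[ParameterKind, list[dict]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        rows = {}
        for kind, prior in self.rows.items():
            rows[kind.value] = None if prior is None else _prior_to_dict(prior)
        return {
            "rows": rows,
            "filters": self.filters,
            "audit": self.audit,
            "unfit": {k.value: v for k, v in self.unfit.items()},
            "reports": {k.value: v for k, v in self.reports.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorTable":
        rows = {ParameterKind(k): (None if v is None else _prior_from_dict(v))
                for k, v in d["rows"].items()}
        return cls(rows=rows, filters=d.get("filters", {}),
                   audit=d.get("audit", {}),
                   unfit={ParameterKind(k): v
                          for k, v in d.get("unfit", {}).items()},
                   reports={ParameterKind(k): v
                            for k, v in d.get("reports", {}).items()})


def _spec_to_dict(spec: DistributionSpec) -> dict:
    return {"family": spec.family.value, "params": dict(spec.params),
            "lower": spec.lower,
            "upper": None if math.isinf(spec.upper) else spec.upper}


def _spec_from_dict(d: dict) -> DistributionSpec:
    return DistributionSpec(
        family=Family(d["family"]), params=dict(d["params"]),
        lower=d["lower"],
        upper=math.inf if d["upper"] is None else d["upper"])


def _prior_to_dict(prior: PriorSpec) -> dict:
    return {
        "kind": prior.kind.value if prior.kind else None,
        "distribution": _spec_to_dict(prior.distribution),
        "mixture_weight": prior.mixture_weight,
        "n": prior.n,
        "empirical_lower": prior.empirical_lower,
        "empirical_upper": prior.empirical_upper,
        "source_template": prior.source_template,
    }


def _prior_from_dict(d: dict) -> PriorSpec:
    return PriorSpec(
        kind=ParameterKind(d["kind"]) if d["kind"] else None,
        distribution=_spec_from_dict(d["distribution"]),
        mixture_weight=d["mixture_weight"], n=d["n"],
        empirical_lower=d["empirical_lower"],
        empirical_upper=d["empirical_upper"],
        source_template=d.get("source_template", ""))


def run_review(corpus: Corpus,
               options: Optional[ReviewOptions] = None) -> PriorTable:
    """Run the full parameter review on a raw corpus.

    Deterministic given ``options.seed``. Kinds whose pooled sample is
    smaller than ``options.min_n`` are marked unfit-able rather than
    fitted.
    """
    opts = options or ReviewOptions()
    result = canonicalize_corpus(corpus, s01_articles=opts.s01_articles)
    audit = dict(result.audit)

    rows: dict[ParameterKind, Optional[PriorSpec]] = {}
    unfit: dict[ParameterKind, str] = {}
    reports: dict[ParameterKind, list[dict]] = {}
    ss = np.random.SeedSequence(entropy=opts.seed)
    kind_seeds = {k: int(s.generate_state(1)[0] % (2 ** 31))
                  for k, s in zip(CANONICAL_KINDS,
                                  ss.spawn(len(CANONICAL_KINDS)))}
    for kind in CANONICAL_KINDS:
        try:
            sample = pool(result, kind, task=opts.task,
                          population=opts.population)
        except EmptySampleError:
            rows[kind] = None
            unfit[kind] = "no pooled values"
            continue
        audit[f"pooled_{kind.value}"] = sample.n
        if sample.n < opts.min_n:
            rows[kind] = None
            unfit[kind] = (f"only {sample.n} pooled values "
                           f"(minimum {opts.min_n})")
            continue
        fits = fit_candidates(sample, kind, n_starts=opts.n_starts,
                              seed=kind_seeds[kind])
        reports[kind] = [_fit_report_row(f) for f in fits]
        best = select_best(fits)
        rows[kind] = dominant_component(best, kind=kind, sample=sample)
    return PriorTable(
        rows=rows,
        filters={"task": opts.task, "population": opts.population,
                 "seed": opts.seed, "n_starts": opts.n_starts,
                 "min_n": opts.min_n},
        audit=audit, unfit=unfit, reports=reports)


def _fit_report_row(fit: FitResult) -> dict:
    spec = fit.spec
    if isinstance(spec, MixtureSpec):
        params = {"weight": spec.weight,
                  "component1": _spec_to_dict(spec.component1),
                  "component2": _spec_to_dict(spec.component2)}
    elif isinstance(spec, DistributionSpec):
        params = _spec_to_dict(spec)
    else:
        params = None
    return {"family": fit.name, "params": params,
            "loglik": fit.loglik if math.isfinite(fit.loglik) else None,
            "k": fit.k_free,
            "aic": fit.aic if math.isfinite(fit.aic) else None,
            "waic": fit.waic, "converged": fit.converged}


PRIOR_CSV_COLUMNS = ("kind", "N", "distribution", "weight", "location_shape",
                     "scale", "df", "t_lb", "t_ub", "e_lb", "e_ub")


def _csv_row(kind: ParameterKind, prior: Optional[PriorSpec]) -> dict:
    if prior is None:
        return {c: (kind.value if c == "kind" else "")
                for c in PRIOR_CSV_COLUMNS}
    spec = prior.distribution
    p = spec.params
    loc_shape = p.get("location", p.get("shape", p.get("meanlog")))
    scale = p.get("scale", p.get("sdlog"))
    return {
        "kind": kind.value, "N": prior.n, "distribution": spec.family.value,
        "weight": "" if prior.mixture_weight is None
        else prior.mixture_weight,
        "location_shape": loc_shape, "scale": scale,
        "df": p.get("df", ""),
        "t_lb": spec.lower,
        "t_ub": "inf" if math.isinf(spec.upper) else spec.upper,
        "e_lb": prior.empirical_lower, "e_ub": prior.empirical_upper,
    }


def serialize_priors(table: PriorTable, path, format: str = "json") -> None:
    """Write the prior table; JSON round-trips losslessly via
    ``load_prior_table``."""
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(table.to_dict(), fh, indent=1, sort_keys=True)
    elif format == "csv":
        rows = [_csv_row(kind, table.rows.get(kind))
                for kind in CANONICAL_KINDS]
        pd.DataFrame(rows, columns=list(PRIOR_CSV_COLUMNS)).to_csv(
            path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def load_prior_table(path) -> PriorTable:
    with open(path, encoding="utf-8") as fh:
        return PriorTable.from_dict(json.load(fh))


def sample_prior(prior: PriorSpec, n: int, seed: int = 0) -> np.ndarray:
    """Draw n values from a fitted prior (truncated, renormalized)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    return prior.distribution.rvs(n, rng)


@dataclass
class PredictiveSummary:
    """Summaries of simulated prior-predictive RT/choice data."""

    mean_rt: float
    accuracy: float        # fraction of upper-boundary (correct) responses
    quantiles: dict[float, float]
    n_trials: int
    n_censored: int        # trials still undecided at max_time


def prior_predictive_rt(draws,
                        noise: float = 1.0,
                        dt: float = 1e-4,
                        seed: int = 0,
                        max_time: float = 30.0) -> PredictiveSummary:
    """Simulate first-passage RTs for sampled parameter combinations.

    ``draws`` is an array of shape (n, 4) with columns (v, a, z_r,
    T_er), or a mapping with those keys. Evidence follows an
    Euler-discretized diffusion with Gaussian increments of mean
    ``v * dt`` and SD ``noise * sqrt(dt)``, starting at ``z_r * a`` and
    absorbing at 0 or ``a``; RT is the first-passage time plus T_er.
    One trial is simulated per parameter vector.

    With ``noise = 0`` the process is deterministic and the RT is
    computed analytically: T_er + (a - z)/v for positive drift (upper
    boundary), T_er + z/|v| for negative drift.
    """
    if isinstance(draws, dict):
        v = np.asarray(draws["v"], float)
        a = np.asarray(draws["a"], float)
        zr = np.asarray(draws["z_r"], float)
        ter = np.asarray(draws["ter"], float)
    else:
        arr = np.asarray(draws, float)
        v, a, zr, ter = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
    if np.any(a <= 0):
        raise transforms.DomainError("boundary separation must be positive")
    if np.any((zr <= 0) | (zr >= 1)):
        raise transforms.DomainError("z_r must lie strictly inside (0, 1)")
    if dt <= 0:
        raise transforms.DomainError("step size dt must be positive")
    n = v.size
    z = zr * a

    if noise == 0:
        if np.any(v == 0):
            raise transforms.DomainError(
                "zero drift never crosses a boundary without noise")
        upper = v > 0
        decision = np.where(upper, (a - z) / np.where(v > 0, v, 1.0),
                            z / np.abs(np.where(v < 0, v, 1.0)))
        rt = ter + decision
        return _summarize(rt, upper, 0)

    rng = np.random.default_rng(seed)
    x = z.copy()
    rt_dec = np.full(n, np.nan)
    upper = np.zeros(n, bool)
    active = np.ones(n, bool)
    sqdt = math.sqrt(dt)
    t = 0.0
    max_steps = int(max_time / dt)
    for step in range(1, max_steps + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        inc = v[idx] * dt + noise * sqdt * rng.standard_normal(idx.size)
        x[idx] += inc
        t = step * dt
        hit_up = x[idx] >= a[idx]
        hit_lo = x[idx] <= 0.0
        done = hit_up | hit_lo
        if done.any():
            fin = idx[done]
            rt_dec[fin] = t
            upper[fin] = hit_up[done]
            active[fin] = False
    n_censored = int(active.sum())
    ok = ~active
    rt = ter[ok] + rt_dec[ok]
    return _summarize(rt, upper[ok], n_censored)


def _summarize(rt: np.ndarray, upper: np.ndarray,
               n_censored: int) -> PredictiveSummary:
    qs = (0.1, 0.3, 0.5, 0.7, 0.9)
    if rt.size == 0:
        quant = {q: math.nan for q in qs}
        return PredictiveSummary(math.nan, math.nan, quant, 0, n_censored)
    quant = {q: float(np.quantile(rt, q)) for q in qs}
    return PredictiveSummary(
        mean_rt=float(np.mean(rt)), accuracy=float(np.mean(upper)),
        quantiles=quant, n_trials=int(rt.size), n_censored=n_censored)


def load_deposited_corpus(path, dialect: Optional[str] = None,
                          column_map: Optional[dict] = None) -> Corpus:
    """Ingest an externally deposited estimate table.

    ``column_map`` renames the deposit's columns to the documented
    schema before validation, accommodating layouts that differ from
    this package's corpus format. The deposited data are not bundled
    and must be supplied locally.
    """
    if column_map:
        df = pd.read_csv(path, sep=dialect or ",", dtype=str,
                         keep_default_na=False)
        df = df.rename(columns=column_map)
        import io
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return read_corpus(buf, dialect=",")
    return read_corpus(path, dialect=dialect)
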