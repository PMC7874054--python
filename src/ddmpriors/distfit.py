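"""Constrained ML fitting of truncated/mixture densities and wAIC selection.

Pooled empirical distributions of DDM parameter estimates are
characterized by candidate densities that respect each parameter's
theoretical bounds: truncated normal, lognormal, gamma, Weibull and
truncated Student's t for parameters bounded below by zero, and
truncated normal / truncated t on [0, 1] for the relative starting
point and its variability. Heavy-tailed empirical distributions
(contaminated by non-standard tasks and reporting errors) are
additionally offered two-component mixtures: gamma + gamma, and
truncated normal paired with a gamma, a lognormal, or another truncated
normal.

Candidates are fitted by maximum likelihood with a seeded multi-start
local search in an unconstrained reparameterization (log for positive
parameters, logit for the mixture weight), compared by Akaike weights
wAIC_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2) with
Delta_i = AIC_i - min AIC, and the winner's dominant mixture component
(the one with the larger weight) is proposed as a single-family prior.

Truncation bounds are fixed constants of the parameter kind, not fitted,
so they never count toward AIC's free-parameter penalty.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, special, stats

from .corpus import ParameterKind
from .transforms import PooledSample

__all__ = [
    "SpecError",
    "FitError",
    "Family",
    "DistributionSpec",
    "MixtureSpec",
    "CandidateTemplate",
    "FitResult",
    "PriorSpec",
    "log_density",
    "fit_ml",
    "fit_candidates",
    "akaike_weights",
    "select_best",
    "dominant_component",
    "candidate_set",
    "BOUNDED_KINDS",
]


class SpecError(Exception):
    """A distribution specification violates its parameter constraints."""


class FitError(Exception):
    """A fitting or model-comparison contract was violated."""


class Family(enum.Enum):
    TRUNCATED_NORMAL = "truncated_normal"
    LOGNORMAL = "lognormal"
    GAMMA = "gamma"
    WEIBULL = "weibull"
    TRUNCATED_T = "truncated_t"


#: parameter names and whether they are positivity-constrained
_FAMILY_PARAMS = {
    Family.TRUNCATED_NORMAL: (("location", False), ("scale", True)),
    Family.LOGNORMAL: (("meanlog", False), ("sdlog", True)),
    Family.GAMMA: (("shape", True), ("scale", True)),
    Family.WEIBULL: (("shape", True), ("scale", True)),
    Family.TRUNCATED_T: (("location", False), ("scale", True), ("df", True)),
}

_FAMILY_ORDER = (Family.TRUNCATED_NORMAL, Family.LOGNORMAL, Family.GAMMA,
                 Family.WEIBULL, Family.TRUNCATED_T)

#: kinds whose support is the unit interval rather than [0, inf)
BOUNDED_KINDS = frozenset({ParameterKind.Z_R, ParameterKind.S_Z_R})

#: mixture pairs offered (order fixes the deterministic tie-break)
_MIXTURE_PAIRS = (
    (Family.GAMMA, Family.GAMMA),
    (Family.TRUNCATED_NORMAL, Family.GAMMA),
    (Family.TRUNCATED_NORMAL, Family.LOGNORMAL),
    (Family.TRUNCATED_NORMAL, Family.TRUNCATED_NORMAL),
)


# Vectorized density kernels built on scipy's special-function ufuncs.
# These avoid per-call construction of frozen scipy distributions, which
# dominates run time inside the multi-start optimizer; the formulas are
# the standard closed forms and agree with scipy.stats to rounding.

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _base_logpdf(family: Family, p: dict, x: np.ndarray) -> np.ndarray:
    if family is Family.TRUNCATED_NORMAL:
        z = (x - p["location"]) / p["scale"]
        return -0.5 * z * z - math.log(p["scale"]) - _LOG_SQRT_2PI
    if family is Family.LOGNORMAL:
        out = np.full_like(x, -np.inf)
        pos = x > 0
        lx = np.log(x[pos])
        z = (lx - p["meanlog"]) / p["sdlog"]
        out[pos] = (-0.5 * z * z - lx - math.log(p["sdlog"])
                    - _LOG_SQRT_2PI)
        return out
    if family is Family.GAMMA:
        a, sc = p["shape"], p["scale"]
        out = np.full_like(x, -np.inf)
        pos = x > 0
        xs = x[pos] / sc
        out[pos] = ((a - 1.0) * np.log(xs) - xs
                    - special.gammaln(a) - math.log(sc))
        if a < 1:
            out[x == 0] = np.inf  # non-integrable spike
        elif a == 1:
            out[x == 0] = -math.log(sc)
        return out
    if family is Family.WEIBULL:
        c, sc = p["shape"], p["scale"]
        out = np.full_like(x, -np.inf)
        pos = x > 0
        xs = x[pos] / sc
        out[pos] = (math.log(c / sc) + (c - 1.0) * np.log(xs) - xs ** c)
        if c < 1:
            out[x == 0] = np.inf
        elif c == 1:
            out[x == 0] = -math.log(sc)
        return out
    if family is Family.TRUNCATED_T:
        df, sc = p["df"], p["scale"]
        z = (x - p["location"]) / sc
        return (special.gammaln((df + 1.0) / 2.0)
                - special.gammaln(df / 2.0)
                - 0.5 * math.log(df * math.pi) - math.log(sc)
                - (df + 1.0) / 2.0 * np.log1p(z * z / df))
    raise SpecError(f"unknown family {family!r}")


def _base_cdf(family: Family, p: dict, x) -> np.ndarray:
    x = np.asarray(x, float)
    if family is Family.TRUNCATED_NORMAL:
        return special.ndtr((x - p["location"]) / p["scale"])
    if family is Family.LOGNORMAL:
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = special.ndtr(
            (np.log(x[pos]) - p["meanlog"]) / p["sdlog"])
        out[np.isposinf(x)] = 1.0
        return out
    if family is Family.GAMMA:
        return special.gammainc(p["shape"], np.maximum(x, 0.0) / p["scale"])
    if family is Family.WEIBULL:
        xs = np.maximum(x, 0.0) / p["scale"]
        with np.errstate(over="ignore"):
            out = -np.expm1(-xs ** p["shape"])
        out[np.isposinf(x)] = 1.0
        return out
    if family is Family.TRUNCATED_T:
        z = (x - p["location"]) / p["scale"]
        out = special.stdtr(p["df"], np.where(np.isfinite(z), z, 0.0))
        out[np.isposinf(x)] = 1.0
        out[np.isneginf(x)] = 0.0
        return out
    raise SpecError(f"unknown family {family!r}")


def _base_sf(family: Family, p: dict, x) -> np.ndarray:
    """Survival function, accurate in the upper tail."""
    x = np.asarray(x, float)
    if family is Family.TRUNCATED_NORMAL:
        return special.ndtr(-(x - p["location"]) / p["scale"])
    if family is Family.LOGNORMAL:
        out = np.ones_like(x)
        pos = x > 0
        out[pos] = special.ndtr(
            -(np.log(x[pos]) - p["meanlog"]) / p["sdlog"])
        out[np.isposinf(x)] = 0.0
        return out
    if family is Family.GAMMA:
        return special.gammaincc(p["shape"],
                                 np.maximum(x, 0.0) / p["scale"])
    if family is Family.WEIBULL:
        xs = np.maximum(x, 0.0) / p["scale"]
        with np.errstate(over="ignore"):
            out = np.exp(-xs ** p["shape"])
        out[np.isposinf(x)] = 0.0
        return out
    if family is Family.TRUNCATED_T:
        z = (x - p["location"]) / p["scale"]
        out = special.stdtr(p["df"], -np.where(np.isfinite(z), z, 0.0))
        out[np.isposinf(x)] = 0.0
        out[np.isneginf(x)] = 1.0
        return out
    raise SpecError(f"unknown family {family!r}")


def _interval_mass(family: Family, p: dict, lower: float,
                   upper: float) -> float:
    """Probability mass on [lower, upper], stable in either tail.

    When both bounds lie in the upper tail, F(upper) - F(lower) cancels
    catastrophically (both CDFs round to 1); the survival-function
    difference is then the accurate form.
    """
    f_lo = float(_base_cdf(family, p, np.array([lower]))[0])
    if f_lo < 0.5:
        return float(_base_cdf(family, p, np.array([upper]))[0]) - f_lo
    return float(_base_sf(family, p, np.array([lower]))[0]
                 - _base_sf(family, p, np.array([upper]))[0])


def _trunc_logpdf(family: Family, p: dict, lower: float, upper: float,
                  x: np.ndarray,
                  min_mass: float = 1e-300) -> Optional[np.ndarray]:
    """Renormalized log-density on [lower, upper]; None if degenerate.

    ``min_mass`` rejects parameterizations that place less than that
    much untruncated probability on the interval: there the mass is a
    difference of nearly equal CDF values and carries no significant
    digits, so the renormalized "density" is rounding noise.
    """
    mass = _interval_mass(family, p, lower, upper)
    if not (mass > min_mass and math.isfinite(mass)):
        return None
    lp = _base_logpdf(family, p, x) - math.log(mass)
    return np.where((x < lower) | (x > upper), -np.inf, lp)


def _frozen(family: Family, params: dict):
    if family is Family.TRUNCATED_NORMAL:
        return stats.norm(loc=params["location"], scale=params["scale"])
    if family is Family.LOGNORMAL:
        return stats.lognorm(s=params["sdlog"],
                             scale=math.exp(params["meanlog"]))
    if family is Family.GAMMA:
        return stats.gamma(a=params["shape"], scale=params["scale"])
    if family is Family.WEIBULL:
        return stats.weibull_min(c=params["shape"], scale=params["scale"])
    if family is Family.TRUNCATED_T:
        return stats.t(df=params["df"], loc=params["location"],
                       scale=params["scale"])
    raise SpecError(f"unknown family {family!r}")


@dataclass(frozen=True)
class DistributionSpec:
    """One candidate density: family, parameters, support interval.

    The density is the family's untruncated density renormalized by its
    probability mass on [lower, upper], hence integrates to 1 there.
    """

    family: Family
    params: dict
    lower: float = 0.0
    upper: float = math.inf

    def __post_init__(self) -> None:
        expected = [n for n, _ in _FAMILY_PARAMS[self.family]]
        got = sorted(self.params)
        if sorted(expected) != got:
            raise SpecError(
                f"{self.family.value} expects parameters {expected}, "
                f"got {got}")
        for name, positive in _FAMILY_PARAMS[self.family]:
            val = self.params[name]
            if not math.isfinite(val):
                raise SpecError(f"{name} must be finite, got {val!r}")
            if positive and not val > 0:
                raise SpecError(f"{name} must be > 0, got {val!r}")
        if not self.lower < self.upper:
            raise SpecError("lower bound must lie below upper bound")

    @property
    def k_free(self) -> int:
        return len(_FAMILY_PARAMS[self.family])

    def _mass(self) -> float:
        dist = _frozen(self.family, self.params)
        return float(dist.cdf(self.upper) - dist.cdf(self.lower))

    def logpdf(self, x):
        """Log-density; -inf outside [lower, upper]."""
        x = np.asarray(x, float)
        scalar = x.ndim == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = _trunc_logpdf(self.family, self.params, self.lower,
                               self.upper, np.atleast_1d(x))
        if lp is None:
            raise SpecError(
                f"{self.family.value} spec has no mass on "
                f"[{self.lower}, {self.upper}]")
        return float(lp[0]) if scalar else lp

    def cdf(self, x):
        dist = _frozen(self.family, self.params)
        mass = self._mass()
        lo = dist.cdf(self.lower)
        c = (dist.cdf(np.asarray(x, float)) - lo) / mass
        return np.clip(c, 0.0, 1.0)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n values by inverse-CDF sampling restricted to the support."""
        dist = _frozen(self.family, self.params)
        lo, hi = dist.cdf(self.lower), dist.cdf(self.upper)
        u = rng.uniform(lo, hi, size=n)
        x = dist.ppf(u)
        return np.clip(x, self.lower, self.upper)

    def std_approx(self) -> float:
        """Robust spread proxy from a truncated quantile grid.

        Used only for the dominance tie-break; heavy-tailed members
        (small df) may lack finite moments, so a trimmed quantile-based
        spread is used instead of the analytic variance.
        """
        dist = _frozen(self.family, self.params)
        lo, hi = dist.cdf(self.lower), dist.cdf(self.upper)
        q = lo + (hi - lo) * np.linspace(0.01, 0.99, 199)
        return float(np.std(dist.ppf(q)))


@dataclass(frozen=True)
class MixtureSpec:
    """Two-component mixture: weight * f1 + (1 - weight) * f2."""

    weight: float
    component1: DistributionSpec
    component2: DistributionSpec

    def __post_init__(self) -> None:
        if not 0 < self.weight < 1:
            raise SpecError(f"mixture weight must be in (0, 1), "
                            f"got {self.weight!r}")
        pair = (self.component1.family, self.component2.family)
        if pair not in _MIXTURE_PAIRS and pair[::-1] not in _MIXTURE_PAIRS:
            raise SpecError(f"mixture pair {pair} not in the allowed set")
        if (self.component1.lower != self.component2.lower
                or self.component1.upper != self.component2.upper):
            raise SpecError("mixture components must share support bounds")

    @property
    def lower(self) -> float:
        return self.component1.lower

    @property
    def upper(self) -> float:
        return self.component1.upper

    @property
    def k_free(self) -> int:
        return self.component1.k_free + self.component2.k_free + 1

    def logpdf(self, x):
        lp1 = np.asarray(self.component1.logpdf(x), float)
        lp2 = np.asarray(self.component2.logpdf(x), float)
        out = np.logaddexp(math.log(self.weight) + lp1,
                           math.log1p(-self.weight) + lp2)
        return out if out.ndim else float(out)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        pick1 = rng.random(n) < self.weight
        out = np.empty(n, float)
        n1 = int(pick1.sum())
        if n1:
            out[pick1] = self.component1.rvs(n1, rng)
        if n - n1:
            out[~pick1] = self.component2.rvs(n - n1, rng)
        return out

    def canonicalized(self) -> "MixtureSpec":
        """Order components so the reported weight is the dominant one."""
        if self.weight >= 0.5:
            return self
        return MixtureSpec(weight=1.0 - self.weight,
                           component1=self.component2,
                           component2=self.component1)


Spec = Union[DistributionSpec, MixtureSpec]


def log_density(spec: Spec, x):
    """Log-density of a (possibly mixture) spec; -inf outside support."""
    return spec.logpdf(x)


# ---------------------------------------------------------------------------
# candidate templates


@dataclass(frozen=True)
class CandidateTemplate:
    """A fit target: one family or an allowed pair, plus support bounds."""

    families: tuple[Family, ...]
    lower: float
    upper: float

    @property
    def is_mixture(self) -> bool:
        return len(self.families) == 2

    @property
    def name(self) -> str:
        return "+".join(f.value for f in self.families)

    @property
    def k_free(self) -> int:
        k = sum(len(_FAMILY_PARAMS[f]) for f in self.families)
        return k + 1 if self.is_mixture else k

    @property
    def order_index(self) -> tuple:
        """Deterministic enumeration order for tie-breaking."""
        return (len(self.families),
                tuple(_FAMILY_ORDER.index(f) for f in self.families))


def candidate_set(kind: ParameterKind) -> list[CandidateTemplate]:
    """Candidate templates for one parameter kind.

    Unit-interval kinds (z_r, s_z_r): truncated normal and truncated t
    on [0, 1] plus the four allowed mixtures truncated to [0, 1]. All
    other kinds: the five single families and the four mixtures on
    [0, inf).
    """
    if kind in BOUNDED_KINDS:
        lo, hi = 0.0, 1.0
        singles = (Family.TRUNCATED_NORMAL, Family.TRUNCATED_T)
    else:
        lo, hi = 0.0, math.inf
        singles = _FAMILY_ORDER
    out = [CandidateTemplate((f,), lo, hi) for f in singles]
    out += [CandidateTemplate(pair, lo, hi) for pair in _MIXTURE_PAIRS]
    return out


# ---------------------------------------------------------------------------
# maximum likelihood


@dataclass(frozen=True)
class FitResult:
    """One fitted candidate with its information-criterion bookkeeping."""

    spec: Optional[Spec]
    template: CandidateTemplate
    loglik: float
    k_free: int
    aic: float
    converged: bool
    n_restarts_used: int
    seed: int
    waic: float = math.nan

    @property
    def name(self) -> str:
        return self.template.name


@dataclass(frozen=True)
class PriorSpec:
    """A prior-table row: the proposed single-family prior for one kind."""

    kind: Optional[ParameterKind]
    distribution: DistributionSpec
    mixture_weight: Optional[float]
    n: int
    empirical_lower: float
    empirical_upper: float
    source_template: str = ""


def _pack_names(families: Sequence[Family]):
    names = []
    for i, fam in enumerate(families):
        for pname, positive in _FAMILY_PARAMS[fam]:
            names.append((i, pname, positive))
    return names


def _theta_to_specs(theta: np.ndarray, template: CandidateTemplate) -> Spec:
    names = _pack_names(template.families)
    vals = []
    idx = 0
    per_comp: list[dict] = [dict() for _ in template.families]
    for (comp, pname, positive), t in zip(names, theta):
        per_comp[comp][pname] = math.exp(t) if positive else t
        idx += 1
    comps = [DistributionSpec(fam, params, template.lower, template.upper)
             for fam, params in zip(template.families, per_comp)]
    if template.is_mixture:
        w = special.expit(theta[idx])
        w = min(max(w, 1e-12), 1 - 1e-12)
        return MixtureSpec(weight=float(w), component1=comps[0],
                           component2=comps[1])
    return comps[0]


def _specs_to_theta(spec: Spec, template: CandidateTemplate) -> np.ndarray:
    comps = ([spec.component1, spec.component2]
             if isinstance(spec, MixtureSpec) else [spec])
    theta = []
    for comp in comps:
        for pname, positive in _FAMILY_PARAMS[comp.family]:
            v = comp.params[pname]
            theta.append(math.log(v) if positive else v)
    if isinstance(spec, MixtureSpec):
        theta.append(special.logit(spec.weight))
    return np.asarray(theta, float)


def _moment_init(family: Family, x: np.ndarray) -> dict:
    m = float(np.mean(x))
    sd = max(float(np.std(x)), 1e-3 * (abs(m) + 1.0))
    if family is Family.TRUNCATED_NORMAL:
        return {"location": m, "scale": sd}
    if family is Family.LOGNORMAL:
        pos = x[x > 0]
        if pos.size == 0:
            return {"meanlog": 0.0, "sdlog": 1.0}
        lx = np.log(pos)
        return {"meanlog": float(np.mean(lx)),
                "sdlog": max(float(np.std(lx)), 1e-3)}
    if family is Family.GAMMA:
        if m <= 0:
            return {"shape": 1.0, "scale": 1.0}
        return {"shape": (m / sd) ** 2, "scale": sd ** 2 / m}
    if family is Family.WEIBULL:
        return {"shape": 1.5, "scale": max(m, 1e-3)}
    if family is Family.TRUNCATED_T:
        return {"location": float(np.median(x)), "scale": max(0.7 * sd, 1e-4),
                "df": 3.0}
    raise SpecError(f"unknown family {family!r}")


def _map_components(spec: Spec, fn) -> Spec:
    if isinstance(spec, MixtureSpec):
        return MixtureSpec(spec.weight, fn(spec.component1),
                           fn(spec.component2))
    return fn(spec)


def _extra_start_specs(template: CandidateTemplate,
                       x: np.ndarray) -> list:
    """Deterministic auxiliary starting points beyond the moment match.

    Truncated location families need them: for skewed data on a bounded
    support the ML location can sit outside the interval (the truncation
    renormalization absorbs the shift), a regime moment-matched starts
    rarely reach; and the truncated t must be able to reach its
    near-Gaussian (large-df) limit.
    """
    base = _initial_spec(template, x)
    sd = max(float(np.std(x)), 1e-6)
    loc_fams = (Family.TRUNCATED_NORMAL, Family.TRUNCATED_T)
    out = []
    if Family.TRUNCATED_T in template.families:
        out.append(_map_components(
            base, lambda c: replace(
                c, params={**c.params, "df": 30.0, "scale": sd})
            if c.family is Family.TRUNCATED_T else c))
    if any(f in loc_fams for f in template.families):
        def skew(offset):
            def fn(c):
                if c.family in loc_fams:
                    return replace(c, params={
                        **c.params, "location": offset, "scale": 2.0 * sd})
                return c
            return fn
        out.append(_map_components(base, skew(template.lower - sd)))
        if math.isfinite(template.upper):
            out.append(_map_components(base, skew(template.upper + sd)))
    return out


def _initial_spec(template: CandidateTemplate, x: np.ndarray) -> Spec:
    comps = []
    for i, fam in enumerate(template.families):
        params = _moment_init(fam, x)
        if template.is_mixture and i == 1:
            # second component starts wider, to catch contaminated tails
            params = {k: (v * 2.0 if k in ("scale", "sdlog") else v)
                      for k, v in params.items()}
        comps.append(DistributionSpec(fam, params, template.lower,
                                      template.upper))
    if template.is_mixture:
        return MixtureSpec(0.7, comps[0], comps[1])
    return comps[0]


_BIG = 1e300


def _implied_sd(family: Family, p: dict) -> float:
    """Rough width of a component, for the degenerate-spike guard."""
    if family in (Family.TRUNCATED_NORMAL, Family.TRUNCATED_T):
        return p["scale"]
    if family is Family.LOGNORMAL:
        return math.exp(min(p["meanlog"], 700.0)) * p["sdlog"]
    if family is Family.GAMMA:
        return math.sqrt(p["shape"]) * p["scale"]
    if family is Family.WEIBULL:
        c = p["shape"]
        try:
            var = math.gamma(1 + 2 / c) - math.gamma(1 + 1 / c) ** 2
        except OverflowError:
            return math.inf
        return p["scale"] * math.sqrt(max(var, 0.0))
    return math.inf


def _neg_loglik(theta: np.ndarray, template: CandidateTemplate,
                x: np.ndarray, sd_floor: float = 0.0) -> float:
    # fast path: unpack theta straight into the density kernels, skipping
    # dataclass construction/validation on every objective evaluation
    if not np.all(np.isfinite(theta)):
        return _BIG
    idx = 0
    comp_lps = []
    try:
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            for fam in template.families:
                p = {}
                for pname, positive in _FAMILY_PARAMS[fam]:
                    t = float(theta[idx])
                    idx += 1
                    if positive:
                        if t > 700.0:
                            return _BIG
                        p[pname] = math.exp(t)
                    else:
                        p[pname] = t
                # caps: beyond these the family is numerically
                # indistinguishable from its Gaussian limit and gammaln
                # cancellation turns the log-likelihood into noise
                if fam is Family.TRUNCATED_T and p["df"] > 1000.0:
                    return _BIG
                if (fam in (Family.GAMMA, Family.WEIBULL)
                        and p["shape"] > 1e6):
                    return _BIG
                if sd_floor and _implied_sd(fam, p) < sd_floor:
                    return _BIG  # degenerate spike on a data point
                lp = _trunc_logpdf(fam, p, template.lower, template.upper, x,
                                   min_mass=1e-9)
                if lp is None:
                    return _BIG
                comp_lps.append(lp)
            if template.is_mixture:
                w = float(special.expit(theta[idx]))
                w = min(max(w, 1e-12), 1.0 - 1e-12)
                lp = np.logaddexp(math.log(w) + comp_lps[0],
                                  math.log1p(-w) + comp_lps[1])
            else:
                lp = comp_lps[0]
    except (OverflowError, ValueError, FloatingPointError):
        return _BIG
    if np.any(np.isposinf(lp)):  # non-integrable spike at a data point
        return _BIG
    total = float(np.sum(lp))
    if not math.isfinite(total):
        return _BIG
    return -total


def fit_ml(sample: Union[PooledSample, np.ndarray, Sequence[float]],
           template: Union[CandidateTemplate, Family, tuple],
           bounds: Optional[tuple[float, float]] = None,
           n_starts: int = 20,
           seed: int = 0) -> FitResult:
    """Fit one candidate by seeded multi-start maximum likelihood.

    The objective is the total log-likelihood, maximized over the
    template's free parameters in an unconstrained reparameterization
    (log for positivity-constrained parameters, logit for the mixture
    weight) with a Nelder-Mead local search from ``n_starts``
    initializations: a moment-matched start followed by seeded
    Gaussian perturbations of it. Restart initializations form a prefix
    sequence, so the best-of-n log-likelihood is non-decreasing in
    ``n_starts`` for a fixed seed.

    A candidate assigning zero density to any data point (e.g. a
    lognormal faced with an exact zero) ends with ``loglik = -inf`` and
    ``converged = False``: effectively eliminated, never an exception.
    """
    if isinstance(sample, PooledSample):
        x = np.asarray(sample.values, float)
    else:
        x = np.asarray(sample, float)
    if x.size == 0:
        raise FitError("cannot fit an empty sample")
    if isinstance(template, Family):
        template = CandidateTemplate((template,), *(bounds or (0.0, math.inf)))
    elif isinstance(template, tuple) and not isinstance(
            template, CandidateTemplate):
        template = CandidateTemplate(tuple(template),
                                     *(bounds or (0.0, math.inf)))
    elif bounds is not None:
        template = CandidateTemplate(template.families, *bounds)

    rng = np.random.default_rng(seed)
    theta0 = _specs_to_theta(_initial_spec(template, x), template)
    # guard against degenerate spike solutions (scale -> 0 on one point),
    # where the likelihood of free-df / mixture models is unbounded
    sd_floor = 1e-3 * max(float(np.std(x)), 1e-12)
    extra_starts = [_specs_to_theta(s, template)
                    for s in _extra_start_specs(template, x)]

    def _local(start: np.ndarray):
        return optimize.minimize(
            _neg_loglik, start, args=(template, x, sd_floor),
            method="Nelder-Mead",
            options={"maxiter": 400 * theta0.size, "xatol": 1e-6,
                     "fatol": 1e-8, "adaptive": theta0.size > 3})

    best_val = math.inf
    best_theta = None
    for i in range(n_starts):
        if i == 0:
            start = theta0
        elif i <= len(extra_starts):
            start = extra_starts[i - 1]
        else:
            jitter = rng.normal(0.0, 0.5, size=theta0.size)
            start = theta0 + jitter
        res = _local(start)
        if res.fun < best_val:
            best_val = float(res.fun)
            best_theta = np.asarray(res.x, float)
    if best_theta is not None and best_val < _BIG / 2:
        # polish: re-start the simplex at the incumbent optimum
        res = _local(best_theta)
        if res.fun < best_val:
            best_val = float(res.fun)
            best_theta = np.asarray(res.x, float)

    if best_theta is None or best_val >= _BIG / 2:
        return FitResult(spec=None, template=template, loglik=-math.inf,
                         k_free=template.k_free, aic=math.inf,
                         converged=False, n_restarts_used=n_starts, seed=seed)
    spec = _theta_to_specs(best_theta, template)
    if isinstance(spec, MixtureSpec):
        spec = spec.canonicalized()
    loglik = -best_val
    k = template.k_free
    return FitResult(spec=spec, template=template, loglik=loglik, k_free=k,
                     aic=2.0 * k - 2.0 * loglik, converged=True,
                     n_restarts_used=n_starts, seed=seed)


def akaike_weights(fits: Sequence[FitResult]) -> list[FitResult]:
    """Fill Akaike weights: waic_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2).

    Delta_i = AIC_i - min AIC over converged fits; non-converged fits
    receive weight 0 and are excluded from the normalization.
    """
    conv = [f for f in fits if f.converged and math.isfinite(f.aic)]
    if not conv:
        raise FitError("no converged fits to weight")
    aics = np.array([f.aic for f in conv])
    delta = aics - aics.min()
    raw = np.exp(-delta / 2.0)
    w = raw / raw.sum()
    weights = dict(zip((id(f) for f in conv), w))
    return [replace(f, waic=float(weights.get(id(f), 0.0))) for f in fits]


def select_best(fits: Sequence[FitResult]) -> FitResult:
    """The fit with maximal Akaike weight.

    Ties (to within 1e-12) are broken by fewer free parameters, then by
    the fixed family/mixture enumeration order, so selection is
    deterministic.
    """
    fits = list(fits)
    if not fits:
        raise FitError("empty fit collection")
    if any(math.isnan(f.waic) for f in fits):
        fits = akaike_weights(fits)
    wmax = max(f.waic for f in fits)
    contenders = [f for f in fits if f.waic >= wmax - 1e-12]
    contenders.sort(key=lambda f: (f.k_free, f.template.order_index))
    return contenders[0]


def dominant_component(fit: FitResult,
                       kind: Optional[ParameterKind] = None,
                       sample: Optional[PooledSample] = None) -> PriorSpec:
    """Extract the proposed prior from a selected fit.

    For a mixture, the component with the larger weight is proposed as
    the prior, with that weight recorded; the weight-0.5 tie goes to
    the component with the smaller spread. Single-family selections
    pass through with no mixture weight.
    """
    if fit.spec is None:
        raise FitError("cannot extract a prior from a non-converged fit")
    n = sample.n if sample is not None else 0
    lo = sample.empirical_lower if sample is not None else math.nan
    hi = sample.empirical_upper if sample is not None else math.nan
    if isinstance(fit.spec, MixtureSpec):
        mix = fit.spec.canonicalized()
        comp, weight = mix.component1, mix.weight
        if weight == 0.5 and (mix.component2.std_approx()
                              < mix.component1.std_approx()):
            comp = mix.component2
        return PriorSpec(kind=kind, distribution=comp, mixture_weight=weight,
                         n=n, empirical_lower=lo, empirical_upper=hi,
                         source_template=fit.name)
    return PriorSpec(kind=kind, distribution=fit.spec, mixture_weight=None,
                     n=n, empirical_lower=lo, empirical_upper=hi,
                     source_template=fit.name)


def fit_candidates(sample: PooledSample,
                   kind: Optional[ParameterKind] = None,
                   n_starts: int = 20,
                   seed: int = 0) -> list[FitResult]:
    """Fit the full candidate set for a kind and fill Akaike weights."""
    kind = kind or sample.kind
    templates = candidate_set(kind)
    ss = np.random.SeedSequence(entropy=seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn(len(templates))]
    fits = [fit_ml(sample, tmpl, n_starts=n_starts, seed=cs)
            for tmpl, cs in zip(templates, child_seeds)]
    return akaike_weights(fits)
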