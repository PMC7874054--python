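"""Truncated/mixture densities, ML fitting and Akaike-weight selection."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import integrate, stats

from ddmpriors.corpus import ParameterKind
from ddmpriors.distfit import (BOUNDED_KINDS, CandidateTemplate,
                               DistributionSpec, Family, FitError, FitResult,
                               MixtureSpec, SpecError, akaike_weights,
                               candidate_set, dominant_component, fit_ml,
                               log_density, select_best)

INF = math.inf

TN01 = DistributionSpec(Family.TRUNCATED_NORMAL,
                        {"location": 0.0, "scale": 1.0}, 0.0, INF)
SPECS_FOR_QUADRATURE = [
    TN01,
    DistributionSpec(Family.TRUNCATED_NORMAL,
                     {"location": 0.33, "scale": 0.22}, 0.0, 1.0),
    DistributionSpec(Family.LOGNORMAL,
                     {"meanlog": 0.3, "sdlog": 0.6}, 0.0, INF),
    DistributionSpec(Family.GAMMA, {"shape": 11.69, "scale": 0.12}, 0.0, INF),
    DistributionSpec(Family.WEIBULL, {"shape": 1.5, "scale": 2.0}, 0.0, INF),
    DistributionSpec(Family.TRUNCATED_T,
                     {"location": 0.44, "scale": 0.08, "df": 1.32}, 0.0, INF),
    DistributionSpec(Family.TRUNCATED_T,
                     {"location": 0.5, "scale": 0.05, "df": 1.85}, 0.0, 1.0),
    DistributionSpec(Family.GAMMA, {"shape": 2.0, "scale": 0.1}, 0.0, 1.0),
    MixtureSpec(0.76,
                DistributionSpec(Family.GAMMA,
                                 {"shape": 11.69, "scale": 0.12}, 0.0, INF),
                DistributionSpec(Family.GAMMA,
                                 {"shape": 2.0, "scale": 1.0}, 0.0, INF)),
    MixtureSpec(0.85,
                DistributionSpec(Family.TRUNCATED_NORMAL,
                                 {"location": 1.76, "scale": 1.51}, 0.0, INF),
                DistributionSpec(Family.LOGNORMAL,
                                 {"meanlog": 0.5, "sdlog": 0.8}, 0.0, INF)),
]


class TestLogDensity:
    def test_half_normal_at_zero(self):
        # renormalizing N(0,1) to [0, inf) doubles the density at 0
        assert log_density(TN01, 0.0) == pytest.approx(
            math.log(2.0 * stats.norm.pdf(0.0)), abs=1e-12)

    def test_outside_support_is_minus_inf(self):
        for spec in SPECS_FOR_QUADRATURE:
            assert log_density(spec, spec.lower - 0.5) == -INF

    def test_mixture_weight_to_one_approaches_component(self):
        c1 = DistributionSpec(Family.GAMMA, {"shape": 3.0, "scale": 0.5},
                              0.0, INF)
        c2 = DistributionSpec(Family.GAMMA, {"shape": 1.0, "scale": 5.0},
                              0.0, INF)
        mix = MixtureSpec(1.0 - 1e-12, c1, c2)
        assert log_density(mix, 1.3) == pytest.approx(
            log_density(c1, 1.3), abs=1e-9)

    def test_invalid_parameters_raise_spec_error(self):
        with pytest.raises(SpecError):
            DistributionSpec(Family.GAMMA, {"shape": -1.0, "scale": 1.0})
        with pytest.raises(SpecError):
            DistributionSpec(Family.TRUNCATED_NORMAL,
                             {"location": 0.0, "scale": 0.0})

    @pytest.mark.parametrize("spec", SPECS_FOR_QUADRATURE,
                             ids=lambda s: getattr(
                                 s, "family", Family.GAMMA).value
                             if isinstance(s, DistributionSpec) else "mix")
    def test_density_integrates_to_one(self, spec):
        upper = spec.upper if math.isfinite(spec.upper) else np.inf
        total, err = integrate.quad(
            lambda x: math.exp(log_density(spec, x)), spec.lower, upper,
            limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("spec", [s for s in SPECS_FOR_QUADRATURE
                                      if isinstance(s, DistributionSpec)],
                             ids=lambda s: s.family.value + str(s.upper))
    def test_matches_quadrature_renormalized_oracle(self, spec):
        """Truncated log-densities must equal the untruncated density
        renormalized by the numerically integrated interval mass."""
        frozen = {
            Family.TRUNCATED_NORMAL: lambda p: stats.norm(
                p["location"], p["scale"]),
            Family.LOGNORMAL: lambda p: stats.lognorm(
                s=p["sdlog"], scale=math.exp(p["meanlog"])),
            Family.GAMMA: lambda p: stats.gamma(
                a=p["shape"], scale=p["scale"]),
            Family.WEIBULL: lambda p: stats.weibull_min(
                c=p["shape"], scale=p["scale"]),
            Family.TRUNCATED_T: lambda p: stats.t(
                df=p["df"], loc=p["location"], scale=p["scale"]),
        }[spec.family](spec.params)
        upper = spec.upper if math.isfinite(spec.upper) else np.inf
        mass, _ = integrate.quad(frozen.pdf, spec.lower, upper, limit=200)
        xs = np.linspace(spec.lower + 1e-6,
                         min(upper, spec.lower + 5.0), 23)
        expected = frozen.logpdf(xs) - math.log(mass)
        got = np.array([log_density(spec, float(x)) for x in xs])
        assert got == pytest.approx(expected, abs=1e-7)


class TestFreeParameterCounts:
    @pytest.mark.parametrize("family,k", [
        (Family.TRUNCATED_NORMAL, 2), (Family.LOGNORMAL, 2),
        (Family.GAMMA, 2), (Family.WEIBULL, 2), (Family.TRUNCATED_T, 3),
    ])
    def test_single_families(self, family, k):
        assert CandidateTemplate((family,), 0.0, INF).k_free == k

    def test_mixture_counts_components_plus_weight(self):
        tmpl = CandidateTemplate(
            (Family.TRUNCATED_NORMAL, Family.TRUNCATED_T), 0.0, 1.0)
        assert tmpl.k_free == 2 + 3 + 1


class TestCandidateSet:
    def test_unbounded_kind_has_nine_templates(self):
        templates = candidate_set(ParameterKind.A)
        assert len(templates) == 9
        assert all(t.lower == 0.0 and math.isinf(t.upper) for t in templates)
        singles = [t for t in templates if not t.is_mixture]
        assert len(singles) == 5

    def test_bounded_kinds_truncated_to_unit_interval(self):
        for kind in BOUNDED_KINDS:
            templates = candidate_set(kind)
            assert all((t.lower, t.upper) == (0.0, 1.0) for t in templates)
            singles = {t.families[0] for t in templates if not t.is_mixture}
            # Weibull and the rest are not offered on [0, 1]
            assert singles == {Family.TRUNCATED_NORMAL, Family.TRUNCATED_T}

    def test_mixture_pairs_are_the_allowed_four(self):
        pairs = {t.families for t in candidate_set(ParameterKind.V)
                 if t.is_mixture}
        assert pairs == {
            (Family.GAMMA, Family.GAMMA),
            (Family.TRUNCATED_NORMAL, Family.GAMMA),
            (Family.TRUNCATED_NORMAL, Family.LOGNORMAL),
            (Family.TRUNCATED_NORMAL, Family.TRUNCATED_NORMAL)}


class TestFitML:
    def test_gamma_parameter_recovery(self, rng):
        true = DistributionSpec(Family.GAMMA,
                                {"shape": 11.69, "scale": 0.12}, 0.0, INF)
        x = true.rvs(5000, rng)
        fit = fit_ml(x, Family.GAMMA, n_starts=3, seed=1)
        assert fit.converged
        assert fit.spec.params["shape"] == pytest.approx(11.69, rel=0.05)
        assert fit.spec.params["scale"] == pytest.approx(0.12, rel=0.05)

    def test_zero_in_sample_eliminates_lognormal(self):
        x = np.array([0.0, 0.5, 1.0, 2.0, 0.3])
        fit = fit_ml(x, Family.LOGNORMAL, n_starts=2, seed=0)
        assert fit.loglik == -INF
        assert not fit.converged

    def test_mirrored_sample_forces_central_location(self, rng):
        true = DistributionSpec(
            Family.TRUNCATED_T,
            {"location": 0.5, "scale": 0.05, "df": 1.85}, 0.0, 1.0)
        x = true.rvs(2500, rng)
        mirrored = np.concatenate([x, 1.0 - x])
        fit = fit_ml(mirrored, Family.TRUNCATED_NORMAL, bounds=(0.0, 1.0),
                     n_starts=3, seed=2)
        assert fit.spec.params["location"] == pytest.approx(0.5, abs=0.02)

    def test_best_loglik_nondecreasing_in_restarts(self, rng):
        true = MixtureSpec(
            0.7,
            DistributionSpec(Family.GAMMA, {"shape": 12.0, "scale": 0.1},
                             0.0, INF),
            DistributionSpec(Family.GAMMA, {"shape": 2.0, "scale": 1.0},
                             0.0, INF))
        x = true.rvs(800, rng)
        tmpl = CandidateTemplate((Family.GAMMA, Family.GAMMA), 0.0, INF)
        logliks = [fit_ml(x, tmpl, n_starts=n, seed=5).loglik
                   for n in (2, 4, 8)]
        assert logliks == sorted(logliks)

    def test_mixture_weight_reported_for_dominant_component(self, rng):
        true = MixtureSpec(
            0.8,
            DistributionSpec(Family.GAMMA, {"shape": 12.0, "scale": 0.1},
                             0.0, INF),
            DistributionSpec(Family.GAMMA, {"shape": 1.5, "scale": 2.0},
                             0.0, INF))
        x = true.rvs(3000, rng)
        tmpl = CandidateTemplate((Family.GAMMA, Family.GAMMA), 0.0, INF)
        fit = fit_ml(x, tmpl, n_starts=6, seed=3)
        assert fit.spec.weight >= 0.5

    def test_empty_sample_is_an_error(self):
        with pytest.raises(FitError):
            fit_ml(np.array([]), Family.GAMMA)


def _fake_fit(aic, converged=True, k=2):
    tmpl = CandidateTemplate((Family.GAMMA,), 0.0, INF)
    return FitResult(spec=DistributionSpec(
        Family.GAMMA, {"shape": 2.0, "scale": 1.0}, 0.0, INF),
        template=tmpl, loglik=(2 * k - aic) / 2.0, k_free=k, aic=aic,
        converged=converged, n_restarts_used=1, seed=0)


class TestAkaikeWeights:
    def test_equal_aics_split_evenly(self):
        out = akaike_weights([_fake_fit(100.0), _fake_fit(100.0)])
        assert [f.waic for f in out] == pytest.approx([0.5, 0.5])

    def test_two_point_difference(self):
        out = akaike_weights([_fake_fit(100.0), _fake_fit(102.0)])
        assert out[0].waic == pytest.approx(0.731, abs=5e-4)
        assert out[1].waic == pytest.approx(0.269, abs=5e-4)

    def test_single_fit_gets_weight_one(self):
        out = akaike_weights([_fake_fit(57.0)])
        assert out[0].waic == pytest.approx(1.0)

    def test_nonconverged_excluded_from_normalization(self):
        out = akaike_weights([_fake_fit(100.0),
                              _fake_fit(90.0, converged=False)])
        assert out[0].waic == pytest.approx(1.0)
        assert out[1].waic == 0.0

    def test_weights_sum_to_one(self, rng):
        fits = [_fake_fit(float(a)) for a in rng.uniform(50, 150, 7)]
        out = akaike_weights(fits)
        assert math.fsum(f.waic for f in out) == pytest.approx(1.0)

    def test_no_converged_fits_is_an_error(self):
        with pytest.raises(FitError):
            akaike_weights([_fake_fit(1.0, converged=False)])

    def test_adding_strictly_worse_model_keeps_argmax(self, rng):
        fits = [_fake_fit(float(a)) for a in (100.0, 104.0, 101.5)]
        best_before = select_best(akaike_weights(fits))
        fits.append(_fake_fit(120.0, k=3))
        best_after = select_best(akaike_weights(fits))
        assert best_after.aic == best_before.aic


class TestSelection:
    def test_argmax_selected(self):
        out = akaike_weights([_fake_fit(100.0), _fake_fit(102.3)])
        assert select_best(out).aic == 100.0

    def test_tie_broken_by_fewer_parameters(self):
        simple = _fake_fit(100.0, k=2)
        complex_ = dataclasses.replace(
            _fake_fit(100.0, k=3),
            template=CandidateTemplate((Family.TRUNCATED_T,), 0.0, INF))
        out = akaike_weights([complex_, simple])
        assert select_best(out).k_free == 2


class TestDominantComponent:
    def test_mixture_dominant_extracted_with_weight(self):
        mix = MixtureSpec(
            0.85,
            DistributionSpec(Family.TRUNCATED_NORMAL,
                             {"location": 1.76, "scale": 1.51}, 0.0, INF),
            DistributionSpec(Family.LOGNORMAL,
                             {"meanlog": 0.5, "sdlog": 0.8}, 0.0, INF))
        tmpl = CandidateTemplate(
            (Family.TRUNCATED_NORMAL, Family.LOGNORMAL), 0.0, INF)
        fit = FitResult(spec=mix, template=tmpl, loglik=-10.0, k_free=5,
                        aic=30.0, converged=True, n_restarts_used=1, seed=0)
        prior = dominant_component(fit, kind=ParameterKind.V)
        assert prior.distribution.family is Family.TRUNCATED_NORMAL
        assert prior.mixture_weight == pytest.approx(0.85)

    def test_minority_first_mixture_is_canonicalized(self):
        mix = MixtureSpec(
            0.24,
            DistributionSpec(Family.GAMMA, {"shape": 2.0, "scale": 1.0},
                             0.0, INF),
            DistributionSpec(Family.GAMMA, {"shape": 11.7, "scale": 0.12},
                             0.0, INF))
        tmpl = CandidateTemplate((Family.GAMMA, Family.GAMMA), 0.0, INF)
        fit = FitResult(spec=mix, template=tmpl, loglik=-10.0, k_free=5,
                        aic=30.0, converged=True, n_restarts_used=1, seed=0)
        prior = dominant_component(fit)
        assert prior.mixture_weight == pytest.approx(0.76)
        assert prior.distribution.params["shape"] == pytest.approx(11.7)

    def test_single_family_passthrough_without_weight(self):
        fit = _fake_fit(100.0)
        prior = dominant_component(fit, kind=ParameterKind.A)
        assert prior.mixture_weight is None
        assert prior.distribution.family is Family.GAMMA


class TestLargePoolSelection:
    @pytest.mark.parametrize("kind", [ParameterKind.A, ParameterKind.T_ER,
                                      ParameterKind.S_Z_R],
                             ids=lambda k: k.value)
    def test_generating_family_selected_on_large_pools(self, kind):
        """With n = 5000 draws straight from a known family, wAIC must
        select that family (or a mixture it dominates) across seeds."""
        from ddmpriors.synthetic_data import default_true_priors
        from ddmpriors.transforms import PooledSample
        from ddmpriors.distfit import fit_candidates
        true = default_true_priors()[kind]
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(7000 + seed)
            x = true.rvs(5000, rng)
            sample = PooledSample(
                kind=kind, values=x, n=x.size,
                empirical_lower=float(x.min()),
                empirical_upper=float(x.max()))
            fits = fit_candidates(sample, kind, n_starts=6, seed=seed)
            best = select_best(fits)
            fam = (best.spec.canonicalized().component1.family
                   if isinstance(best.spec, MixtureSpec)
                   else best.spec.family)
            hits += fam is true.family
        assert hits == 3


class TestSampling:
    def test_draws_respect_truncation(self, rng):
        spec = DistributionSpec(Family.TRUNCATED_T,
                                {"location": 0.5, "scale": 0.05, "df": 1.85},
                                0.0, 1.0)
        x = spec.rvs(5000, rng)
        assert np.all((x >= 0.0) & (x <= 1.0))
        assert np.mean(x) == pytest.approx(0.5, abs=0.02)

    def test_gamma_moments(self, rng):
        spec = DistributionSpec(Family.GAMMA,
                                {"shape": 11.69, "scale": 0.12}, 0.0, INF)
        x = spec.rvs(20000, rng)
        mean = 11.69 * 0.12
        se = math.sqrt(11.69) * 0.12 / math.sqrt(x.size)
        assert abs(np.mean(x) - mean) < 3 * se
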