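"""ILR transform, mixture likelihood, sampler behaviour, convergence stats."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from isomix import (
    MCMCConfig,
    MixingParams,
    ModelSpec,
    SourceSummary,
    TEFSpec,
    expected_mixture,
    gelman_rubin,
    ilr_forward,
    ilr_inverse,
    linear_predictor,
    log_likelihood,
    sample_posterior,
)
from tests.conftest import make_consumer


class TestILR:
    def test_even_split_maps_to_zero(self):
        assert ilr_forward(np.array([0.5, 0.5])) == pytest.approx([0.0])
        assert ilr_forward(np.full(3, 1 / 3)) == pytest.approx([0.0, 0.0])

    def test_two_part_closed_form(self):
        # z = (1/sqrt(2)) ln(p1/p2)
        z = ilr_forward(np.array([0.8, 0.2]))
        assert z[0] == pytest.approx(math.log(4.0) / math.sqrt(2.0), abs=1e-9)
        assert z[0] == pytest.approx(0.98026, abs=1e-5)

    def test_inverse_at_zero(self):
        assert ilr_inverse(np.zeros(1)) == pytest.approx([0.5, 0.5])

    def test_large_coordinate_limit(self):
        p = ilr_inverse(np.array([30.0]))
        assert p[0] == pytest.approx(1.0, abs=1e-12)

    @given(
        st.lists(st.floats(0.01, 0.99), min_size=2, max_size=5).filter(
            lambda v: sum(v) > 0
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, raw):
        p = np.array(raw) / sum(raw)
        back = ilr_inverse(ilr_forward(p), k=len(p))
        assert np.max(np.abs(back - p)) < 1e-12
        assert float(back.sum()) == pytest.approx(1.0, abs=1e-12)
        assert np.all(back > 0)

    def test_zero_component_rejected(self):
        with pytest.raises(ValueError):
            ilr_forward(np.array([1.0, 0.0]))

    def test_matches_scikit_bio_basis(self):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        for p in ([0.8, 0.2], [0.5, 0.3, 0.2], [0.1, 0.2, 0.3, 0.4]):
            ours = ilr_forward(np.array(p))
            theirs = skbio_comp.ilr(np.array(p))
            assert ours == pytest.approx(theirs, abs=1e-10)


class TestLinearPredictor:
    def _spec(self, two_sources, omnivore_tef, **flags):
        return ModelSpec(sources=two_sources, tef=omnivore_tef, **flags)

    def test_null_model_returns_intercept(self, two_sources, omnivore_tef):
        spec = self._spec(two_sources, omnivore_tef)
        params = MixingParams(ilr_intercept=np.array([0.7]), resid_sd=np.array([0.5, 0.5]))
        assert linear_predictor(spec, params) == pytest.approx([0.7])

    def test_zero_effects_reduce_to_intercept(self, two_sources, omnivore_tef):
        spec = self._spec(
            two_sources, omnivore_tef, include_site=True, include_species=True,
            include_length=True,
        )
        params = MixingParams(
            ilr_intercept=np.array([0.7]),
            resid_sd=np.array([0.5, 0.5]),
            species_effects=np.zeros((3, 1)),
            sigma_species=0.3,
            site_effects=np.zeros((2, 1)),
            sigma_site=0.2,
            beta_length=np.array([0.0]),
        )
        eta = linear_predictor(spec, params, species_index=1, site_index=0, z_length=0.0)
        assert eta == pytest.approx([0.7])

    def test_length_term_arithmetic(self, two_sources, omnivore_tef):
        spec = self._spec(two_sources, omnivore_tef, include_length=True)
        params = MixingParams(
            ilr_intercept=np.array([0.0]),
            resid_sd=np.array([0.5, 0.5]),
            beta_length=np.array([0.5]),
        )
        assert linear_predictor(spec, params, z_length=2.0) == pytest.approx([1.0])

    def test_unknown_species_index_errors(self, two_sources, omnivore_tef):
        spec = self._spec(two_sources, omnivore_tef, include_species=True)
        params = MixingParams(
            ilr_intercept=np.array([0.0]),
            resid_sd=np.array([0.5, 0.5]),
            species_effects=np.zeros((3, 1)),
            sigma_species=0.3,
        )
        with pytest.raises(IndexError):
            linear_predictor(spec, params, species_index=7)


class TestExpectedMixture:
    def test_pure_algal_diet(self, two_sources, omnivore_tef):
        mean, var = expected_mixture(
            np.array([1.0, 0.0]), two_sources, omnivore_tef, "d13C"
        )
        assert mean == pytest.approx(-23.3 + 0.6)
        assert var == pytest.approx(2.42**2 + 1.3**2)

    def test_even_mix_zero_variance(self):
        sources = (
            SourceSummary("a", {"d13C": -20.0}, {"d13C": 0.0}, 3),
            SourceSummary("b", {"d13C": -30.0}, {"d13C": 0.0}, 3),
        )
        tef = TEFSpec("omnivore", {"d13C": 0.0}, {"d13C": 0.0})
        mean, var = expected_mixture(np.array([0.5, 0.5]), sources, tef, "d13C")
        assert mean == pytest.approx(-25.0)
        assert var == pytest.approx(0.0)

    def test_variance_matches_monte_carlo_oracle(self, two_sources, omnivore_tef, rng):
        # mechanism oracle: sample per-source values and TEFs, mix, measure
        p = np.array([0.7, 0.3])
        n = 1_000_000
        mu = np.array([s.means["d13C"] for s in two_sources])
        om = np.array([s.sds["d13C"] for s in two_sources])
        lam, tau = omnivore_tef.means["d13C"], omnivore_tef.sds["d13C"]
        x = mu + om * rng.standard_normal((n, 2))
        t = lam + tau * rng.standard_normal((n, 2))
        mixed = (p * (x + t)).sum(axis=1) + 0.5 * rng.standard_normal(n)
        mean, var = expected_mixture(p, two_sources, omnivore_tef, "d13C", resid_sd=0.5)
        assert mean == pytest.approx(mixed.mean(), abs=3 * mixed.std() / math.sqrt(n))
        mc_var = mixed.var()
        se_var = mc_var * math.sqrt(2.0 / n)  # SE of a normal variance estimate
        assert var == pytest.approx(mc_var, abs=3 * se_var)

    def test_missing_tracer_is_configuration_error(self, two_sources, omnivore_tef):
        with pytest.raises(KeyError):
            expected_mixture(np.array([0.5, 0.5]), two_sources, omnivore_tef, "d34S")


class TestLogLikelihood:
    def _spec(self, two_sources, omnivore_tef, **kw):
        return ModelSpec(sources=two_sources, tef=omnivore_tef, **kw)

    def test_consumer_at_mode(self, two_sources, omnivore_tef):
        spec = self._spec(two_sources, omnivore_tef, tracers=("d13C",))
        params = MixingParams(ilr_intercept=np.array([0.0]), resid_sd=np.array([0.5]))
        p = ilr_inverse(params.ilr_intercept)
        mean, var = expected_mixture(p, two_sources, omnivore_tef, "d13C", resid_sd=0.5)
        consumer = make_consumer(d13C=mean)
        total, pointwise = log_likelihood(spec, params, [consumer])
        assert total == pytest.approx(-0.5 * math.log(2 * math.pi * var), abs=1e-10)

    def test_agreement_with_normal_density_oracle(self, two_sources, omnivore_tef, rng):
        # independent route: scipy normal logpdf at moments assembled by hand
        spec = self._spec(two_sources, omnivore_tef)
        for _ in range(20):
            eta = float(rng.normal(0, 1.5))
            resid = rng.uniform(0.1, 2.0, size=2)
            params = MixingParams(ilr_intercept=np.array([eta]), resid_sd=resid)
            consumers = [
                make_consumer(
                    record_id=f"c{i}",
                    d13C=float(rng.uniform(-33, -20)),
                    d15N=float(rng.uniform(2, 12)),
                )
                for i in range(4)
            ]
            total, _ = log_likelihood(spec, params, consumers)
            p = ilr_inverse(np.array([eta]))
            expected = 0.0
            for c in consumers:
                for j, tracer in enumerate(("d13C", "d15N")):
                    m, v = expected_mixture(
                        p, two_sources, omnivore_tef, tracer, resid_sd=float(resid[j])
                    )
                    expected += stats.norm.logpdf(getattr(c, tracer), m, math.sqrt(v))
            assert total == pytest.approx(expected, abs=1e-10)

    def test_additivity_when_doubling_consumers(self, two_sources, omnivore_tef):
        spec = self._spec(two_sources, omnivore_tef)
        params = MixingParams(ilr_intercept=np.array([0.3]), resid_sd=np.array([0.5, 0.5]))
        consumers = [make_consumer(record_id=f"c{i}", d13C=-26.0, d15N=7.0) for i in range(3)]
        single, _ = log_likelihood(spec, params, consumers)
        double, _ = log_likelihood(spec, params, consumers * 2)
        assert double == pytest.approx(2 * single, abs=1e-9)


class TestSamplePosterior:
    def test_prior_only_run_centers_on_even_split(self, two_sources, omnivore_tef):
        spec = ModelSpec(
            sources=two_sources, tef=omnivore_tef, likelihood_weight=0.0,
            fixed_resid_sd={"d13C": 0.5, "d15N": 0.5},
        )
        fit = sample_posterior(
            spec, [make_consumer()], MCMCConfig(chains=2, iterations=4000, seed=7)
        )
        p = fit.proportion_draws()[:, 0]
        assert p.mean() == pytest.approx(0.5, abs=0.03)

    def test_unambiguous_data_pins_diet(self, omnivore_tef):
        # consumers exactly at the TEF-shifted source-A mean, tight sources
        sources = (
            SourceSummary("a", {"d13C": -23.0, "d15N": 2.0}, {"d13C": 0.1, "d15N": 0.1}, 4),
            SourceSummary("b", {"d13C": -31.0, "d15N": 3.0}, {"d13C": 0.1, "d15N": 0.1}, 4),
        )
        tef = TEFSpec("omnivore", {"d13C": 0.6, "d15N": 4.8}, {"d13C": 0.1, "d15N": 0.1})
        consumers = [
            make_consumer(record_id=f"c{i}", d13C=-23.0 + 0.6, d15N=2.0 + 4.8)
            for i in range(30)
        ]
        spec = ModelSpec(sources=sources, tef=tef)
        fit = sample_posterior(spec, consumers, MCMCConfig(seed=11))
        assert fit.proportion_draws()[:, 0].mean() > 0.95

    def test_symmetric_consumer_stays_near_half(self, omnivore_tef):
        sources = (
            SourceSummary("a", {"d13C": -20.0}, {"d13C": 1.0}, 4),
            SourceSummary("b", {"d13C": -30.0}, {"d13C": 1.0}, 4),
        )
        tef = TEFSpec("omnivore", {"d13C": 0.0}, {"d13C": 1.0})
        spec = ModelSpec(sources=sources, tef=tef, tracers=("d13C",))
        fit = sample_posterior(
            spec, [make_consumer(d13C=-25.0)], MCMCConfig(seed=3)
        )
        assert fit.proportion_draws()[:, 0].mean() == pytest.approx(0.5, abs=0.05)

    def test_reproducible_given_seed(self, two_sources, omnivore_tef):
        spec = ModelSpec(sources=two_sources, tef=omnivore_tef)
        consumers = [make_consumer(record_id=f"c{i}", d13C=-26.0, d15N=7.5) for i in range(5)]
        cfg = MCMCConfig(chains=2, iterations=500, burn_in=300, seed=99)
        a = sample_posterior(spec, consumers, cfg)
        b = sample_posterior(spec, consumers, cfg)
        assert np.array_equal(a.draws, b.draws)
        c = sample_posterior(spec, consumers, MCMCConfig(chains=2, iterations=500, burn_in=300, seed=100))
        assert not np.array_equal(a.draws, c.draws)

    def test_site_species_relabeling_equivariance(self, two_sources, omnivore_tef, rng):
        """Permuting species labels permutes their effects but leaves the
        population-level posterior unchanged (same seed, same geometry)."""
        spec = ModelSpec(sources=two_sources, tef=omnivore_tef, include_species=True)
        consumers = [
            make_consumer(
                record_id=f"c{i}",
                species_code=f"sp{i % 3}",
                d13C=float(rng.normal(-26, 2)),
                d15N=float(rng.normal(7, 1)),
            )
            for i in range(18)
        ]
        cfg = MCMCConfig(chains=2, iterations=1500, burn_in=800, seed=5)
        fit = sample_posterior(spec, consumers, cfg)
        relabeled = [
            make_consumer(
                record_id=c.record_id,
                species_code={"sp0": "spB", "sp1": "spC", "sp2": "spA"}[c.species_code],
                d13C=c.d13C,
                d15N=c.d15N,
            )
            for c in consumers
        ]
        fit2 = sample_posterior(spec, relabeled, cfg)
        for code, new in (("sp0", "spB"), ("sp1", "spC"), ("sp2", "spA")):
            a = fit.proportion_draws(code)[:, 0]
            b = fit2.proportion_draws(new)[:, 0]
            assert a.mean() == pytest.approx(b.mean(), abs=0.04)


class TestGelmanRubin:
    def test_iid_chains_converged(self, rng):
        draws = rng.standard_normal((4, 2000))
        assert gelman_rubin(draws)[0] < 1.01

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 2000), rng.normal(10, 1, 2000)])
        assert gelman_rubin(chains)[0] > 2.0

    def test_copied_chains_near_one(self, rng):
        one = rng.standard_normal(1000)
        assert gelman_rubin(np.stack([one, one]))[0] == pytest.approx(1.0, abs=0.05)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((2, 100)))

    def test_needs_two_chains(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(rng.standard_normal((1, 100)))
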