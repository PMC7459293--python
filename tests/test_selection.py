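"""LOO scoring, model weights, posterior model averaging, lattice wiring."""

import numpy as np
import pandas as pd
import pytest

from isomix import (
    MCMCConfig,
    ModelSpec,
    SourceSummary,
    TEFSpec,
    build_lattice,
    compute_loo,
    exact_refit_loo,
    loo_weights,
    model_average,
    run_lattice,
    sample_posterior,
)
from isomix.selection import LOOResult
from tests.conftest import make_consumer


def _loo(looic: float, ids=("a", "b", "c")) -> LOOResult:
    n = len(ids)
    return LOOResult(
        elpd_loo=-looic / 2.0,
        se=1.0,
        pointwise=np.full(n, -looic / (2.0 * n)),
        pareto_k=np.zeros(n),
        consumer_ids=list(ids),
    )


class TestLooWeights:
    def test_equal_looic_splits_evenly(self):
        wt = loo_weights([_loo(100.0), _loo(100.0)])
        assert wt["weight"].tolist() == pytest.approx([0.5, 0.5])

    def test_delta_two_closed_form(self):
        wt = loo_weights([_loo(100.0), _loo(102.0)])
        e = np.exp(-1.0)
        assert wt["weight"].tolist() == pytest.approx([1 / (1 + e), e / (1 + e)], abs=1e-4)
        assert wt["weight"].iloc[0] == pytest.approx(0.7311, abs=1e-4)

    def test_extreme_delta_is_stable(self):
        wt = loo_weights([_loo(100.0), _loo(300.0)])
        assert np.isfinite(wt["weight"]).all()
        assert wt["weight"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        assert wt["weight"].sum() == pytest.approx(1.0, abs=1e-10)

    def test_invariant_to_constant_shift(self):
        a = loo_weights([_loo(10.0), _loo(14.0), _loo(11.0)])
        b = loo_weights([_loo(510.0), _loo(514.0), _loo(511.0)])
        assert a["weight"].tolist() == pytest.approx(b["weight"].tolist(), abs=1e-12)

    def test_different_consumer_sets_rejected(self):
        with pytest.raises(ValueError, match="different consumer"):
            loo_weights([_loo(10.0), _loo(11.0, ids=("x", "y", "z"))])

    def test_looic_is_minus_two_elpd(self):
        r = _loo(123.4)
        assert r.looic == pytest.approx(-2.0 * r.elpd_loo)

    def test_stacking_prefers_strictly_better_model(self):
        n = 20
        good = LOOResult(-0.5 * n, 1.0, np.full(n, -0.5), np.zeros(n),
                         [f"c{i}" for i in range(n)])
        bad = LOOResult(-2.0 * n, 1.0, np.full(n, -2.0), np.zeros(n),
                        [f"c{i}" for i in range(n)])
        wt = loo_weights([good, bad], method="stacking")
        assert wt["weight"].sum() == pytest.approx(1.0, abs=1e-8)
        assert wt["weight"].iloc[0] > 0.99


@pytest.fixture(scope="module")
def small_fit(request):
    """One small fitted model reused across LOO/averaging tests."""
    sources = (
        SourceSummary("a", {"d13C": -23.0}, {"d13C": 1.5}, 4),
        SourceSummary("b", {"d13C": -31.0}, {"d13C": 1.5}, 4),
    )
    tef = TEFSpec("omnivore", {"d13C": 0.6}, {"d13C": 1.0})
    spec = ModelSpec(
        sources=sources, tef=tef, tracers=("d13C",), fixed_resid_sd={"d13C": 0.8}
    )
    rng = np.random.default_rng(0)
    consumers = [
        make_consumer(record_id=f"c{i}", d13C=float(rng.normal(-26.0, 1.5)))
        for i in range(5)
    ]
    fit = sample_posterior(spec, consumers, MCMCConfig(chains=2, seed=21))
    return spec, consumers, fit


class TestComputeLoo:
    def test_elpd_matches_constant_pointwise(self, small_fit):
        _, consumers, fit = small_fit
        loo = compute_loo(fit)
        # definitional identity plus pointwise-sum consistency
        assert loo.looic == pytest.approx(-2.0 * loo.elpd_loo)
        assert loo.pointwise.sum() == pytest.approx(loo.elpd_loo, abs=1e-8)
        assert len(loo.pareto_k) == len(consumers)

    def test_constant_loglik_degenerate(self, small_fit):
        _, _, fit = small_fit
        from dataclasses import replace as _  # noqa: F401

        frozen = fit.__class__(**{**fit.__dict__})
        frozen.pointwise_loglik = np.full_like(fit.pointwise_loglik, -1.25)
        with pytest.raises(ValueError, match="degenerate|constant"):
            compute_loo(frozen)

    def test_matches_exact_refit_oracle(self, small_fit):
        spec, consumers, fit = small_fit
        psis = compute_loo(fit)
        exact = exact_refit_loo(
            spec, consumers, MCMCConfig(chains=2, iterations=2000, burn_in=1000, seed=33)
        )
        assert psis.elpd_loo == pytest.approx(
            exact.elpd_loo, abs=2.0 * max(psis.se, exact.se)
        )


class TestModelAverage:
    def test_single_model_identity(self, small_fit):
        _, _, fit = small_fit
        wt = pd.DataFrame({"model": ["only"], "looic": [10.0], "delta_looic": [0.0],
                           "weight": [1.0]})
        avg = model_average([fit], wt, "diet", seed=1)
        own = fit.proportion_draws("sp01")[:, 0]
        assert avg["mean"].iloc[0] == pytest.approx(own.mean(), abs=0.01)
        assert avg["q50"].iloc[0] == pytest.approx(np.median(own), abs=0.01)

    def test_interval_bounds_ordered(self, small_fit):
        _, _, fit = small_fit
        wt = pd.DataFrame({"model": ["m0", "m1"], "looic": [10.0, 11.0],
                           "delta_looic": [0.0, 1.0], "weight": [0.6225, 0.3775]})
        avg = model_average([fit, fit], wt, "diet", seed=2)
        row = avg.iloc[0]
        assert row["q2.5"] <= row["q25"] <= row["q50"] <= row["q75"] <= row["q97.5"]
        assert 0.0 <= row["q2.5"] and row["q97.5"] <= 1.0

    def test_mixture_quantiles_match_pooled_draw_oracle(self, small_fit):
        _, _, fit = small_fit
        wt = pd.DataFrame({"model": ["m0", "m1"], "looic": [0.0, 0.0],
                           "delta_looic": [0.0, 0.0], "weight": [0.5, 0.5]})
        avg = model_average([fit, fit], wt, "diet", n_draws=100_000, seed=3)
        pooled = fit.proportion_draws("sp01")[:, 0]  # both components identical
        for q, col in ((0.25, "q25"), (0.5, "q50"), (0.75, "q75")):
            assert avg[col].iloc[0] == pytest.approx(
                float(np.quantile(pooled, q)), abs=0.005
            )

    def test_point_mass_mixture_mean(self):
        """Two degenerate posteriors at p = 0.2 and p = 0.4 with equal
        weights average to 0.3."""
        fits = [_point_mass_posterior(p) for p in (0.2, 0.4)]
        wt = pd.DataFrame({"model": ["lo", "hi"], "looic": [0.0, 0.0],
                           "delta_looic": [0.0, 0.0], "weight": [0.5, 0.5]})
        avg = model_average(fits, wt, "diet", n_draws=200_000, seed=4)
        assert avg["mean"].iloc[0] == pytest.approx(0.3, abs=0.005)

    def test_weight_mismatch_rejected(self, small_fit):
        _, _, fit = small_fit
        wt = pd.DataFrame({"model": ["a"], "looic": [0.0], "delta_looic": [0.0],
                           "weight": [1.0]})
        with pytest.raises(ValueError, match="differ in length"):
            model_average([fit, fit], wt, "diet")


def _point_mass_posterior(p_value: float):
    """A fitted-posterior stand-in whose every draw encodes the same diet
    proportion (synthetic degenerate posterior for mixture arithmetic)."""
    from isomix.mixing import MixingPosterior, ModelSpec, _ParamLayout, ilr_forward

    sources = (
        SourceSummary("a", {"d13C": -23.0}, {"d13C": 1.0}, 4),
        SourceSummary("b", {"d13C": -31.0}, {"d13C": 1.0}, 4),
    )
    tef = TEFSpec("omnivore", {"d13C": 0.6}, {"d13C": 1.0})
    spec = ModelSpec(sources=sources, tef=tef, tracers=("d13C",),
                     fixed_resid_sd={"d13C": 0.5})
    layout = _ParamLayout(spec, n_species=1, n_sites=1)
    z = float(ilr_forward(np.array([p_value, 1.0 - p_value]))[0])
    draws = np.full((2, 500, layout.size), z)
    return MixingPosterior(
        spec=spec,
        draws=draws,
        pointwise_loglik=np.zeros((2, 500, 1)),
        param_names=layout.param_names(),
        rhat={"intercept": 1.0},
        accept_rate=np.ones(2),
        seed=0,
        species_codes=["sp01"],
        site_ids=["site1"],
        consumer_ids=["c1"],
        _layout=layout,
    )


class TestLattice:
    def test_single_species_gives_four_models(self, two_sources, omnivore_tef):
        base = ModelSpec(sources=two_sources, tef=omnivore_tef)
        specs, notes = build_lattice(base, n_species=1, n_sites=3)
        assert len(specs) == 4
        assert not any(s.include_species for s in specs)
        assert any("species" in n for n in notes)

    def test_single_site_drops_site_models_with_note(self, two_sources, omnivore_tef):
        base = ModelSpec(sources=two_sources, tef=omnivore_tef)
        specs, notes = build_lattice(base, n_species=5, n_sites=1)
        assert len(specs) == 4
        assert any("site" in n for n in notes)

    def test_full_lattice_has_eight_members(self, two_sources, omnivore_tef):
        base = ModelSpec(sources=two_sources, tef=omnivore_tef)
        specs, _ = build_lattice(base, n_species=5, n_sites=3)
        assert len(specs) == 8
        assert len({s.label for s in specs}) == 8

    def test_run_lattice_outputs_are_consistent(self, two_sources, omnivore_tef, rng):
        consumers = [
            make_consumer(
                record_id=f"c{i}",
                species_code="sp01",
                site_id=f"site{i % 2}",
                standard_length=float(rng.uniform(50, 200)),
                d13C=float(rng.normal(-26, 2)),
                d15N=float(rng.normal(7.5, 1.5)),
            )
            for i in range(24)
        ]
        res = run_lattice(
            consumers,
            two_sources,
            omnivore_tef,
            MCMCConfig(chains=2, iterations=800, burn_in=500, seed=17),
            guild="omnivore",
        )
        assert len(res.weight_table) == 4  # single species
        assert res.weight_table["weight"].sum() == pytest.approx(1.0, abs=1e-10)
        assert res.weight_table["delta_looic"].min() == pytest.approx(0.0)
        assert set(res.diet_estimates["species_code"]) == {"sp01"}
        assert {"ilr", "proportion"} == set(res.effects["scale"])
        assert len(res.convergence) == 4
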