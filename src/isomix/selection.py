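"""Model comparison and averaging over the covariate lattice.

Each guild/habitat analysis fits every admissible combination of the three
covariate flags (site, species, length) — the full lattice has 8 members —
then scores each fit by PSIS-LOO (leave-one-out cross-validation), converts
LOOic differences to Akaike-style weights w_m proportional to
exp(-delta_LOOic_m / 2), and forms model-averaged posteriors by resampling
draws from each model in proportion to its weight (a mixture of posterior
distributions, not an average of summaries).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ConsumerRecord, SourceSummary, TEFSpec
from .mixing import (
    MCMCConfig,
    MixingPosterior,
    ModelSpec,
    _PosteriorDensity,
    sample_posterior,
)
from .preprocess import standardize_lengths

__all__ = [
    "LOOResult",
    "compute_loo",
    "exact_refit_loo",
    "loo_weights",
    "model_average",
    "LatticeResult",
    "build_lattice",
    "run_lattice",
]

#: Pareto-k above this marks a consumer whose LOO contribution is unreliable.
PARETO_K_WARN = 0.7

_QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


@dataclass
class LOOResult:
    """PSIS-LOO score for one fitted model."""

    elpd_loo: float
    se: float
    pointwise: np.ndarray  # per-consumer elpd contributions
    pareto_k: np.ndarray
    consumer_ids: list[str]

    @property
    def looic(self) -> float:
        return -2.0 * self.elpd_loo

    @property
    def flagged(self) -> list[str]:
        """Consumers whose Pareto-k exceeds the reliability threshold."""
        return [
            cid for cid, k in zip(self.consumer_ids, self.pareto_k) if k > PARETO_K_WARN
        ]


def compute_loo(posterior: MixingPosterior) -> LOOResult:
    """PSIS-smoothed importance-sampling LOO from the stored pointwise
    log-likelihood draws (needs >= 100 post-burn-in draws)."""
    import arviz as az

    ll = posterior.pointwise_loglik
    if ll.shape[0] * ll.shape[1] < 100:
        raise ValueError("need >= 100 post-burn-in draws for PSIS-LOO")
    if np.allclose(ll.var(axis=(0, 1)), 0.0):
        raise ValueError("pointwise log-likelihood is constant across draws; "
                         "importance weights are degenerate")
    idata = az.from_dict(
        posterior={"theta0": posterior.draws[:, :, 0]},
        log_likelihood={"obs": ll},
    )
    res = az.loo(idata, pointwise=True)
    return LOOResult(
        elpd_loo=float(res.elpd_loo),
        se=float(res.se),
        pointwise=np.asarray(res.loo_i.values, dtype=float),
        pareto_k=np.asarray(res.pareto_k.values, dtype=float),
        consumer_ids=list(posterior.consumer_ids),
    )


def exact_refit_loo(
    spec: ModelSpec,
    consumers: Sequence[ConsumerRecord],
    config: MCMCConfig,
    z_lengths: Sequence[float] | None = None,
) -> LOOResult:
    """Exact leave-one-out: refit the model n times, each time holding one
    consumer out, and score the held-out consumer against the reduced
    posterior.  Expensive (n refits) but free of importance-sampling error;
    the recommended fallback when many Pareto-k diagnostics exceed 0.7.
    """
    consumers = list(consumers)
    if z_lengths is None and spec.include_length:
        z_lengths, _ = standardize_lengths(consumers)
    z = None if z_lengths is None else np.asarray(z_lengths, dtype=float)
    pointwise = np.empty(len(consumers))
    for i, held_out in enumerate(consumers):
        rest = consumers[:i] + consumers[i + 1 :]
        z_rest = None if z is None else np.delete(z, i)
        sub_seed = None if config.seed is None else (config.seed * 1_000 + i) % 2**31
        fit = sample_posterior(spec, rest, replace(config, seed=sub_seed), z_rest)
        # held-out log predictive density under the reduced posterior
        dens = _PosteriorDensity(spec, [held_out], None if z is None else z[i : i + 1])
        theta = fit.draws.reshape(-1, fit.draws.shape[-1])
        ll = dens.pointwise_loglik(theta)[:, 0]
        m = ll.max()
        pointwise[i] = m + math.log(np.mean(np.exp(ll - m)))
    elpd = float(pointwise.sum())
    se = float(math.sqrt(len(consumers) * pointwise.var(ddof=0)))
    return LOOResult(
        elpd_loo=elpd,
        se=se,
        pointwise=pointwise,
        pareto_k=np.zeros(len(consumers)),
        consumer_ids=[c.record_id for c in consumers],
    )


def loo_weights(
    results: Sequence[LOOResult],
    labels: Sequence[str] | None = None,
    method: str = "looic",
) -> pd.DataFrame:
    """Model weights from LOO scores.

    The default ("looic") gives Akaike-style weights, w_m proportional to
    exp(-delta_LOOic_m / 2) with delta relative to the best (lowest) LOOic,
    computed with a log-sum-exp so extreme deltas do not under/overflow.
    ``method="stacking"`` instead maximizes the pooled log score of the
    weighted pointwise predictive densities (offered for comparison; it
    tends to zero out redundant models rather than splitting weight among
    them).  All models must have been scored on the same consumers.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 models to weight")
    ids0 = results[0].consumer_ids
    for r in results[1:]:
        if r.consumer_ids != ids0:
            raise ValueError("models were fitted to different consumer sets")
    if labels is None:
        labels = [f"model_{i}" for i in range(len(results))]
    looic = np.array([r.looic for r in results])
    delta = looic - looic.min()
    if method == "looic":
        logw = -delta / 2.0
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
    elif method == "stacking":
        w = _stacking_weights(np.stack([r.pointwise for r in results]))
    else:
        raise ValueError(f"unknown weighting method {method!r}")
    return pd.DataFrame(
        {"model": list(labels), "looic": looic, "delta_looic": delta, "weight": w}
    )


def _stacking_weights(pointwise: np.ndarray) -> np.ndarray:
    """Maximize sum_i log sum_m w_m exp(elpd_im) over the weight simplex
    (softmax parametrization, quasi-Newton optimizer)."""
    from scipy import optimize, special

    m, _ = pointwise.shape
    lp = pointwise - pointwise.max(axis=0, keepdims=True)

    def neg_score(alpha: np.ndarray) -> float:
        logw = alpha - special.logsumexp(alpha)
        return -float(special.logsumexp(lp + logw[:, None], axis=0).sum())

    res = optimize.minimize(neg_score, np.zeros(m), method="L-BFGS-B")
    w = np.exp(res.x - special.logsumexp(res.x))
    return w / w.sum()


def _resample_counts(
    weights: np.ndarray, n_total: int, rng: np.random.Generator
) -> np.ndarray:
    return rng.multinomial(n_total, weights / weights.sum())


def _summary_row(draws: np.ndarray) -> dict[str, float]:
    qs = np.quantile(draws, _QUANTILES)
    return {
        "mean": float(draws.mean()),
        "q2.5": float(qs[0]),
        "q25": float(qs[1]),
        "q50": float(qs[2]),
        "q75": float(qs[3]),
        "q97.5": float(qs[4]),
    }


def model_average(
    posteriors: Sequence[MixingPosterior],
    weights: pd.DataFrame,
    quantity: str = "diet",
    n_draws: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Weight-proportional mixture of the models' posteriors.

    ``quantity`` is "diet" (per-species proportion of the first source, the
    algal-biofilm pathway by convention) or "length_effect" (reported on both
    the ILR-coefficient scale and as the change in first-source proportion
    from z = -1 to z = +1; models without the length term contribute zeros).
    Draw counts per model are multinomial in the weights, seeded.
    """
    if len(posteriors) != len(weights):
        raise ValueError("weights table and posterior list differ in length")
    w = weights["weight"].to_numpy(dtype=float)
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    n_total = n_draws or min(p.n_draws for p in posteriors)
    counts = _resample_counts(w, n_total, rng)

    if quantity == "diet":
        species = list(
            dict.fromkeys(sp for p in posteriors for sp in p.species_codes)
        )
        rows = []
        for sp in species:
            mixture = []
            provenance = {}
            for post_, c, label in zip(posteriors, counts, weights["model"]):
                if c == 0:
                    continue
                draws = post_.proportion_draws(sp)[:, 0]
                idx = rng.integers(0, len(draws), size=c)
                mixture.append(draws[idx])
                provenance[label] = int(c)
            pooled = np.concatenate(mixture)
            row = {"species_code": sp, **_summary_row(pooled), "n_draws": len(pooled)}
            row["provenance"] = ";".join(f"{k}:{v}" for k, v in provenance.items())
            rows.append(row)
        return pd.DataFrame(rows)

    if quantity == "length_effect":
        mix_ilr, mix_prop = [], []
        for post_, c in zip(posteriors, counts):
            if c == 0:
                continue
            beta, dprop = post_.length_effect_draws()
            idx = rng.integers(0, len(beta), size=c)
            mix_ilr.append(beta[idx, 0])
            mix_prop.append(dprop[idx])
        rows = []
        for scale, pooled in (
            ("ilr", np.concatenate(mix_ilr)),
            ("proportion", np.concatenate(mix_prop)),
        ):
            row = {"scale": scale, **_summary_row(pooled), "n_draws": len(pooled)}
            row["significant"] = bool(row["q2.5"] > 0 or row["q97.5"] < 0)
            rows.append(row)
        return pd.DataFrame(rows)

    raise ValueError(f"unknown quantity {quantity!r}")


# ---------------------------------------------------------------------------
# the covariate lattice
# ---------------------------------------------------------------------------

@dataclass
class LatticeResult:
    """Everything a guild/habitat analysis produces."""

    guild: str | None
    habitat: str | None
    weight_table: pd.DataFrame
    diet_estimates: pd.DataFrame
    effects: pd.DataFrame
    posteriors: dict[str, MixingPosterior]
    loos: dict[str, LOOResult]
    convergence: pd.DataFrame
    notes: list[str] = field(default_factory=list)

    @property
    def top_model(self) -> str:
        i = int(self.weight_table["weight"].to_numpy().argmax())
        return str(self.weight_table["model"].iloc[i])


def build_lattice(
    base: ModelSpec, n_species: int, n_sites: int
) -> tuple[list[ModelSpec], list[str]]:
    """All admissible covariate subsets of the 8-model lattice.

    Species-flag models are dropped when only one species is present, and
    site-flag models when only one site is present (a note is returned;
    the flags are meaningless there, not an error).
    """
    notes: list[str] = []
    if n_species < 2:
        notes.append("single species in group: species-effect models dropped")
    if n_sites < 2:
        notes.append("single site in group: site-effect models dropped")
    specs = []
    for site, species, length in itertools.product((False, True), repeat=3):
        if species and n_species < 2:
            continue
        if site and n_sites < 2:
            continue
        specs.append(
            replace(
                base,
                include_site=site,
                include_species=species,
                include_length=length,
            )
        )
    return specs, notes


def run_lattice(
    consumers: Sequence[ConsumerRecord],
    sources: Sequence[SourceSummary],
    tef: TEFSpec,
    config: MCMCConfig | None = None,
    guild: str | None = None,
    habitat: str | None = None,
    tracers: tuple[str, ...] = ("d13C", "d15N"),
) -> LatticeResult:
    """Fit every admissible lattice member for one guild/habitat group, then
    weight by LOOic and model-average diet proportions and the length effect.

    Consumers are assumed pre-filtered to the group (a guild/habitat filter
    is applied defensively when the arguments are given).  Lengths are
    standardized once, so every model sees the same z-scores.
    """
    config = config or MCMCConfig()
    consumers = [
        c
        for c in consumers
        if (guild is None or c.guild == guild)
        and (habitat is None or c.habitat == habitat)
    ]
    if not consumers:
        raise ValueError("no consumers in this guild/habitat group")

    z_lengths, _ = standardize_lengths(consumers)
    n_species = len({c.species_code for c in consumers})
    n_sites = len({c.site_id for c in consumers})
    base = ModelSpec(
        sources=tuple(sources), tef=tef, tracers=tracers, guild=guild, habitat=habitat
    )
    specs, notes = build_lattice(base, n_species, n_sites)

    posteriors: dict[str, MixingPosterior] = {}
    loos: dict[str, LOOResult] = {}
    conv_rows = []
    for i, spec in enumerate(specs):
        sub_seed = None if config.seed is None else (config.seed * 100 + i) % 2**31
        fit = sample_posterior(spec, consumers, replace(config, seed=sub_seed), z_lengths)
        posteriors[spec.label] = fit
        loos[spec.label] = compute_loo(fit)
        conv_rows.append(
            {
                "model": spec.label,
                "max_rhat": fit.max_rhat,
                "converged": fit.converged,
                "min_accept": float(fit.accept_rate.min()),
                "n_pareto_k_flagged": len(loos[spec.label].flagged),
            }
        )
        frac_bad = len(loos[spec.label].flagged) / len(consumers)
        if frac_bad > 0.10:
            notes.append(
                f"model '{spec.label}': {frac_bad:.0%} of consumers have "
                f"Pareto-k > {PARETO_K_WARN}; consider exact_refit_loo"
            )

    labels = [s.label for s in specs]
    wt = loo_weights([loos[m] for m in labels], labels)
    avg_seed = None if config.seed is None else (config.seed * 100 + 97) % 2**31
    diet = model_average(
        [posteriors[m] for m in labels], wt, "diet", seed=avg_seed
    )
    effects = model_average(
        [posteriors[m] for m in labels], wt, "length_effect", seed=avg_seed
    )
    if guild is not None:
        diet.insert(0, "guild", guild)
        effects.insert(0, "guild", guild)
    if habitat is not None:
        diet.insert(0, "habitat", habitat)
        effects.insert(0, "habitat", habitat)
    return LatticeResult(
        guild=guild,
        habitat=habitat,
        weight_table=wt,
        diet_estimates=diet,
        effects=effects,
        posteriors=posteriors,
        loos=loos,
        convergence=pd.DataFrame(conv_rows),
        notes=notes,
    )
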