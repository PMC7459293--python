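"""Hierarchical Bayesian mixing model for K-source diets on the ILR scale.

The estimand is each consumer's diet-proportion vector p over K basal
sources.  Proportions are modelled through the isometric log-ratio (ILR)
transform, which maps the open K-simplex to unrestricted R^(K-1) so that a
linear model applies:

    ilr(p_i) = intercept + species[i] + site[i] + beta * z_length_i

with species and site as zero-mean normal random effects and standardized
length as a fixed effect.  Observed tissue isotope values get a Gaussian
likelihood whose moments mix TEF-shifted source distributions:

    mean_j  = sum_k p_k (mu_jk + lambda_j)
    var_j   = sum_k p_k^2 (omega_jk^2 + tau_j^2) + sigma_j^2

i.e. process error (source and TEF variability scaled by squared
proportions) plus a per-tracer residual SD.  Priors are proper but weakly
informative: Normal(0, 5) on intercept and length coefficient (approximately
flat on p for K = 2), half-normal(0, 2) on random-effect scales, and
half-normal(0, 5 permil) on residual SDs.

Sampling uses an adaptive random-walk Metropolis with per-chain covariance
adaptation during burn-in (frozen afterwards, so retained draws form a
time-homogeneous Markov chain); chains run vectorised side by side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import ConsumerRecord, SourceSummary, TEFSpec

__all__ = [
    "ilr_basis",
    "ilr_forward",
    "ilr_inverse",
    "PriorConfig",
    "MCMCConfig",
    "ModelSpec",
    "MixingParams",
    "MixingPosterior",
    "linear_predictor",
    "expected_mixture",
    "log_likelihood",
    "sample_posterior",
    "gelman_rubin",
]

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# isometric log-ratio transform
# ---------------------------------------------------------------------------

def ilr_basis(k: int) -> np.ndarray:
    """Orthonormal Helmert-style ILR contrast matrix, shape (k, k-1).

    Column j contrasts the geometric mean of the first j parts against part
    j+1; for k = 2 the single coordinate is (1/sqrt(2)) ln(p1/p2).  The basis
    depends on source input order, so outputs record that order.
    """
    if k < 2:
        raise ValueError("need at least 2 parts")
    v = np.zeros((k, k - 1))
    for j in range(1, k):
        v[:j, j - 1] = math.sqrt(1.0 / (j * (j + 1)))
        v[j, j - 1] = -math.sqrt(j / (j + 1.0))
    return v


def ilr_forward(p: np.ndarray) -> np.ndarray:
    """Map proportion vectors (last axis sums to 1, all parts > 0) to
    ILR coordinates of length K-1."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("ILR requires strictly positive proportions")
    logp = np.log(p)
    clr = logp - logp.mean(axis=-1, keepdims=True)
    return clr @ ilr_basis(p.shape[-1])


def ilr_inverse(z: np.ndarray, k: int | None = None) -> np.ndarray:
    """Map ILR coordinates back to the open simplex (rows sum to 1)."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if not np.all(np.isfinite(z)):
        raise ValueError("ILR coordinates must be finite")
    if k is None:
        k = z.shape[-1] + 1
    y = z @ ilr_basis(k).T
    y -= y.max(axis=-1, keepdims=True)
    e = np.exp(y)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative prior scales (see module docstring)."""

    intercept_sd: float = 5.0
    beta_sd: float = 5.0
    random_effect_scale: float = 2.0  # half-normal scale for sigma_species/site
    resid_sd_scale: float = 5.0  # half-normal scale, permil


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.  ``iterations`` counts retained post-burn-in draws
    per chain; ``burn_in`` draws are discarded (and used for adaptation)."""

    chains: int = 3
    iterations: int = 4_000
    burn_in: int = 2_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.chains < 1 or self.iterations < 1 or self.burn_in < 0:
            raise ValueError("invalid MCMC configuration")

    @classmethod
    def preset(cls, name: str, seed: int | None = None) -> "MCMCConfig":
        """Named presets: "test" (3 x 4,000 draws, 2,000 burn-in) and
        "full" (200,000 total iterations with a 50,000 burn-in)."""
        if name == "test":
            return cls(seed=seed)
        if name == "full":
            return cls(chains=3, iterations=150_000, burn_in=50_000, seed=seed)
        raise KeyError(f"unknown MCMC preset {name!r}")


@dataclass(frozen=True)
class ModelSpec:
    """One member of the covariate lattice for a guild/habitat analysis."""

    sources: tuple[SourceSummary, ...]
    tef: TEFSpec
    tracers: tuple[str, ...] = ("d13C", "d15N")
    include_site: bool = False
    include_species: bool = False
    include_length: bool = False
    guild: str | None = None
    habitat: str | None = None
    priors: PriorConfig = field(default_factory=PriorConfig)
    #: Fix residual SDs (tracer -> permil) instead of sampling them.
    fixed_resid_sd: dict | None = None
    #: Scale on the log-likelihood; 0 gives a prior-only run.
    likelihood_weight: float = 1.0

    def __post_init__(self) -> None:
        if len(self.sources) < 2:
            raise ValueError("mixing model needs K >= 2 sources")
        if not self.tracers:
            raise ValueError("at least one tracer required")
        for s in self.sources:
            for t in self.tracers:
                if t not in s.means:
                    raise ValueError(f"source {s.source_name!r} lacks tracer {t!r}")
        for t in self.tracers:
            if t not in self.tef.means:
                raise ValueError(f"TEF for guild {self.tef.guild!r} lacks tracer {t!r}")

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def flags(self) -> tuple[bool, bool, bool]:
        return (self.include_site, self.include_species, self.include_length)

    @property
    def label(self) -> str:
        parts = [
            name
            for name, on in (
                ("site", self.include_site),
                ("species", self.include_species),
                ("length", self.include_length),
            )
            if on
        ]
        return " + ".join(parts) if parts else "null"

    def source_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(mu, omega, lam, tau): source means/SDs (J, K) and TEF mean/SD (J,)."""
        j, k = len(self.tracers), self.n_sources
        mu = np.empty((j, k))
        omega = np.empty((j, k))
        lam = np.empty(j)
        tau = np.empty(j)
        for jj, t in enumerate(self.tracers):
            for kk, s in enumerate(self.sources):
                mu[jj, kk] = s.means[t]
                omega[jj, kk] = s.sds[t]
            lam[jj] = self.tef.means[t]
            tau[jj] = self.tef.sds[t]
        return mu, omega, lam, tau


@dataclass
class MixingParams:
    """A single point in parameter space (used for deterministic evaluation;
    the sampler works on the packed vector internally)."""

    ilr_intercept: np.ndarray  # (K-1,)
    resid_sd: np.ndarray  # (J,), permil
    species_effects: np.ndarray | None = None  # (S, K-1)
    sigma_species: float | None = None
    site_effects: np.ndarray | None = None  # (G, K-1)
    sigma_site: float | None = None
    beta_length: np.ndarray | None = None  # (K-1,)


# ---------------------------------------------------------------------------
# deterministic model pieces
# ---------------------------------------------------------------------------

def linear_predictor(
    spec: ModelSpec,
    params: MixingParams,
    species_index: int | None = None,
    site_index: int | None = None,
    z_length: float = 0.0,
) -> np.ndarray:
    """ILR-scale linear predictor for one consumer.

    Random effects contribute only when the corresponding flag is set on the
    spec; the length term uses the standardized length z.
    """
    eta = np.array(params.ilr_intercept, dtype=float)
    if spec.include_species:
        if params.species_effects is None:
            raise ValueError("spec includes species but params lack species_effects")
        if species_index is None or not (0 <= species_index < len(params.species_effects)):
            raise IndexError(f"species index {species_index} out of range")
        eta = eta + params.species_effects[species_index]
    if spec.include_site:
        if params.site_effects is None:
            raise ValueError("spec includes site but params lack site_effects")
        if site_index is None or not (0 <= site_index < len(params.site_effects)):
            raise IndexError(f"site index {site_index} out of range")
        eta = eta + params.site_effects[site_index]
    if spec.include_length:
        if params.beta_length is None:
            raise ValueError("spec includes length but params lack beta_length")
        eta = eta + np.asarray(params.beta_length, dtype=float) * z_length
    return eta


def expected_mixture(
    p: np.ndarray,
    sources: Sequence[SourceSummary],
    tef: TEFSpec,
    tracer: str,
    resid_sd: float = 0.0,
) -> tuple[float, float]:
    """Mean and variance (permil, permil^2) of a consumer's isotope value for
    one tracer, given its diet proportions.

    mean = sum_k p_k (mu_k + lambda); variance = sum_k p_k^2 (omega_k^2 +
    tau^2) + resid_sd^2 — TEF variability is realized independently per
    source (process error), plus residual variance.
    """
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != len(sources):
        raise ValueError("proportion vector length must match source count")
    if abs(float(p.sum()) - 1.0) > 1e-9 or np.any(p < 0):
        raise ValueError("p must be a probability vector")
    try:
        mu = np.array([s.means[tracer] for s in sources])
        om = np.array([s.sds[tracer] for s in sources])
        lam, tau = tef.means[tracer], tef.sds[tracer]
    except KeyError:
        raise KeyError(f"missing tracer {tracer!r} in sources or TEF") from None
    mean = float(p @ (mu + lam))
    var = float((p**2) @ (om**2 + tau**2)) + resid_sd**2
    return mean, var


def log_likelihood(
    spec: ModelSpec,
    params: MixingParams,
    consumers: Sequence[ConsumerRecord],
    z_lengths: Sequence[float] | None = None,
) -> tuple[float, np.ndarray]:
    """Gaussian log-likelihood of the consumers at one parameter point.

    Tracers are conditionally independent given the diet proportions.
    Returns (total, per-consumer pointwise values).
    """
    post = _PosteriorDensity(spec, consumers, z_lengths)
    theta = post.layout.pack(params)[None, :]
    pointwise = post.pointwise_loglik(theta)[0]
    return float(pointwise.sum()), pointwise


# ---------------------------------------------------------------------------
# parameter packing and the posterior density
# ---------------------------------------------------------------------------

class _ParamLayout:
    """Maps between MixingParams and the flat sampler vector.  Scales are
    sampled on the log scale (with the Jacobian folded into the prior)."""

    def __init__(self, spec: ModelSpec, n_species: int, n_sites: int):
        self.spec = spec
        self.d_ilr = spec.n_sources - 1
        self.n_species = n_species
        self.n_sites = n_sites
        self.n_tracers = len(spec.tracers)
        self.sample_resid = spec.fixed_resid_sd is None
        slices: dict[str, slice] = {}
        pos = 0

        def add(name: str, size: int) -> None:
            nonlocal pos
            slices[name] = slice(pos, pos + size)
            pos += size

        add("intercept", self.d_ilr)
        if spec.include_length:
            add("beta_length", self.d_ilr)
        if spec.include_species:
            add("species_effects", n_species * self.d_ilr)
            add("log_sigma_species", 1)
        if spec.include_site:
            add("site_effects", n_sites * self.d_ilr)
            add("log_sigma_site", 1)
        if self.sample_resid:
            add("log_resid_sd", self.n_tracers)
        self.slices = slices
        self.size = pos
        if not self.sample_resid:
            self.fixed_resid = np.array(
                [spec.fixed_resid_sd[t] for t in spec.tracers], dtype=float
            )

    def param_names(self) -> list[str]:
        """One label per flat coordinate, for diagnostics and CSV export."""
        names: list[str] = []
        for key, sl in self.slices.items():
            width = sl.stop - sl.start
            if width == 1:
                names.append(key)
            elif key in ("species_effects", "site_effects"):
                for u in range(width // self.d_ilr):
                    for v in range(self.d_ilr):
                        names.append(f"{key}[{u},{v}]")
            else:
                names.extend(f"{key}[{v}]" for v in range(width))
        return names

    def pack(self, params: MixingParams) -> np.ndarray:
        theta = np.zeros(self.size)
        theta[self.slices["intercept"]] = np.asarray(params.ilr_intercept, dtype=float)
        if "beta_length" in self.slices:
            theta[self.slices["beta_length"]] = np.asarray(params.beta_length, dtype=float)
        if "species_effects" in self.slices:
            theta[self.slices["species_effects"]] = np.asarray(
                params.species_effects, dtype=float
            ).ravel()
            theta[self.slices["log_sigma_species"]] = math.log(params.sigma_species)
        if "site_effects" in self.slices:
            theta[self.slices["site_effects"]] = np.asarray(
                params.site_effects, dtype=float
            ).ravel()
            theta[self.slices["log_sigma_site"]] = math.log(params.sigma_site)
        if self.sample_resid:
            theta[self.slices["log_resid_sd"]] = np.log(
                np.asarray(params.resid_sd, dtype=float)
            )
        return theta

    def unpack(self, theta: np.ndarray) -> MixingParams:
        theta = np.asarray(theta, dtype=float)
        get = lambda name: theta[..., self.slices[name]]
        kwargs: dict = {
            "ilr_intercept": get("intercept"),
            "resid_sd": (
                np.exp(get("log_resid_sd")) if self.sample_resid else self.fixed_resid.copy()
            ),
        }
        if "beta_length" in self.slices:
            kwargs["beta_length"] = get("beta_length")
        if "species_effects" in self.slices:
            kwargs["species_effects"] = get("species_effects").reshape(
                self.n_species, self.d_ilr
            )
            kwargs["sigma_species"] = float(np.exp(get("log_sigma_species")))
        if "site_effects" in self.slices:
            kwargs["site_effects"] = get("site_effects").reshape(self.n_sites, self.d_ilr)
            kwargs["sigma_site"] = float(np.exp(get("log_sigma_site")))
        return MixingParams(**kwargs)


class _PosteriorDensity:
    """Vectorised log-posterior over a batch of parameter vectors."""

    def __init__(
        self,
        spec: ModelSpec,
        consumers: Sequence[ConsumerRecord],
        z_lengths: Sequence[float] | None = None,
    ):
        if not consumers:
            raise ValueError("need at least one consumer")
        self.spec = spec
        self.consumers = list(consumers)
        self.species_codes = list(dict.fromkeys(c.species_code for c in consumers))
        self.site_ids = list(dict.fromkeys(c.site_id for c in consumers))
        self.sp_idx = np.array(
            [self.species_codes.index(c.species_code) for c in consumers]
        )
        self.site_idx = np.array([self.site_ids.index(c.site_id) for c in consumers])
        if spec.include_length:
            if z_lengths is None:
                from .preprocess import standardize_lengths

                z_lengths, _ = standardize_lengths(consumers)
            self.z = np.asarray(z_lengths, dtype=float)
            if len(self.z) != len(consumers):
                raise ValueError("z_lengths length mismatch")
        else:
            self.z = np.zeros(len(consumers))
        self.x = np.array(
            [[getattr(c, t) for t in spec.tracers] for c in consumers], dtype=float
        )  # (n, J)
        if not np.all(np.isfinite(self.x)):
            raise ValueError("consumers must carry finite values for the model's tracers")
        self.mu, self.omega, self.lam, self.tau = spec.source_arrays()
        self.v_basis = ilr_basis(spec.n_sources)  # (K, K-1)
        self.layout = _ParamLayout(spec, len(self.species_codes), len(self.site_ids))

    # -- core evaluations ---------------------------------------------------

    def _proportions(self, theta: np.ndarray) -> np.ndarray:
        """Diet proportions per batch member and consumer, (M, n, K)."""
        lay = self.layout
        sl = lay.slices
        eta = theta[:, None, sl["intercept"]]  # (M, 1, D)
        if "species_effects" in sl:
            eff = theta[:, sl["species_effects"]].reshape(-1, lay.n_species, lay.d_ilr)
            eta = eta + eff[:, self.sp_idx, :]
        if "site_effects" in sl:
            eff = theta[:, sl["site_effects"]].reshape(-1, lay.n_sites, lay.d_ilr)
            eta = eta + eff[:, self.site_idx, :]
        if "beta_length" in sl:
            eta = eta + theta[:, None, sl["beta_length"]] * self.z[None, :, None]
        y = eta @ self.v_basis.T  # (M, n, K)
        y -= y.max(axis=-1, keepdims=True)
        e = np.exp(y)
        return e / e.sum(axis=-1, keepdims=True)

    def _resid_sd(self, theta: np.ndarray) -> np.ndarray:
        lay = self.layout
        if lay.sample_resid:
            return np.exp(theta[:, lay.slices["log_resid_sd"]])  # (M, J)
        return np.broadcast_to(lay.fixed_resid, (theta.shape[0], lay.n_tracers))

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Per-consumer log-likelihood for each batch member, (M, n)."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        p = self._proportions(theta)  # (M, n, K)
        sigma = self._resid_sd(theta)  # (M, J)
        out = np.zeros((theta.shape[0], len(self.consumers)))
        for j in range(self.layout.n_tracers):
            mean = p @ (self.mu[j] + self.lam[j])  # (M, n)
            var = (p**2) @ (self.omega[j] ** 2 + self.tau[j] ** 2) + (
                sigma[:, j] ** 2
            )[:, None]
            out += -0.5 * (_LOG_2PI + np.log(var)) - (self.x[:, j] - mean) ** 2 / (
                2.0 * var
            )
        return out * self.spec.likelihood_weight

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        lay, sl, pr = self.layout, self.layout.slices, self.spec.priors
        lp = -0.5 * np.sum((theta[:, sl["intercept"]] / pr.intercept_sd) ** 2, axis=1)
        if "beta_length" in sl:
            lp += -0.5 * np.sum((theta[:, sl["beta_length"]] / pr.beta_sd) ** 2, axis=1)
        for eff_name, sig_name in (
            ("species_effects", "log_sigma_species"),
            ("site_effects", "log_sigma_site"),
        ):
            if eff_name in sl:
                u = theta[:, sl[sig_name]][:, 0]
                sigma = np.exp(u)
                eff = theta[:, sl[eff_name]]
                n_eff = eff.shape[1]
                # effects | sigma ~ N(0, sigma); sigma ~ half-normal; +u Jacobian
                lp += (
                    -0.5 * np.sum(eff**2, axis=1) / sigma**2
                    - n_eff * u
                    - 0.5 * (sigma / pr.random_effect_scale) ** 2
                    + u
                )
        if lay.sample_resid:
            u = theta[:, sl["log_resid_sd"]]
            sigma = np.exp(u)
            lp += np.sum(-0.5 * (sigma / pr.resid_sd_scale) ** 2 + u, axis=1)
        return lp

    def log_posterior(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pointwise = self.pointwise_loglik(theta)
        return pointwise.sum(axis=1) + self.log_prior(theta), pointwise

    # -- diagnostics ----------------------------------------------------------

    def separation_warning(self, min_sep: float = 0.5) -> str | None:
        """Warn when no tracer separates any source pair by >= min_sep
        combined SDs (the model will struggle; consider pooling)."""
        k = self.spec.n_sources
        best = 0.0
        for j in range(self.layout.n_tracers):
            for a in range(k):
                for b in range(a + 1, k):
                    denom = math.sqrt(
                        self.omega[j, a] ** 2 + self.omega[j, b] ** 2 + 2 * self.tau[j] ** 2
                    )
                    if denom > 0:
                        best = max(best, abs(self.mu[j, a] - self.mu[j, b]) / denom)
        if best < min_sep:
            return (
                f"sources separated by only {best:.2f} combined SDs "
                f"(< {min_sep}); consider pooling overlapping sources"
            )
        return None


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

@dataclass
class MixingPosterior:
    """Posterior draws plus everything needed downstream (LOO, averaging)."""

    spec: ModelSpec
    draws: np.ndarray  # (chains, iterations, n_params)
    pointwise_loglik: np.ndarray  # (chains, iterations, n_consumers)
    param_names: list[str]
    rhat: dict[str, float]
    accept_rate: np.ndarray  # per chain
    seed: int | None
    species_codes: list[str]
    site_ids: list[str]
    consumer_ids: list[str]
    warnings: list[str] = field(default_factory=list)
    _layout: _ParamLayout | None = field(default=None, repr=False)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def converged(self) -> bool:
        """Convergence bar: every split-chain PSRF below 1.01."""
        return self.max_rhat < 1.01

    def flat(self, name: str) -> np.ndarray:
        """All draws of one named block, chains flattened: (n_draws, width)."""
        sl = self._layout.slices[name]
        return self.draws[..., sl].reshape(-1, sl.stop - sl.start)

    def proportion_draws(self, species_code: str | None = None) -> np.ndarray:
        """Draws of the diet-proportion vector (n_draws, K) for a typical
        individual: site effect 0, z-length 0, and the given species' random
        effect (or 0 for the population level when None / no species term)."""
        eta = self.flat("intercept")
        if species_code is not None and "species_effects" in self._layout.slices:
            s = self.species_codes.index(species_code)
            d = self._layout.d_ilr
            eff = self.flat("species_effects").reshape(self.n_draws, -1, d)
            eta = eta + eff[:, s, :]
        return ilr_inverse(eta, k=self.spec.n_sources)

    def length_effect_draws(self) -> tuple[np.ndarray, np.ndarray]:
        """(ILR-scale beta draws (n_draws, D), proportion-scale draws).

        The proportion scale is the change in the first source's proportion
        between z = -1 and z = +1 around the intercept.  Models without the
        length term contribute zeros.
        """
        if "beta_length" not in self._layout.slices:
            zeros = np.zeros((self.n_draws, self._layout.d_ilr))
            return zeros, np.zeros(self.n_draws)
        beta = self.flat("beta_length")
        eta0 = self.flat("intercept")
        k = self.spec.n_sources
        hi = ilr_inverse(eta0 + beta, k=k)[:, 0]
        lo = ilr_inverse(eta0 - beta, k=k)[:, 0]
        return beta, hi - lo

    def to_frame(self):
        """Draws as a tidy DataFrame (one row per draw, labelled columns)."""
        import pandas as pd

        c, i, d = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(c * i, d), columns=self.param_names)
        df.insert(0, "chain", np.repeat(np.arange(c), i))
        df.insert(1, "iteration", np.tile(np.arange(i), c))
        return df


def _laplace_init(post: _PosteriorDensity) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and a Cholesky factor of the local (Laplace)
    covariance, used to initialize chains and the proposal shape.

    Scale coordinates are bounded away from zero during the optimization:
    the centered random-effects density is unbounded along sigma -> 0 with
    all effects -> 0 (an integrable spike of negligible mass), and an
    unconstrained optimizer dives into it.  Eigen-variances of the inverse
    Hessian are clipped to keep early proposals sane along soft or
    unidentified directions.
    """
    from scipy import optimize

    lay = post.layout
    d = lay.size
    x0 = np.zeros(d)
    bounds: list[tuple[float | None, float | None]] = [(None, None)] * d
    for name, lo in (
        ("log_sigma_species", math.log(0.05)),
        ("log_sigma_site", math.log(0.05)),
        ("log_resid_sd", math.log(0.01)),
    ):
        if name in lay.slices:
            sl = lay.slices[name]
            x0[sl] = math.log(0.5)
            for i in range(sl.start, sl.stop):
                bounds[i] = (lo, math.log(50.0))

    def neg(theta: np.ndarray) -> float:
        return -float(post.log_posterior(theta[None, :])[0][0])

    res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
    mode = res.x

    # batched central-difference Hessian of -log posterior
    h = 1e-3
    pts = []
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h
            ej[j] = h
            pts.extend([mode + ei + ej, mode + ei - ej, mode - ei + ej, mode - ei - ej])
    vals = -post.log_posterior(np.asarray(pts))[0]
    hess = np.zeros((d, d))
    idx = 0
    for i in range(d):
        for j in range(i, d):
            f = vals[idx * 4 : (idx + 1) * 4]
            hess[i, j] = hess[j, i] = (f[0] - f[1] - f[2] + f[3]) / (4 * h * h)
            idx += 1
    w, v = np.linalg.eigh(hess)
    w = np.clip(w, 1.0 / 25.0, 1e6)  # proposal variance in [1e-6, 25] per direction
    cov = (v / w) @ v.T
    return mode, np.linalg.cholesky(cov + 1e-10 * np.eye(d))


def _slice_update_scale(
    u0: float, s2: float, n_eff: int, prior_scale: float, rng: np.random.Generator
) -> float:
    """Univariate slice sample of a log random-effect scale u given the
    effects (sum of squares s2 over n_eff scalars).  The conditional is
    prior-only — no likelihood evaluation:

        f(u) = -s2 e^{-2u} / 2 - (n_eff - 1) u - e^{2u} / (2 prior_scale^2)
    """

    def logf(u: float) -> float:
        return (
            -0.5 * s2 * math.exp(-2.0 * u)
            - (n_eff - 1) * u
            - 0.5 * math.exp(2.0 * u) / prior_scale**2
        )

    y = logf(u0) + math.log(rng.random() + 1e-300)
    w = 1.0
    lo = u0 - w * rng.random()
    hi = lo + w
    for _ in range(50):
        if logf(lo) <= y:
            break
        lo -= w
    for _ in range(50):
        if logf(hi) <= y:
            break
        hi += w
    for _ in range(100):
        u1 = lo + (hi - lo) * rng.random()
        if logf(u1) > y:
            return u1
        if u1 < u0:
            lo = u1
        else:
            hi = u1
    return u0


def sample_posterior(
    spec: ModelSpec,
    consumers: Sequence[ConsumerRecord],
    config: MCMCConfig | None = None,
    z_lengths: Sequence[float] | None = None,
) -> MixingPosterior:
    """Draw from the posterior with an adaptive random-walk Metropolis.

    Each iteration combines three moves: (1) a joint random-walk proposal
    whose covariance and step scale adapt per chain during burn-in
    (Laplace-initialized, frozen afterwards); (2) a likelihood-invariant
    recentering move that shifts mass between the intercept and each
    random-effect block along their soft trade-off direction (the
    acceptance ratio involves only priors, so it is essentially free); and
    (3) a prior-conditional slice update of each random-effect scale.
    Reproducible given ``config.seed``.  Non-convergence (any split-chain
    PSRF >= 1.01) is recorded in ``warnings`` rather than raised.
    """
    config = config or MCMCConfig()
    post = _PosteriorDensity(spec, consumers, z_lengths)
    lay = post.layout
    sl = lay.slices
    d, n_chains, d_ilr = lay.size, config.chains, lay.d_ilr
    rng = np.random.default_rng(config.seed)

    mode, chol0 = _laplace_init(post)
    theta = mode[None, :] + 0.5 * (rng.standard_normal((n_chains, d)) @ chol0.T)
    logp, pointwise = post.log_posterior(theta)

    target_acc = 0.234 if d > 4 else 0.35
    log_scale = np.full(n_chains, math.log(2.38 / math.sqrt(d)))
    chol = np.broadcast_to(chol0, (n_chains, d, d)).copy()
    mean = theta.copy()
    m2 = np.zeros((n_chains, d, d))
    count = 1

    re_blocks = [
        (eff, scale, prior)
        for eff, scale, prior in (
            ("species_effects", "log_sigma_species", spec.priors.random_effect_scale),
            ("site_effects", "log_sigma_site", spec.priors.random_effect_scale),
        )
        if eff in sl
    ]
    recenter_scale = {eff: np.zeros(n_chains) for eff, _, _ in re_blocks}
    isd2 = spec.priors.intercept_sd**2

    total = config.burn_in + config.iterations
    keep_draws = np.empty((n_chains, config.iterations, d))
    keep_pw = np.empty((n_chains, config.iterations, len(consumers)))
    accepted = np.zeros(n_chains)

    for t in range(total):
        adapting = t < config.burn_in
        eps = rng.standard_normal((n_chains, d))
        step = np.einsum("cij,cj->ci", chol, eps)
        prop = theta + np.exp(log_scale)[:, None] * step
        logp_prop, pw_prop = post.log_posterior(prop)
        accept = np.log(rng.random(n_chains)) < (logp_prop - logp)
        theta[accept] = prop[accept]
        logp[accept] = logp_prop[accept]
        pointwise[accept] = pw_prop[accept]

        for eff_name, scale_name, prior_scale in re_blocks:
            eff_sl, u_sl = sl[eff_name], sl[scale_name]
            # recentering: intercept += delta, every effect row -= delta
            delta = np.exp(recenter_scale[eff_name])[:, None] * rng.standard_normal(
                (n_chains, d_ilr)
            )
            inter = theta[:, sl["intercept"]]
            eff = theta[:, eff_sl].reshape(n_chains, -1, d_ilr)
            sig2 = np.exp(2.0 * theta[:, u_sl][:, 0])
            dlp = (
                ((inter**2).sum(1) - ((inter + delta) ** 2).sum(1)) / (2.0 * isd2)
                + ((eff**2).sum((1, 2)) - ((eff - delta[:, None, :]) ** 2).sum((1, 2)))
                / (2.0 * sig2)
            )
            r_acc = np.log(rng.random(n_chains)) < dlp
            theta[r_acc, sl["intercept"]] += delta[r_acc]
            eff[r_acc] -= delta[r_acc, None, :]
            theta[:, eff_sl] = eff.reshape(n_chains, -1)
            logp[r_acc] += dlp[r_acc]
            if adapting:
                recenter_scale[eff_name] += (t + 1) ** -0.6 * (
                    r_acc.astype(float) - 0.44
                )
            # slice-update the block scale from its prior-only conditional
            n_eff = eff_sl.stop - eff_sl.start
            for c in range(n_chains):
                s2 = float((theta[c, eff_sl] ** 2).sum())
                u_old = float(theta[c, u_sl][0])
                u_new = _slice_update_scale(u_old, s2, n_eff, prior_scale, rng)
                if u_new != u_old:
                    theta[c, u_sl] = u_new
                    sig_old2, sig_new2 = math.exp(2 * u_old), math.exp(2 * u_new)
                    logp[c] += (
                        -0.5 * s2 * (1 / sig_new2 - 1 / sig_old2)
                        - (n_eff - 1) * (u_new - u_old)
                        - 0.5 * (sig_new2 - sig_old2) / prior_scale**2
                    )

        if adapting:
            gamma = (t + 1) ** -0.6
            log_scale += gamma * (accept.astype(float) - target_acc)
            # online per-chain covariance for the proposal shape
            count += 1
            delta_m = theta - mean
            mean += delta_m / count
            m2 += np.einsum("ci,cj->cij", delta_m, theta - mean)
            if t >= 200 and t % 50 == 0:
                cov = m2 / (count - 1) + 1e-8 * np.eye(d)
                for c in range(n_chains):
                    try:
                        chol[c] = np.linalg.cholesky(cov[c])
                    except np.linalg.LinAlgError:
                        pass
        else:
            accepted += accept
            i = t - config.burn_in
            keep_draws[:, i] = theta
            keep_pw[:, i] = pointwise

    names = lay.param_names()
    warnings_out: list[str] = []
    if n_chains >= 2:
        rhat = dict(zip(names, gelman_rubin(keep_draws)))
    else:
        rhat = {name: float("nan") for name in names}
        warnings_out.append("single chain: split-chain PSRF unavailable")
    sep = post.separation_warning()
    if sep:
        warnings_out.append(sep)
    bad = [name for name, r in rhat.items() if not (r < 1.01)]
    if bad and n_chains >= 2:
        worst = max(rhat.values())
        warnings_out.append(
            f"non-convergence: split-chain PSRF >= 1.01 for {len(bad)} "
            f"parameter(s) (worst {worst:.3f})"
        )

    return MixingPosterior(
        spec=spec,
        draws=keep_draws,
        pointwise_loglik=keep_pw,
        param_names=names,
        rhat=rhat,
        accept_rate=accepted / config.iterations,
        seed=config.seed,
        species_codes=post.species_codes,
        site_ids=post.site_ids,
        consumer_ids=[c.record_id for c in consumers],
        warnings=warnings_out,
        _layout=lay,
    )


# ---------------------------------------------------------------------------
# convergence diagnostic
# ---------------------------------------------------------------------------

def gelman_rubin(draws: np.ndarray, rank_normalized: bool = False) -> np.ndarray:
    """Split-chain potential scale reduction factor (R-hat) per parameter.

    ``draws`` has shape (chains, iterations) or (chains, iterations,
    n_params).  Each chain is split in half, then R-hat = sqrt(((n-1)/n W +
    B/n) / W) with W the mean within-chain variance and B/n the variance of
    the split-chain means.  ``rank_normalized=True`` instead returns the
    rank-normalized variant (via arviz), which is more sensitive near
    convergence but saturates for grossly separated chains.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        return np.array([_split_rhat_1d(draws, rank_normalized)])
    if draws.ndim != 3:
        raise ValueError("draws must be (chains, iterations[, n_params])")
    return np.array(
        [_split_rhat_1d(draws[:, :, j], rank_normalized) for j in range(draws.shape[2])]
    )


def _split_rhat_1d(chains: np.ndarray, rank_normalized: bool) -> float:
    m, n = chains.shape
    if m < 2 or n < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    if rank_normalized:
        import arviz as az

        return float(az.rhat(az.convert_to_dataset(chains[:, :, None]))["x"].values)
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    within = split.var(axis=1, ddof=1)
    w = float(within.mean())
    if w == 0.0:
        raise ValueError("zero within-chain variance; R-hat undefined")
    b_over_n = float(split.mean(axis=1).var(ddof=1))
    var_hat = (half - 1) / half * w + b_over_n
    return math.sqrt(var_hat / w)
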