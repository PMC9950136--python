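"""Posterior sampling for the population tensor model.

Hamiltonian Monte Carlo over the joint vector of all parameters and
log-transformed hyperparameters, with

* leapfrog integration, step count S = min(100, ceil(1/eps));
* dual-averaging adaptation of the step size toward 80% acceptance during
  warmup (frozen for the final 4% of warmup);
* a diagonal mass matrix re-estimated twice during warmup from the inverse
  empirical variances of recent draws;
* an interleaved Metropolis-Hastings rescaling move that exploits the
  scale invariance of CP components (U,T,V) -> (aU, bT, V/(ab)): the move
  multiplies two factor norms by lognormal factors and divides the third
  to keep the product zeta = |U||T||V| fixed, so the likelihood is
  untouched and only the chi-distributed norm priors enter the acceptance
  probability.

Model comparison uses Pareto-smoothed importance sampling (PSIS) LOO over
per-trial pointwise log-likelihood draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gmlm import GmlmModel, GmlmParams, PopulationDesign
from .priors import StimulusPrior

logger = logging.getLogger(__name__)


@dataclass
class SamplerConfig:
    """Tuning constants of the sampler.

    The reference schedule is 25,000 warmup / 50,000 samples with mass
    updates at warmup samples 4,001 and 19,001 (windows 2,001-4,000 and
    4,001-19,000); ``scaled`` shrinks the schedule proportionally for
    desk-scale runs.
    """

    n_warmup: int = 25000
    n_samples: int = 50000
    target_accept: float = 0.8
    eps0: float = 0.01
    max_leapfrog: int = 100
    adapt_frac: float = 0.96  # eps adapted for the first 96% of warmup
    mass_window_fracs: tuple[float, float, float] = (0.08, 0.16, 0.76)
    mh_interleave: int = 10
    mh_omega: float = 0.2
    divergence_threshold: float = 1000.0
    seed: int = 0

    @classmethod
    def scaled(cls, n_warmup: int, n_samples: int, **kw) -> "SamplerConfig":
        return cls(n_warmup=n_warmup, n_samples=n_samples, **kw)

    def mass_update_points(self) -> tuple[int, int]:
        f0, f1, f2 = self.mass_window_fracs
        return (int(self.n_warmup * f1), int(self.n_warmup * f2))


@dataclass
class PosteriorSamples:
    """Post-warmup draws plus sampler diagnostics."""

    param_draws: np.ndarray  # (n_samples, n_params) float32
    hyper_draws: np.ndarray  # (n_samples, n_hyper), natural scale
    hyper_names: list[str]
    accept_flags: np.ndarray  # (n_samples,) bool, HMC proposals post-warmup
    accept_stats: np.ndarray  # (n_samples,) min(1, exp(-dH))
    eps_trace: np.ndarray
    n_divergent: int
    warmup_accept_flags: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.param_draws.shape[0]

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accept_flags))

    def hyper_median(self) -> dict[str, float]:
        med = np.median(self.hyper_draws, axis=0)
        return dict(zip(self.hyper_names, med))


def n_leapfrog_steps(eps: float, cap: int = 100) -> int:
    return int(min(cap, int(np.ceil(1.0 / eps))))


def leapfrog_hmc_step(
    z: np.ndarray,
    logp_and_grad,
    eps: float,
    mass_diag: np.ndarray,
    rng: np.random.Generator,
    max_steps: int = 100,
    divergence_threshold: float = 1000.0,
):
    """One HMC proposal from state ``z``; returns (z', accepted, alpha, divergent).

    ``logp_and_grad(z) -> (log density, gradient)``. Momentum is drawn from
    N(0, M) with diagonal M; kinetic energy is p^T M^{-1} p / 2.
    """
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        f0, g0 = logp_and_grad(z)
        if not np.all(np.isfinite(g0)):
            raise FloatingPointError("non-finite gradient at the current state")
        p0 = rng.standard_normal(z.shape) * np.sqrt(mass_diag)
        S = n_leapfrog_steps(eps, cap=max_steps)
        zc, p = z.copy(), p0.copy()
        g = g0
        p = p + 0.5 * eps * g
        for s in range(S):
            zc = zc + eps * p / mass_diag
            if np.max(np.abs(zc)) > 1e8:  # runaway trajectory: abort early
                return z, False, 0.0, True
            f, g = logp_and_grad(zc)
            if not np.all(np.isfinite(g)) or not np.isfinite(f):
                return z, False, 0.0, True
            p = p + (eps if s < S - 1 else 0.5 * eps) * g
        H0 = -f0 + 0.5 * np.sum(p0**2 / mass_diag)
        H1 = -f + 0.5 * np.sum(p**2 / mass_diag)
        dH = H1 - H0
    if not np.isfinite(dH) or dH > divergence_threshold:
        return z, False, 0.0, True
    alpha = min(1.0, float(np.exp(-dH)))
    if rng.random() < alpha:
        return zc, True, alpha, False
    return z, False, alpha, False


class DualAveraging:
    """Nesterov dual-averaging step-size adaptation (Hoffman-Gelman constants)."""

    def __init__(self, eps0: float, target: float = 0.8, gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.h_bar = 0.0
        self.log_eps_bar = np.log(eps0)
        self.m = 0
        self.log_eps = np.log(eps0)

    def update(self, accept_stat: float) -> float:
        self.m += 1
        m = self.m
        frac = 1.0 / (m + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def eps_frozen(self) -> float:
        return float(np.exp(self.log_eps_bar))


def mass_matrix_from_window(draws: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Diagonal mass = inverse per-coordinate empirical variance of ``draws``."""
    var = np.var(draws, axis=0)
    low = var < floor
    if np.any(low):
        logger.warning("%d coordinates had near-zero variance; floored", int(low.sum()))
        var = np.maximum(var, floor)
    return 1.0 / var


def _log_chi_unnorm(x: float, k: int, eta: float) -> float:
    return (k - 1) * np.log(x) - 0.5 * (eta * x) ** 2


def mh_rescale_component(
    factors: tuple[np.ndarray, np.ndarray, np.ndarray],
    dims: tuple[int, int, int],
    etas: tuple[float, float, float],
    omega: float,
    rng: np.random.Generator,
) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], bool]:
    """One rescaling proposal on the norms of a CP component (u, t, v).

    Draws lognormal factors s_u, s_t, proposes u* = s_u u, t* = s_t t,
    v* = v/(s_u s_t), so zeta = u t v is preserved and the likelihood is
    unchanged. The target is the conditional prior of the norms given zeta
    (independent chi densities with the change-of-variables factor
    1/(u t)); together with the multiplicative-random-walk Hastings
    correction the log acceptance ratio is

        log A = log p(u*, t* | zeta) - log p(u, t | zeta) + log s_u + log s_t.
    """
    uvec, tvec, vvec = factors
    Su, St, Sv = dims
    eu, et, ev = etas
    u, t, v = np.linalg.norm(uvec), np.linalg.norm(tvec), np.linalg.norm(vvec)
    if u <= 0 or t <= 0 or v <= 0:
        return factors, False
    zeta = u * t * v
    su = float(np.exp(rng.normal(0.0, omega)))
    st = float(np.exp(rng.normal(0.0, omega)))
    u2, t2 = su * u, st * t
    v2 = zeta / (u2 * t2)

    def cond_logp(a, b):
        c = zeta / (a * b)
        return (
            _log_chi_unnorm(a, Su, eu)
            + _log_chi_unnorm(b, St, et)
            + _log_chi_unnorm(c, Sv, ev)
            - np.log(a)
            - np.log(b)
        )

    log_alpha = cond_logp(u2, t2) - cond_logp(u, t) + np.log(su) + np.log(st)
    if np.log(rng.random()) < log_alpha:
        return (uvec * su, tvec * st, vvec / (su * st)), True
    return factors, False


def _apply_mh_rescaling(
    model: GmlmModel,
    params: GmlmParams,
    hyper: dict[str, float],
    omega: float,
    reps: int,
    rng: np.random.Generator,
) -> GmlmParams:
    """Interleaved rescaling moves for every stimulus and touch-bar component."""
    if model.rank > 0:
        sp = StimulusPrior.build(model.spec, hyper)
        for r in range(model.rank):
            for _ in range(reps):
                uvec = params.U_stim[:, r]
                un = np.linalg.norm(uvec)
                if un <= 0:
                    break
                uhat = uvec / un
                eta_u = float(np.sqrt(uhat @ sp.prec @ uhat))
                (u2, t2, v2), _ = mh_rescale_component(
                    (params.U_stim[:, r], params.T_stim[:, r], params.V_stim[:, r]),
                    (model.spec.S, model.P_stim, model.N),
                    (eta_u, 1.0, 1.0),
                    omega,
                    rng,
                )
                params.U_stim[:, r] = u2
                params.T_stim[:, r] = t2
                params.V_stim[:, r] = v2
    if model.include_tbar and params.T_tbar is not None:
        eta_t = 1.0 / hyper["psi_tbar"]
        for q in range(model.rank_tbar):
            for _ in range(reps):
                # two-factor variant: dummy unit "u" leg with chi dim 1
                (t2, v2), _ = _mh_rescale_pair(
                    (params.T_tbar[:, q], params.V_tbar[:, q]),
                    (model.P_tbar, model.N),
                    (eta_t, 1.0),
                    omega,
                    rng,
                )
                params.T_tbar[:, q] = t2
                params.V_tbar[:, q] = v2
    return params


def _mh_rescale_pair(factors, dims, etas, omega, rng):
    tvec, vvec = factors
    St, Sv = dims
    et, ev = etas
    t, v = np.linalg.norm(tvec), np.linalg.norm(vvec)
    if t <= 0 or v <= 0:
        return factors, False
    zeta = t * v
    s = float(np.exp(rng.normal(0.0, omega)))
    t2 = s * t
    v2 = zeta / t2

    def cond_logp(a):
        c = zeta / a
        return _log_chi_unnorm(a, St, et) + _log_chi_unnorm(c, Sv, ev) - np.log(a)

    log_alpha = cond_logp(t2) - cond_logp(t) + np.log(s)
    if np.log(rng.random()) < log_alpha:
        return (tvec * s, vvec / s), True
    return factors, False


class GmlmPosterior:
    """Flattened joint posterior over (parameters, log hyperparameters)."""

    def __init__(self, model: GmlmModel, design: PopulationDesign):
        self.model = model
        self.design = design
        self.hyper_names = model.hyper_names()
        self.n_hyper = len(self.hyper_names)
        self.dim = model.n_params + self.n_hyper

    def pack(self, params: GmlmParams, hyper: dict[str, float]) -> np.ndarray:
        logh = np.log([hyper[n] for n in self.hyper_names])
        return np.concatenate([self.model.pack(params), logh])

    def unpack(self, z: np.ndarray) -> tuple[GmlmParams, dict[str, float]]:
        params = self.model.unpack(z[: self.model.n_params])
        # clip keeps exp() finite during exploratory leapfrog trajectories;
        # the bound is far outside any credible hyperparameter range
        logh = np.clip(z[self.model.n_params :], -40.0, 40.0)
        hyper = {n: float(np.exp(v)) for n, v in zip(self.hyper_names, logh)}
        return params, hyper

    def logp_and_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        params, hyper = self.unpack(z)
        f, grad, hgrad = self.model.log_posterior_and_grad(params, hyper, self.design)
        gz = np.concatenate(
            [self.model.pack(grad), [hgrad[n] for n in self.hyper_names]]
        )
        return f, gz


def run_sampler(
    model: GmlmModel,
    design: PopulationDesign,
    config: SamplerConfig,
    init: tuple[GmlmParams, dict[str, float]] | None = None,
) -> PosteriorSamples:
    """Warmup (adaptation) followed by posterior draws.

    Hyperparameters are initialized from i.i.d. standard normal draws in
    log space; parameters use the model's random initialization.
    """
    rng = np.random.default_rng(config.seed)
    post = GmlmPosterior(model, design)
    if init is None:
        params0 = model.init_params(rng, design)
        hyper0 = {
            n: float(np.exp(rng.standard_normal() * 0.5)) for n in post.hyper_names
        }
    else:
        params0, hyper0 = init
    z = post.pack(params0, hyper0)

    eps = config.eps0
    da = DualAveraging(config.eps0, target=config.target_accept)
    mass = np.ones(post.dim)
    W = config.n_warmup
    adapt_until = int(config.adapt_frac * W)
    f0, f1, f2 = config.mass_window_fracs
    mass_points = {int(W * f1): (int(W * f0), int(W * f1)), int(W * f2): (int(W * f1), int(W * f2))}
    warm_buffer = np.zeros((W, post.dim), dtype=np.float32)

    n_total = W + config.n_samples
    param_draws = np.zeros((config.n_samples, model.n_params), dtype=np.float32)
    hyper_draws = np.zeros((config.n_samples, post.n_hyper))
    accept_flags = np.zeros(config.n_samples, dtype=bool)
    accept_stats = np.zeros(config.n_samples)
    warm_accept = np.zeros(W, dtype=bool)
    eps_trace = np.zeros(n_total)
    n_div = 0

    for it in range(n_total):
        z, accepted, alpha, divergent = leapfrog_hmc_step(
            z,
            post.logp_and_grad,
            eps,
            mass,
            rng,
            max_steps=config.max_leapfrog,
            divergence_threshold=config.divergence_threshold,
        )
        n_div += int(divergent)
        # interleaved rescaling moves (cheap: prior-only acceptance)
        params, hyper = post.unpack(z)
        params = _apply_mh_rescaling(
            model, params, hyper, config.mh_omega, config.mh_interleave, rng
        )
        z = post.pack(params, hyper)

        if it < W:
            warm_buffer[it] = z
            warm_accept[it] = accepted
            if it + 1 <= adapt_until:
                eps = da.update(alpha)
            else:
                eps = da.eps_frozen
            for point, (lo, hi) in mass_points.items():
                if it + 1 == point and hi > lo + 1:
                    mass = mass_matrix_from_window(warm_buffer[lo:hi].astype(float))
        else:
            k = it - W
            param_draws[k] = z[: model.n_params]
            hyper_draws[k] = np.exp(z[model.n_params :])
            accept_flags[k] = accepted
            accept_stats[k] = alpha
        eps_trace[it] = eps

    if n_div > 0.1 * n_total:
        raise RuntimeError(f"sampler diverged persistently ({n_div}/{n_total} steps)")
    return PosteriorSamples(
        param_draws=param_draws,
        hyper_draws=hyper_draws,
        hyper_names=post.hyper_names,
        accept_flags=accept_flags,
        accept_stats=accept_stats,
        eps_trace=eps_trace,
        n_divergent=n_div,
        warmup_accept_flags=warm_accept,
    )


def map_with_median_hypers(
    model: GmlmModel,
    design: PopulationDesign,
    samples: PosteriorSamples,
    params0: GmlmParams | None = None,
) -> tuple[GmlmParams, dict[str, float]]:
    """MAP estimate with hyperparameters fixed at marginal posterior medians."""
    hyper = samples.hyper_median()
    if params0 is None:
        params0 = model.unpack(samples.param_draws[-1].astype(float))
    params = model.fit_map(design, hyper, params0=params0)
    return params, hyper


def pointwise_loglik_draws(
    model: GmlmModel,
    design: PopulationDesign,
    samples: PosteriorSamples,
    thin: int = 1,
) -> np.ndarray:
    """(n_draws, n_trials) per-trial log-likelihood over (thinned) draws."""
    idx = np.arange(0, samples.n_samples, thin)
    out = np.zeros((len(idx), design.n_raw_trials))
    for i, k in enumerate(idx):
        params = model.unpack(samples.param_draws[k].astype(float))
        out[i] = model.log_likelihood_per_trial(params, design)
    return out


def psis_loo(
    model: GmlmModel,
    design: PopulationDesign,
    samples: PosteriorSamples,
    thin: int = 1,
) -> dict:
    """PSIS-LOO: per-trial elpd, per-neuron means, and Pareto-k diagnostics."""
    import arviz as az
    from scipy.special import logsumexp

    ll = pointwise_loglik_draws(model, design, samples, thin=thin)  # (draws, trials)
    lw, k = az.psislw(-ll.T)  # (trials, draws)
    lw = np.asarray(lw)
    elpd_i = logsumexp(lw + ll.T, axis=1)
    k = np.asarray(k)
    frac_bad = float(np.mean(k > 0.7))
    if frac_bad > 0:
        logger.warning("PSIS: %.0f%% of trials have Pareto k > 0.7", 100 * frac_bad)
    per_neuron = {}
    for n in range(design.n_neurons):
        m = design.raw_neuron == n
        if m.any():
            per_neuron[n] = float(np.mean(elpd_i[m]))
    return {
        "elpd_trial": elpd_i,
        "per_neuron": per_neuron,
        "pareto_k": k,
        "frac_k_above_0.7": frac_bad,
    }
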