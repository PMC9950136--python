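"""Single-neuron Poisson point-process GLM (the full-rank reference model).

The log firing rate of one cell is

    lambda(t) = w + (h_spk * y)(t) + (k_tbar * x_tbar)(t)
                + sum_s (k^(s) * x^(s))(t),

with spike counts y(t) ~ Poisson(exp(lambda(t)) * Delta). All kernels are
basis expansions (see :mod:`poptensor.bases`), so the model is an ordinary
Poisson GLM in the basis coefficients, fit by MAP under the structured
Gaussian priors of :mod:`poptensor.priors`. Hyperparameters are set by
maximizing a Laplace approximation of the evidence times the half-t
hyperprior, optimized in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .bases import BasisSet, history_design, place_basis
from .core_data import Trial
from .priors import (
    StimulusPrior,
    default_stim_hyper,
    half_t_logpdf,
    stim_hyper_names,
)
from .task_design import DesignSpec, trial_regressors

logger = logging.getLogger(__name__)


@dataclass
class GlmParams:
    """Basis-space parameters of one cell's GLM."""

    w: float
    h_coeffs: np.ndarray  # (P_spk,)
    tbar_coeffs: np.ndarray  # (P_tbar,)
    stim_coeffs: np.ndarray  # (S, P_stim)

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [[self.w], self.h_coeffs, self.tbar_coeffs, self.stim_coeffs.ravel()]
        )

    @classmethod
    def unpack(cls, beta: np.ndarray, P_spk: int, P_tbar: int, S: int, P_stim: int):
        i = 1
        h = beta[i : i + P_spk]
        i += P_spk
        tb = beta[i : i + P_tbar]
        i += P_tbar
        st = beta[i : i + S * P_stim].reshape(S, P_stim)
        return cls(w=float(beta[0]), h_coeffs=h, tbar_coeffs=tb, stim_coeffs=st)


@dataclass
class GlmDesign:
    """Stacked design matrix over the trials of one neuron."""

    X: np.ndarray  # (total bins, dim)
    y: np.ndarray  # (total bins,)
    trial_slices: list[slice]
    bin_width: float
    P_spk: int
    P_tbar: int
    S: int
    P_stim: int

    @property
    def dim(self) -> int:
        return self.X.shape[1]


def build_design(trials: list[Trial], spec: DesignSpec, bases: BasisSet, bin_width: float) -> GlmDesign:
    """Assemble the Poisson-GLM design matrix for one neuron's trials."""
    P_spk = bases.hist.n_functions
    P_tbar = bases.tbar.n_functions
    P_stim = bases.stim.n_functions
    S = spec.S
    blocks, ys, slices = [], [], []
    pos = 0
    for tr in trials:
        T = tr.n_bins
        reg = trial_regressors(tr, spec)
        Xh = history_design(bases.hist, tr.counts)
        Xb = (
            place_basis(bases.tbar, tr.t_tbar, T)
            if tr.t_tbar is not None
            else np.zeros((T, P_tbar))
        )
        A_s = place_basis(bases.stim, tr.t_sample_on, T)
        A_t = place_basis(bases.stim, tr.t_test_on, T)
        Xs = (
            reg.x_dir_sample[None, :, None] * A_s[:, None, :]
            + reg.x_dir_test[None, :, None] * A_t[:, None, :]
        ).reshape(T, S * P_stim)
        blocks.append(np.hstack([np.ones((T, 1)), Xh, Xb, Xs]))
        ys.append(tr.counts)
        slices.append(slice(pos, pos + T))
        pos += T
    return GlmDesign(
        X=np.vstack(blocks),
        y=np.concatenate(ys).astype(float),
        trial_slices=slices,
        bin_width=bin_width,
        P_spk=P_spk,
        P_tbar=P_tbar,
        S=S,
        P_stim=P_stim,
    )


def log_rate(params: GlmParams, design: GlmDesign) -> np.ndarray:
    """Per-bin log rate lambda(t) over the stacked design."""
    return design.X @ params.pack()


def poisson_log_likelihood(lam: np.ndarray, y: np.ndarray, bin_width: float) -> float:
    """Sum of Poisson log-pmf terms with mean exp(lambda) * Delta."""
    mu_log = lam + np.log(bin_width)
    return float(np.sum(y * mu_log - np.exp(mu_log) - gammaln(y + 1)))


def log_likelihood(params: GlmParams, design: GlmDesign) -> float:
    return poisson_log_likelihood(log_rate(params, design), design.y, design.bin_width)


def log_likelihood_trial(params: GlmParams, design: GlmDesign, trial_index: int) -> float:
    sl = design.trial_slices[trial_index]
    lam = design.X[sl] @ params.pack()
    return poisson_log_likelihood(lam, design.y[sl], design.bin_width)


# ---------------------------------------------------------------------------
# priors over the packed parameter vector


@dataclass
class GlmPrior:
    """Gaussian prior over the packed GLM parameter vector (flat on w)."""

    stim: StimulusPrior
    psi_tbar: float
    psi_spk: float
    precision: np.ndarray
    log_norm: float  # normalization of the proper part

    @classmethod
    def build(cls, spec: DesignSpec, hyper: dict[str, float], design: GlmDesign) -> "GlmPrior":
        stim = StimulusPrior.build(spec, hyper)
        dim = 1 + design.P_spk + design.P_tbar + design.S * design.P_stim
        P = np.zeros((dim, dim))
        i = 1
        P[i : i + design.P_spk, i : i + design.P_spk] = np.eye(design.P_spk) / hyper["psi_spk"] ** 2
        i += design.P_spk
        P[i : i + design.P_tbar, i : i + design.P_tbar] = (
            np.eye(design.P_tbar) / hyper["psi_tbar"] ** 2
        )
        i += design.P_tbar
        P[i:, i:] = np.kron(stim.prec, np.eye(design.P_stim))
        logdet_stim = 2 * float(np.sum(np.log(np.diag(stim.chol))))
        n_proper = design.P_spk + design.P_tbar + design.S * design.P_stim
        log_norm = -0.5 * (
            n_proper * np.log(2 * np.pi)
            + design.P_spk * 2 * np.log(hyper["psi_spk"])
            + design.P_tbar * 2 * np.log(hyper["psi_tbar"])
            + design.P_stim * logdet_stim
        )
        return cls(stim=stim, psi_tbar=hyper["psi_tbar"], psi_spk=hyper["psi_spk"], precision=P, log_norm=log_norm)

    def logpdf(self, beta: np.ndarray) -> float:
        return float(-0.5 * beta @ self.precision @ beta + self.log_norm)


def default_hyper(spec: DesignSpec) -> dict[str, float]:
    h = default_stim_hyper(spec)
    h["psi_tbar"] = 1.0
    h["psi_spk"] = 1.0
    return h


def build_prior(spec: DesignSpec, hyper: dict[str, float], design: GlmDesign) -> GlmPrior:
    return GlmPrior.build(spec, hyper, design)


# ---------------------------------------------------------------------------
# MAP fitting and evidence optimization


def _neg_log_posterior(beta, design: GlmDesign, prior: GlmPrior):
    eta = design.X @ beta + np.log(design.bin_width)
    eta = np.minimum(eta, 30.0)  # overflow guard; never binds near the optimum
    mu = np.exp(eta)
    ll = float(design.y @ eta - mu.sum() - gammaln(design.y + 1).sum())
    lp = -0.5 * beta @ prior.precision @ beta
    g = -(design.X.T @ (design.y - mu)) + prior.precision @ beta
    return -(ll + lp), g, mu


def fit_map(
    design: GlmDesign,
    prior: GlmPrior,
    beta0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmParams:
    """Newton MAP fit of the (log-concave) posterior at fixed hyperparameters."""
    beta = np.zeros(design.dim) if beta0 is None else beta0.copy()
    f, g, mu = _neg_log_posterior(beta, design, prior)
    for it in range(max_iter):
        H = design.X.T @ (design.X * mu[:, None]) + prior.precision
        H[np.diag_indices_from(H)] += 1e-9
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            H[np.diag_indices_from(H)] += 1e-6
            step = np.linalg.solve(H, g)
        t = 1.0
        for _ in range(40):
            f_new, g_new, mu_new = _neg_log_posterior(beta - t * step, design, prior)
            if f_new <= f - 1e-4 * t * (g @ step):
                break
            t *= 0.5
        beta = beta - t * step
        rel = (f - f_new) / max(1.0, abs(f))
        f, g, mu = f_new, g_new, mu_new
        if np.linalg.norm(g) < tol * max(1.0, np.linalg.norm(beta)) or rel < 1e-12:
            break
    else:
        if np.linalg.norm(g) > 1e-3:
            raise RuntimeError(f"MAP fit did not converge (grad norm {np.linalg.norm(g):.2e})")
    return GlmParams.unpack(beta, design.P_spk, design.P_tbar, design.S, design.P_stim)


def laplace_log_evidence(ll_at_map: float, logprior_at_map: float, hessian: np.ndarray) -> float:
    """Laplace correction: log p(y|H) ~ ll + lp + d/2 log 2pi - 1/2 log|A|.

    ``hessian`` is the negative Hessian of the log posterior at the MAP.
    Exact whenever the posterior is Gaussian (conjugate likelihoods).
    """
    sign, logdet = np.linalg.slogdet(hessian)
    if sign <= 0:
        raise np.linalg.LinAlgError("posterior Hessian is not positive definite")
    d = hessian.shape[0]
    return ll_at_map + logprior_at_map + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet


def laplace_evidence(
    design: GlmDesign, prior: GlmPrior, beta0: np.ndarray | None = None
) -> tuple[float, GlmParams]:
    """Laplace approximation of log p(y | hyperparameters).

    Evaluates log lik + log prior at the MAP and corrects with the log
    determinant of the posterior Hessian: the Gaussian approximation of
    the parameter posterior makes the evidence integral tractable.
    """
    params = fit_map(design, prior, beta0=beta0)
    beta = params.pack()
    ll = log_likelihood(params, design)
    lp = prior.logpdf(beta)
    mu = np.exp(np.minimum(design.X @ beta + np.log(design.bin_width), 30.0))
    H = design.X.T @ (design.X * mu[:, None]) + prior.precision
    try:
        ev = laplace_log_evidence(ll, lp, H)
    except np.linalg.LinAlgError:
        H[np.diag_indices_from(H)] += 1e-6
        logger.warning("posterior Hessian required jitter for a positive determinant")
        ev = laplace_log_evidence(ll, lp, H)
    return ev, params


def _softplus(x: float) -> float:
    return float(np.logaddexp(0.0, x))


def optimize_evidence(
    design: GlmDesign,
    spec: DesignSpec,
    hyper0: dict[str, float] | None = None,
    max_iter: int = 200,
) -> tuple[GlmParams, dict[str, float]]:
    """Empirical-Bayes hyperparameter selection by Laplace evidence.

    Scale hyperparameters are optimized as logs (positivity); the GP
    arc-length tau uses a softplus reparameterization (tau >= 0). The
    objective is the Laplace evidence plus the half-t log hyperprior.
    """
    names = stim_hyper_names(spec) + ["psi_tbar", "psi_spk"]
    h0 = default_hyper(spec) if hyper0 is None else dict(hyper0)

    def decode(z: np.ndarray) -> dict[str, float]:
        h = {}
        for name, zi in zip(names, z):
            h[name] = _softplus(zi) if name == "tau" else float(np.exp(zi))
        return h

    def encode(h: dict[str, float]) -> np.ndarray:
        out = []
        for name in names:
            v = h[name]
            if name == "tau":
                out.append(np.log(np.expm1(max(v, 1e-6))))
            else:
                out.append(np.log(v))
        return np.array(out)

    warm = {"beta": None}

    def neg_objective(z: np.ndarray) -> float:
        h = decode(z)
        prior = GlmPrior.build(spec, h, design)
        try:
            ev, params = laplace_evidence(design, prior, beta0=warm["beta"])
        except (RuntimeError, np.linalg.LinAlgError):
            return 1e12
        warm["beta"] = params.pack()
        hyperprior = sum(float(half_t_logpdf(h[name])) for name in names)
        return -(ev + hyperprior)

    from scipy.optimize import minimize

    res = minimize(
        neg_objective,
        encode(h0),
        method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-3, "fatol": 1e-4},
    )
    h_opt = decode(res.x)
    prior = GlmPrior.build(spec, h_opt, design)
    params = fit_map(design, prior, beta0=warm["beta"])
    return params, h_opt


def fit_mle(design: GlmDesign, spec: DesignSpec, ridge: float = 1e-6) -> GlmParams:
    """Maximum-likelihood fit (vanishing-prior limit, tiny ridge for conditioning)."""
    prior = GlmPrior.build(spec, {k: 1.0 for k in stim_hyper_names(spec) + ["psi_tbar", "psi_spk"]}, design)
    prior.precision = ridge * np.eye(design.dim)
    prior.precision[0, 0] = 0.0
    prior.log_norm = 0.0
    return fit_map(design, prior)
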