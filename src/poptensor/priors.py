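"""Structured Gaussian priors over stimulus-kernel coefficients.

The prior over the S stimulus coefficients (per temporal-basis index) is
built from latent Gaussian sums: a shared stimulus-independent latent
(variance psi_0^2) induces correlation between all kernels, category
latents (psi_c^2 / psi_s^2) tie same-category kernels together, cos/sin
latents (psi_d^2) encode smooth cosine tuning, and — for the per-direction
("full") models — a circular Gaussian-process latent over direction angle
with variance psi_theta^2 and arc-length hyperparameter tau >= 0:

    K(theta, theta') = (1 + (tau+4)/pi * d) * (1 - d/pi)^(tau+4),
    d = arccos(cos(theta - theta')),

so K = 1 at d = 0 and K = 0 at d = pi (opposite directions uncorrelated
through this term). Because every kernel is a linear function of the
latents, the joint prior is zero-mean Gaussian with covariance
sum_h psi_h^2 L_h L_h^T (+ psi_theta^2 K_gp(tau)); the loadings L_h are
kept explicit both to sample the construction directly (an independent
check on the assembled covariance) and to differentiate the prior with
respect to log-hyperparameters inside samplers.

Hyperpriors are independent half-t densities with nu = 4:
p(h) ∝ (1 + h^2/nu)^(-(nu+1)/2), finite and maximal at h = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task_design import DesignSpec

HALF_T_NU = 4.0


def half_t_logpdf(h: np.ndarray | float, nu: float = HALF_T_NU) -> np.ndarray | float:
    """Unnormalized log half-t density for h >= 0."""
    h = np.asarray(h, dtype=float)
    out = np.where(h < 0, -np.inf, -(nu + 1) / 2 * np.log1p(h**2 / nu))
    return out if out.ndim else float(out)


def half_t_dlogpdf_dlogh(h: np.ndarray | float, nu: float = HALF_T_NU):
    """d log p(h) / d log h for the half-t hyperprior."""
    h = np.asarray(h, dtype=float)
    return -(nu + 1) * (h**2 / nu) / (1 + h**2 / nu)


def gp_direction_kernel(theta_deg: np.ndarray, tau: float) -> np.ndarray:
    """Circular GP kernel matrix over motion directions (degrees)."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    d = np.arccos(np.clip(np.cos(th[:, None] - th[None, :]), -1.0, 1.0))
    base = np.clip(1 - d / np.pi, 0.0, 1.0)
    return (1 + (tau + 4) / np.pi * d) * base ** (tau + 4)


def gp_direction_kernel_dtau(theta_deg: np.ndarray, tau: float) -> np.ndarray:
    """Derivative of the circular GP kernel with respect to tau."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    d = np.arccos(np.clip(np.cos(th[:, None] - th[None, :]), -1.0, 1.0))
    base = np.clip(1 - d / np.pi, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        logb = np.where(base > 0, np.log(np.where(base > 0, base, 1.0)), 0.0)
    pow_term = base ** (tau + 4)
    out = (d / np.pi) * pow_term + (1 + (tau + 4) / np.pi * d) * pow_term * logb
    out[base == 0] = 0.0
    return out


def stim_hyper_names(spec: DesignSpec) -> list[str]:
    p = spec.parameterization
    if p == "none":
        return ["psi_0", "psi_s"]
    if p == "category":
        return ["psi_0", "psi_c"]
    if p in ("cosine", "cosine_independent"):
        return ["psi_0", "psi_c", "psi_d"]
    return ["psi_0", "psi_c", "psi_d", "psi_theta", "tau"]


def default_stim_hyper(spec: DesignSpec) -> dict[str, float]:
    h = {name: 1.0 for name in stim_hyper_names(spec)}
    return h


def _latent_loadings(spec: DesignSpec) -> dict[str, np.ndarray]:
    """Loading matrices L_h: coefficients = sum_h psi_h * L_h @ z_h, z std normal.

    The GP latent is excluded (its loading depends on tau); see _gp_block.
    """
    S = spec.S
    labels = spec.coefficient_labels()
    p = spec.parameterization
    out: dict[str, np.ndarray] = {}
    if p == "none":
        out["psi_0"] = np.ones((S, 1))
        out["psi_s"] = np.eye(S)  # independent sample and test latents
        return out
    if p in ("category", "cosine", "cosine_independent"):
        cat_labels = ["cs1", "cs2", "ct1", "ct2"]
        L0 = np.zeros((S, 1))
        Lc = np.zeros((S, 4))
        for j, lab in enumerate(cat_labels):
            i = labels.index(lab)
            L0[i, 0] = 1.0
            Lc[i, j] = 1.0
        out["psi_0"] = L0
        out["psi_c"] = Lc
        if p != "category":
            dir_labels = [l for l in labels if l.startswith(("cos", "sin"))]
            Ld = np.zeros((S, len(dir_labels)))
            for j, lab in enumerate(dir_labels):
                Ld[labels.index(lab), j] = 1.0
            out["psi_d"] = Ld
        return out
    dirs = spec.direction_set_deg
    cats = [spec.category(t) for t in dirs]
    if p == "full":
        # latents: gamma_0, gamma_cs1, gamma_cs2, gamma_ct1, gamma_ct2,
        # gamma_cos, gamma_sin (+ GP handled separately)
        Lc = np.zeros((S, 4))
        Ld = np.zeros((S, 2))
        for k in (1, 2):
            i = labels.index(f"ct{k}")
            Lc[i, k - 1] = -1.0  # test kernel subtracts the sample-category latent
            Lc[i, 2 + k - 1] = 1.0
        for theta, c in zip(dirs, cats):
            i = labels.index(f"theta_{theta:g}")
            Lc[i, c - 1] = 1.0
            Ld[i, 0] = np.cos(np.deg2rad(theta))
            Ld[i, 1] = np.sin(np.deg2rad(theta))
        out["psi_0"] = np.ones((S, 1))
        out["psi_c"] = Lc
        out["psi_d"] = Ld
        return out
    # full_independent: shared gamma_0; per-role category and cos/sin latents
    # with hyperparameters shared between the roles.
    Lc = np.zeros((S, 4))
    Ld = np.zeros((S, 4))
    for role_i, role in enumerate(("s", "t")):
        for theta, c in zip(dirs, cats):
            i = labels.index(f"{role}_theta_{theta:g}")
            Lc[i, 2 * role_i + c - 1] = 1.0
            Ld[i, 2 * role_i] = np.cos(np.deg2rad(theta))
            Ld[i, 2 * role_i + 1] = np.sin(np.deg2rad(theta))
    out["psi_0"] = np.ones((S, 1))
    out["psi_c"] = Lc
    out["psi_d"] = Ld
    return out


def _gp_block(spec: DesignSpec, tau: float, deriv: bool = False) -> np.ndarray:
    """GP covariance (per psi_theta^2) embedded in the S x S coefficient space."""
    S = spec.S
    labels = spec.coefficient_labels()
    dirs = np.array(spec.direction_set_deg)
    K = gp_direction_kernel_dtau(dirs, tau) if deriv else gp_direction_kernel(dirs, tau)
    M = np.zeros((S, S))
    if spec.parameterization == "full":
        idx = [labels.index(f"theta_{t:g}") for t in dirs]
        M[np.ix_(idx, idx)] = K
    else:  # full_independent: an independent GP per role
        for role in ("s", "t"):
            idx = [labels.index(f"{role}_theta_{t:g}") for t in dirs]
            M[np.ix_(idx, idx)] = K
    return M


def build_prior_cov(spec: DesignSpec, hyper: dict[str, float]) -> np.ndarray:
    """Assembled S x S prior covariance of the stimulus coefficients."""
    names = stim_hyper_names(spec)
    missing = [n for n in names if n not in hyper]
    if missing:
        raise ValueError(f"missing hyperparameters {missing}")
    C = np.zeros((spec.S, spec.S))
    for name, L in _latent_loadings(spec).items():
        C += hyper[name] ** 2 * (L @ L.T)
    if "psi_theta" in names:
        C += hyper["psi_theta"] ** 2 * _gp_block(spec, hyper["tau"])
    return C


def sample_latent_construction(
    spec: DesignSpec, hyper: dict[str, float], rng: np.random.Generator, size: int
) -> np.ndarray:
    """Draw (size, S) coefficient vectors by sampling the latents directly.

    This samples each latent (shared, category, cos/sin, circular GP) and
    assembles the kernels, without forming the joint covariance — an
    independent check that build_prior_cov matches the construction.
    """
    X = np.zeros((size, spec.S))
    for name, L in _latent_loadings(spec).items():
        z = rng.standard_normal((size, L.shape[1]))
        X += hyper[name] * z @ L.T
    if "psi_theta" in stim_hyper_names(spec):
        dirs = np.array(spec.direction_set_deg)
        K = gp_direction_kernel(dirs, hyper["tau"]) + 1e-10 * np.eye(len(dirs))
        cK = np.linalg.cholesky(K)
        labels = spec.coefficient_labels()
        roles = [""] if spec.parameterization == "full" else ["s_", "t_"]
        prefix = "" if spec.parameterization == "full" else None
        for role in roles:
            z = rng.standard_normal((size, len(dirs)))
            gp = hyper["psi_theta"] * z @ cK.T
            for j, t in enumerate(dirs):
                lab = f"{role}theta_{t:g}"
                X[:, labels.index(lab)] += gp[:, j]
    return X


@dataclass
class StimulusPrior:
    """Zero-mean Gaussian prior over the S stimulus coefficients.

    ``cov`` applies independently to each temporal-basis index of a GLM
    stimulus-kernel matrix, or to each column of the population model's
    stimulus-weight matrix U.
    """

    spec: DesignSpec
    hyper: dict[str, float]
    cov: np.ndarray
    chol: np.ndarray
    prec: np.ndarray

    @classmethod
    def build(cls, spec: DesignSpec, hyper: dict[str, float]) -> "StimulusPrior":
        C = build_prior_cov(spec, hyper) + 1e-10 * np.eye(spec.S)
        chol = np.linalg.cholesky(C)
        prec = np.linalg.inv(C)
        return cls(spec=spec, hyper=dict(hyper), cov=C, chol=chol, prec=prec)

    def logpdf(self, X: np.ndarray) -> float:
        """Log density of (S,) or (S, m) coefficient columns under N(0, C)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != self.spec.S:
            raise ValueError("coefficient dimension mismatch")
        m = X.shape[1]
        sol = np.linalg.solve(self.chol, X)
        quad = float(np.sum(sol**2))
        logdet = 2 * float(np.sum(np.log(np.diag(self.chol))))
        return -0.5 * quad - 0.5 * m * (logdet + self.spec.S * np.log(2 * np.pi))

    def grad_logpdf(self, X: np.ndarray) -> np.ndarray:
        return -self.prec @ X

    def dlogpdf_dloghyper(self, X: np.ndarray) -> dict[str, float]:
        """Gradient of logpdf with respect to each log-hyperparameter.

        tau enters through log tau like the scale hyperparameters.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        m = X.shape[1]
        out: dict[str, float] = {}
        loadings = _latent_loadings(self.spec)
        PX = self.prec @ X
        for name in stim_hyper_names(self.spec):
            if name == "tau":
                dC = self.hyper["psi_theta"] ** 2 * _gp_block(self.spec, self.hyper["tau"], deriv=True)
                dC = dC * self.hyper["tau"]  # chain rule: d/d log tau
            elif name == "psi_theta":
                dC = 2 * self.hyper[name] ** 2 * _gp_block(self.spec, self.hyper["tau"])
            else:
                L = loadings[name]
                dC = 2 * self.hyper[name] ** 2 * (L @ L.T)
            quad = 0.5 * float(np.sum(PX * (dC @ PX)))
            trace = 0.5 * m * float(np.trace(self.prec @ dC))
            out[name] = quad - trace
        return out
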