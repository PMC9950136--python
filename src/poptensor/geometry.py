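"""Subspace geometry of the population stimulus response.

Two complementary views of the fitted tensor model:

* **Trajectories** — the stimulus kernel tensor K(t, theta_d, n) over
  sample directions is projected onto its top principal dimensions with a
  higher-order SVD; optionally the across-direction mean response is
  removed first so stimulus-independent transients do not dominate.

* **Direction ellipse / category vector** (cosine-tuned model) — at each
  time t the population direction tuning traces the ellipse
  E_t(theta) = f1(t) cos(theta) + f2(t) sin(theta) in the orthonormalized
  R-dimensional output space; the angle theta_max of the major axis, the
  major/minor axis norms and the norm of the category-difference vector
  F_t quantify how direction and category are encoded. theta_max is only
  identified modulo 180 deg and is reported in [45, 225) so it can be read
  against the category boundary. Metrics are invariant to rotations of the
  component space and to the CP rescaling invariance.

Applied per posterior draw, these yield median curves with credible
intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# HOSVD trajectories


def hosvd_subspace(
    K: np.ndarray, n_dims: int = 3, remove_mean: bool = False
) -> dict:
    """Project a (T, D, N) kernel tensor onto its top neural dimensions.

    Factor matrices come from SVDs of the mode unfoldings (orthonormal);
    the projection K*(t, theta, i) = (1/sqrt(N)) K x_3 Vhat[:, :n_dims]^T
    scales by the population size so differently sized populations are
    comparable. With ``remove_mean`` the across-direction mean is
    subtracted at every (t, i) first.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 3 or K.size == 0:
        raise ValueError("need a nonempty (time, direction, neuron) tensor")
    T, D, N = K.shape
    if n_dims > N:
        raise ValueError("n_dims exceeds the neuron-mode size")
    if remove_mean:
        K = K - K.mean(axis=1, keepdims=True)
    U1, _, _ = np.linalg.svd(K.reshape(T, D * N), full_matrices=False)
    U2, _, _ = np.linalg.svd(K.transpose(1, 0, 2).reshape(D, T * N), full_matrices=False)
    U3, _, _ = np.linalg.svd(K.transpose(2, 0, 1).reshape(N, T * D), full_matrices=False)
    proj = np.einsum("tdn,ni->tdi", K, U3[:, :n_dims]) / np.sqrt(N)
    return {
        "trajectories": proj,  # (T, D, n_dims)
        "T_hat": U1,
        "U_hat": U2,
        "V_hat": U3,
    }


# ---------------------------------------------------------------------------
# direction ellipse and category vector (cosine parameterization)


def _output_rotation(V_stim: np.ndarray) -> np.ndarray:
    """R = orth(V)^T V / sqrt(N): orthonormalized output coordinates."""
    N = V_stim.shape[0]
    Q, _ = np.linalg.qr(V_stim)
    return (Q.T @ V_stim) / np.sqrt(N)


def ellipse_axes_vectors(
    Tk: np.ndarray, U_stim: np.ndarray, V_stim: np.ndarray, labels: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(T, R) vectors f1, f2 with E_t(theta) = f1 cos(theta) + f2 sin(theta).

    ``Tk`` is the (T, R) matrix of temporal kernels (basis times temporal
    coefficients) evaluated at the times of interest.
    """
    if "cos" not in labels or "sin" not in labels:
        raise ValueError("direction ellipse requires the cosine parameterization")
    R = _output_rotation(V_stim)  # (R, R)
    icos, isin = labels.index("cos"), labels.index("sin")
    f1 = (Tk * U_stim[icos][None, :]) @ R.T
    f2 = (Tk * U_stim[isin][None, :]) @ R.T
    return f1, f2


def direction_ellipse(
    Tk: np.ndarray, U_stim: np.ndarray, V_stim: np.ndarray, labels: list[str], t: int
):
    """Callable E_t(theta_deg) -> point in R^R at time index ``t``."""
    f1, f2 = ellipse_axes_vectors(Tk, U_stim, V_stim, labels)

    def E(theta_deg):
        th = np.deg2rad(np.asarray(theta_deg, dtype=float))
        return np.cos(th)[..., None] * f1[t] + np.sin(th)[..., None] * f2[t]

    return E


def fold_angle(theta_deg: float, lo: float = 45.0) -> float:
    """Fold an angle (identified mod 180 deg) into [lo, lo + 180)."""
    t = theta_deg % 180.0
    if t < lo:
        t += 180.0
    return t


def ellipse_axes(
    f1: np.ndarray, f2: np.ndarray, grid_check: bool = False
) -> tuple[float, float, float, bool]:
    """Major-axis angle and axis norms of E(theta) = f1 cos + f2 sin.

    D(theta) = ||E(theta) - E(theta + 180)|| = 2 ||E(theta)|| is maximized
    in closed form at t0 = 1/2 atan2(2 f1.f2, |f1|^2 - |f2|^2); of the two
    candidates {t0, t0 + 90} the one with larger D is the major axis. The
    angle is folded into [45, 225). Near-circular ellipses are flagged
    degenerate (tie broken toward the lower angle). Returns
    (theta_max_deg, major_norm, minor_norm, degenerate).
    """
    a = float(f1 @ f1)
    b = float(f2 @ f2)
    c = float(f1 @ f2)

    def D(theta_deg):
        th = np.deg2rad(theta_deg)
        return 2 * np.sqrt(
            max(a * np.cos(th) ** 2 + b * np.sin(th) ** 2 + 2 * c * np.sin(th) * np.cos(th), 0.0)
        )

    degenerate = abs(a - b) < 1e-12 * max(1.0, a + b) and abs(c) < 1e-12 * max(1.0, a + b)
    if degenerate:
        t0 = 45.0
    else:
        t0 = float(np.rad2deg(0.5 * np.arctan2(2 * c, a - b)))
    cands = [fold_angle(t0), fold_angle(t0 + 90.0)]
    d0, d1 = D(cands[0]), D(cands[1])
    if abs(d0 - d1) < 1e-12 * max(1.0, d0 + d1):
        theta_max = min(cands)
        degenerate = True
    else:
        theta_max = cands[0] if d0 >= d1 else cands[1]
    major = D(theta_max)
    minor = D(theta_max + 90.0)
    if grid_check:
        grid = np.arange(0.0, 180.0, 1.0)
        dg = np.array([D(t) for t in grid])
        t_grid = fold_angle(float(grid[np.argmax(dg)]))
        diff = min(
            abs(t_grid - theta_max) % 180.0, 180.0 - abs(t_grid - theta_max) % 180.0
        )
        if diff > 1.0 and not degenerate:
            logger.warning(
                "closed-form major axis %.2f deg disagrees with grid argmax %.2f deg",
                theta_max,
                t_grid,
            )
    return theta_max, major, minor, degenerate


def category_vector(
    Tk: np.ndarray, U_stim: np.ndarray, V_stim: np.ndarray, labels: list[str]
) -> np.ndarray:
    """(T, R) category tuning vector F_t (cs1 minus cs2 kernels, projected)."""
    if "cs1" not in labels or "cs2" not in labels:
        raise ValueError("category vector requires sample-category coefficients")
    R = _output_rotation(V_stim)
    dU = U_stim[labels.index("cs1")] - U_stim[labels.index("cs2")]
    return (Tk * dU[None, :]) @ R.T


def category_vector_norm(Tk, U_stim, V_stim, labels) -> np.ndarray:
    return np.linalg.norm(category_vector(Tk, U_stim, V_stim, labels), axis=1)


@dataclass
class SubspaceGeometry:
    """Per-time posterior summaries (median and central 99% interval)."""

    times: np.ndarray  # seconds relative to sample onset
    theta_max: np.ndarray  # (T, 3): median, lo, hi (degrees in [45, 225))
    major_norm: np.ndarray  # (T, 3)
    minor_norm: np.ndarray  # (T, 3)
    category_norm: np.ndarray  # (T, 3)


def geometry_of_params(Tk: np.ndarray, U_stim: np.ndarray, V_stim: np.ndarray, labels):
    """Per-time (theta_max, major, minor, category norm) for one draw."""
    f1, f2 = ellipse_axes_vectors(Tk, U_stim, V_stim, labels)
    T = Tk.shape[0]
    th = np.zeros(T)
    major = np.zeros(T)
    minor = np.zeros(T)
    for t in range(T):
        th[t], major[t], minor[t], _ = ellipse_axes(f1[t], f2[t])
    cat = category_vector_norm(Tk, U_stim, V_stim, labels)
    return th, major, minor, cat


def posterior_geometry(
    draws: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    basis_B: np.ndarray,
    times_idx: np.ndarray,
    labels: list[str],
    bin_width: float,
    cri: float = 0.99,
) -> SubspaceGeometry:
    """Summarize geometry metrics over posterior draws of (T_stim, U, V).

    ``draws`` holds (T_stim coeffs, U_stim, V_stim) per draw; temporal
    kernels are basis_B[times_idx] @ T_stim.
    """
    lo_q, hi_q = (1 - cri) / 2, 1 - (1 - cri) / 2
    all_th, all_major, all_minor, all_cat = [], [], [], []
    for T_stim, U, V in draws:
        Tk = basis_B[times_idx] @ T_stim
        th, major, minor, cat = geometry_of_params(Tk, U, V, labels)
        all_th.append(th)
        all_major.append(major)
        all_minor.append(minor)
        all_cat.append(cat)

    def summarize(x):
        x = np.array(x)  # (draws, T)
        return np.stack(
            [np.median(x, axis=0), np.quantile(x, lo_q, axis=0), np.quantile(x, hi_q, axis=0)],
            axis=1,
        )

    return SubspaceGeometry(
        times=times_idx * bin_width,
        theta_max=summarize(all_th),
        major_norm=summarize(all_major),
        minor_norm=summarize(all_minor),
        category_norm=summarize(all_cat),
    )


# ---------------------------------------------------------------------------
# component-wise summaries


@dataclass
class ComponentMetrics:
    theta_deg: np.ndarray  # (R,) preferred direction per component (nan if a=0)
    direction_magnitude: np.ndarray  # (R,)
    c_sample: np.ndarray  # (R,)
    c_test: np.ndarray  # (R,)


def component_metrics(U_stim: np.ndarray, labels: list[str]) -> ComponentMetrics:
    """Per-component direction angle/magnitude and category magnitudes."""
    icos, isin = labels.index("cos"), labels.index("sin")
    ucos, usin = U_stim[icos], U_stim[isin]
    a = np.sqrt(ucos**2 + usin**2)
    theta = np.rad2deg(np.arctan2(usin, ucos))
    theta = np.where(a > 0, theta, np.nan)
    cs = np.abs(U_stim[labels.index("cs1")] - U_stim[labels.index("cs2")])
    ct = np.abs(U_stim[labels.index("ct1")] - U_stim[labels.index("ct2")])
    return ComponentMetrics(theta_deg=theta, direction_magnitude=a, c_sample=cs, c_test=ct)


def normalize_components(params, dyn_sign: bool = True):
    """Move each component's scale into the neuron loadings.

    After normalization the temporal and stimulus factors of every
    component have unit norm; the kernel tensor is unchanged (the CP
    rescaling invariance). For rank-1 dynamic-history factors the sign is
    fixed by the mode of sign(V) and the sign of the first history-kernel
    coefficient so filters are comparable across fits.
    """
    out = params.copy()
    for r in range(out.T_stim.shape[1]):
        nt = np.linalg.norm(out.T_stim[:, r])
        nu = np.linalg.norm(out.U_stim[:, r])
        if nt == 0 or nu == 0:
            logger.warning("component %d has a zero-norm factor; left unchanged", r)
            continue
        out.V_stim[:, r] *= nt * nu
        out.T_stim[:, r] /= nt
        out.U_stim[:, r] /= nu
    if out.dyn is not None and dyn_sign and out.dyn.H_dspk.shape[1] > 0:
        d = out.dyn
        sv = np.sign(d.V_dspk)
        sv[sv == 0] = 1
        mode_sign = 1.0 if (sv > 0).mean() >= 0.5 else -1.0
        s = mode_sign * np.sign(d.H_dspk[0, 0] or 1.0) * np.sign(d.U_dspk[0, 0] or 1.0)
        d.T_dspk *= s
        d.H_dspk *= np.sign(d.H_dspk[0, 0] or 1.0)
    return out


def fit_history_timescale(
    kernel: np.ndarray, bin_width: float = 0.005
) -> tuple[float, bool]:
    """Exponential decay constant (ms) of a spike-history kernel.

    Least-squares fit of A*exp(-t/tau) to the kernel over post-spike lags;
    returns (tau_ms, decaying_flag). A non-decaying best fit is flagged
    but still reported.
    """
    from scipy.optimize import curve_fit

    kernel = np.asarray(kernel, dtype=float)
    if np.allclose(kernel, 0):
        raise ValueError("kernel is identically zero")
    t = (np.arange(len(kernel)) + 1) * bin_width * 1000.0  # ms, lag centers

    def f(x, A, tau):
        return A * np.exp(-x / tau)

    A0 = kernel[0] if kernel[0] != 0 else float(np.max(np.abs(kernel)))
    try:
        popt, _ = curve_fit(f, t, kernel, p0=[A0, 20.0], maxfev=20000)
        tau = float(popt[1])
    except RuntimeError:
        return float("nan"), False
    decaying = tau > 0
    if not decaying:
        logger.warning("history kernel fit is non-decaying (tau=%.1f ms)", tau)
    return tau, decaying
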