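"""Raised-cosine temporal bases for stimulus, touch-bar and spike-history kernels.

Kernels are expressed as B @ coeffs where B is a (lags x n_functions) basis
matrix. The raw basis is a set of log-stretched raised-cosine bumps,

    b_j(t) = 1/2 (1 + cos(pi * clip((phi(t) - phi_j) / delta, -1, 1))),
    phi(t) = log(t + stretch * t_peak_last),

with bump centers phi_j equally spaced in the warped time phi and delta the
center spacing, so each bump overlaps only its immediate neighbors. The
basis returned for modeling is orthonormalized (QR in peak order, signs
fixed so each column peaks positive); kernels therefore live in the same
linear span as the raw bumps but with an orthonormal coordinate system,
which makes i.i.d. priors over coefficients act as smoothness priors over
kernels.

Alignment conventions:
  * stimulus basis — causal; lag 0 is the event bin, and the basis is zero
    there (responses start strictly after stimulus onset);
  * touch-bar basis — time-reversed stimulus functions with support mostly
    before the release (acausal build-up to the decision);
  * spike-history basis — strictly causal in the spike lag (lag >= 1 bin):
    two Kronecker deltas for the first two bins plus raised-cosine bumps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import DEFAULT_BIN_WIDTH


@dataclass
class BasisMatrix:
    """Temporal basis sampled on a bin-lag grid.

    ``B`` has one row per lag in ``lags`` (bin offsets relative to the
    event: positive = after). ``B_raw`` keeps the unorthonormalized bumps.
    """

    B: np.ndarray
    lags: np.ndarray
    alignment: str  # causal-post-event | acausal-pre-event | post-spike
    bin_width: float

    @property
    def n_functions(self) -> int:
        return self.B.shape[1]

    B_raw: np.ndarray | None = None


def _orthonormalize(B: np.ndarray) -> np.ndarray:
    """QR-orthonormalize columns in place-order; peak of each column positive."""
    Q, R = np.linalg.qr(B)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs
    # fix sign so each column's extremum is positive
    for j in range(Q.shape[1]):
        k = np.argmax(np.abs(Q[:, j]))
        if Q[k, j] < 0:
            Q[:, j] = -Q[:, j]
    return Q


def raised_cosine_bumps(
    t: np.ndarray, n: int, stretch: float, peak_first: float, peak_last: float
) -> np.ndarray:
    """Evaluate n log-stretched raised-cosine bumps at times ``t`` (seconds)."""
    if n < 1:
        raise ValueError("need at least one basis function")
    for v in (stretch, peak_first, peak_last):
        if not np.isfinite(v):
            raise ValueError("non-finite basis argument")
    if peak_first > peak_last or stretch < 0:
        raise ValueError("require peak_first <= peak_last and stretch >= 0")
    b = stretch * peak_last
    if peak_first + b <= 0:
        # guard the log; shift just enough to keep the warp defined
        b = 1e-4 - peak_first
    phi = lambda x: np.log(x + b)
    centers = np.linspace(phi(peak_first), phi(peak_last), n)
    delta = centers[1] - centers[0] if n > 1 else 1.0
    t = np.asarray(t, dtype=float)
    valid = t + b > 0
    warped = np.full(t.shape, -np.inf)
    warped[valid] = np.log(t[valid] + b)
    arg = (warped[:, None] - centers[None, :]) / delta
    return 0.5 * (1 + np.cos(np.pi * np.clip(arg, -1.0, 1.0)))


def raised_cosine_basis(
    n: int,
    stretch: float,
    peak_first: float,
    peak_last: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_bins: int | None = None,
    oversample: int = 25,
) -> BasisMatrix:
    """Causal raised-cosine basis on a bin grid starting at the event.

    Bumps are averaged over each bin (an ``oversample``-point subgrid) so
    that bumps narrower than a bin still contribute their mass. The number
    of lag bins defaults to covering the support of the last bump.
    """
    if n < 1:
        raise ValueError("need at least one basis function")
    if not all(np.isfinite(v) for v in (stretch, peak_first, peak_last, bin_width)):
        raise ValueError("non-finite basis argument")
    if n_bins is None:
        b = stretch * peak_last if peak_first + stretch * peak_last > 0 else 1e-4 - peak_first
        centers = np.linspace(np.log(peak_first + b), np.log(peak_last + b), n)
        delta = centers[1] - centers[0] if n > 1 else 1.0
        t_max = np.exp(centers[-1] + delta) - b
        n_bins = int(np.ceil(t_max / bin_width)) + 1
    sub = (np.arange(n_bins * oversample) + 0.5) * (bin_width / oversample)
    vals = raised_cosine_bumps(sub, n, stretch, peak_first, peak_last)
    raw = vals.reshape(n_bins, oversample, n).mean(axis=1)
    B = _orthonormalize(raw)
    return BasisMatrix(
        B=B,
        lags=np.arange(n_bins),
        alignment="causal-post-event",
        bin_width=bin_width,
        B_raw=raw,
    )


def stimulus_basis(
    n: int = 24,
    stretch: float = 0.2,
    peak_first: float = 0.040,
    peak_last: float = 1.540,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> BasisMatrix:
    """24-function causal stimulus basis; zero at the stimulus-onset bin.

    Peaks span 40-1540 ms relative to onset with a nonlinear stretch of
    0.2 (the raw peak grid 0-1500 ms shifted so the first function vanishes
    at exact onset time).
    """
    bm = raised_cosine_basis(n, stretch, peak_first, peak_last, bin_width)
    raw = bm.B_raw.copy()
    raw[0, :] = 0.0  # no response in the onset bin itself
    B = _orthonormalize(raw)
    B[0, :] = 0.0
    return BasisMatrix(B=B, lags=bm.lags, alignment="causal-post-event", bin_width=bin_width, B_raw=raw)


def touchbar_basis(
    n: int = 8,
    bin_width: float = DEFAULT_BIN_WIDTH,
    stim_kwargs: dict | None = None,
) -> BasisMatrix:
    """Acausal touch-bar basis: first ``n`` stimulus functions, time-reversed.

    The reversed functions are shifted so peaks span about -235 to +25 ms
    relative to the release, giving the finest temporal resolution near the
    release time.
    """
    stim = stimulus_basis(bin_width=bin_width, **(stim_kwargs or {}))
    raw_rev = stim.B_raw[::-1, :n]
    # peak of first (fastest) stimulus function is at ~40 ms post event; after
    # reversal place it at +25 ms relative to release.
    peak_bin_rev = int(np.argmax(raw_rev[:, 0]))
    target_lag = int(round(0.025 / bin_width))
    lags = np.arange(len(raw_rev)) - peak_bin_rev + target_lag
    keep = lags >= -int(np.ceil(0.300 / bin_width))  # support window around release
    raw = raw_rev[keep]
    lags = lags[keep]
    B = _orthonormalize(raw)
    return BasisMatrix(B=B, lags=lags, alignment="acausal-pre-event", bin_width=bin_width, B_raw=raw)


def spike_history_basis(
    n_delta: int = 2,
    n_cosine: int = 8,
    stretch: float = 0.05,
    peak_first: float = 0.010,
    peak_last: float = 0.200,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> BasisMatrix:
    """Post-spike history basis: delta functions for the first bins + bumps.

    The two Kronecker deltas capture the refractory bins immediately after
    a spike (lags 1 and 2, i.e. 0-5 and 5-10 ms); the remaining raised
    cosines (stretch 0.05) capture slower post-spike dynamics. All columns
    vanish at lag 0: a spike cannot excite its own bin.
    """
    # cosine part evaluated at lag-bin centers, starting after the deltas
    b = stretch * peak_last
    centers = np.linspace(np.log(peak_first + b), np.log(peak_last + b), n_cosine)
    delta_c = centers[1] - centers[0] if n_cosine > 1 else 1.0
    t_max = np.exp(centers[-1] + delta_c) - b
    n_lags = max(int(np.ceil(t_max / bin_width)) + 1, n_delta + n_cosine)
    lags = np.arange(1, n_lags + 1)
    oversample = 25
    sub = ((lags[0] - 1) * oversample + np.arange(n_lags * oversample) + 0.5) * (
        bin_width / oversample
    )
    cos_vals = raised_cosine_bumps(sub, n_cosine, stretch, peak_first, peak_last)
    cos_raw = cos_vals.reshape(n_lags, oversample, n_cosine).mean(axis=1)
    cos_raw[:n_delta, :] = 0.0  # deltas own the first bins
    raw = np.zeros((n_lags, n_delta + n_cosine))
    for j in range(n_delta):
        raw[j, j] = 1.0
    raw[:, n_delta:] = cos_raw
    B = _orthonormalize(raw)
    return BasisMatrix(B=B, lags=lags, alignment="post-spike", bin_width=bin_width, B_raw=raw)


def project_kernel(basis: BasisMatrix, kernel: np.ndarray) -> np.ndarray:
    """Least-squares coefficients of ``kernel`` in the (orthonormal) basis."""
    return basis.B.T @ kernel


def reconstruct_kernel(basis: BasisMatrix, coeffs: np.ndarray) -> np.ndarray:
    return basis.B @ coeffs


def place_basis(basis: BasisMatrix, event_bin: int, T: int) -> np.ndarray:
    """(T, n) design block: basis rows aligned to an event at ``event_bin``.

    Row t holds the basis evaluated at lag t - event_bin; convolving a
    kernel with a unit impulse at the event reduces to this placement.
    """
    A = np.zeros((T, basis.n_functions))
    idx = event_bin + basis.lags
    valid = (idx >= 0) & (idx < T)
    A[idx[valid]] = basis.B[valid]
    return A


def history_design(basis: BasisMatrix, counts: np.ndarray) -> np.ndarray:
    """(T, n) spike-history design: counts convolved with each basis column.

    Strictly causal: row t only depends on counts before bin t (the basis
    lags start at 1).
    """
    counts = np.asarray(counts, dtype=float)
    T = len(counts)
    X = np.zeros((T, basis.n_functions))
    for row, lag in enumerate(basis.lags):
        lag = int(lag)
        if lag < 1:
            raise ValueError("spike-history basis must be strictly causal")
        if lag < T:
            X[lag:, :] += counts[: T - lag, None] * basis.B[row][None, :]
    return X


@dataclass
class BasisSet:
    """The three temporal bases used by the models."""

    stim: BasisMatrix
    tbar: BasisMatrix
    hist: BasisMatrix

    @classmethod
    def default(cls, bin_width: float = DEFAULT_BIN_WIDTH, **kwargs) -> "BasisSet":
        return cls(
            stim=stimulus_basis(bin_width=bin_width, **kwargs.get("stim", {})),
            tbar=touchbar_basis(bin_width=bin_width, **kwargs.get("tbar", {})),
            hist=spike_history_basis(bin_width=bin_width, **kwargs.get("hist", {})),
        )
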