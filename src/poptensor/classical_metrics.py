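"""Single-neuron ROC tuning indices, parametric tuning curves and behavior.

* rCTI — ROC-based category tuning index in [-0.5, 0.5]: the mean
  across-category pairwise discriminability (|AUC - 0.5|) of spike-count
  distributions between directions minus the mean within-category pairwise
  discriminability. 0 means directions are indistinguishable or equally
  discriminable within and across categories; +0.5 means perfect
  across-category separation with none within; -0.5 the reverse.
* rDSI — shuffle-corrected direction selectivity: the maximum
  within-category pairwise |AUC - 0.5| minus its mean under shuffled
  direction labels, so direction-blind cells score ~0.
* Parametric tuning curve — Poisson regression of windowed counts on a
  category indicator (+-0.5) and cos/sin of direction; category magnitude
  is |beta_cat| and direction magnitude the peak-to-trough response
  2 sqrt(beta_sin^2 + beta_cos^2), both shuffle-corrected because the
  magnitudes are positively biased.
* Behavioral performance — Beta(1, 1)-prior beta-binomial: posterior mean
  (k+1)/(n+2) with central 99% credible interval.

AUCs use midranks, so ties are handled without randomization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import beta as beta_dist, rankdata

logger = logging.getLogger(__name__)

SAMPLE_WINDOW = (0.0, 0.650)  # s after sample onset
DELAY_WINDOW = (0.800, 1.450)


def auc(x: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve for separating samples x from y (midranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty condition")
    ranks = rankdata(np.concatenate([x, y]))
    rx = ranks[: len(x)].sum()
    u = rx - len(x) * (len(x) + 1) / 2
    return float(u / (len(x) * len(y)))


def _pairwise_discriminability(counts_by_direction: dict, pairs) -> list[float]:
    return [
        abs(auc(counts_by_direction[a], counts_by_direction[b]) - 0.5)
        for a, b in pairs
    ]


def _split_pairs(directions, category_fn):
    within, across = [], []
    for a, b in combinations(sorted(directions), 2):
        (within if category_fn(a) == category_fn(b) else across).append((a, b))
    return within, across


def rcti(counts_by_direction: dict, category_fn) -> float:
    """ROC category tuning index in [-0.5, 0.5].

    ``counts_by_direction`` maps direction (deg) -> per-trial spike counts
    in the analysis window; ``category_fn`` maps direction -> {1, 2}.
    """
    dirs = list(counts_by_direction)
    within, across = _split_pairs(dirs, category_fn)
    if not within or not across:
        raise ValueError("need at least two directions in each category")
    d_across = np.mean(_pairwise_discriminability(counts_by_direction, across))
    d_within = np.mean(_pairwise_discriminability(counts_by_direction, within))
    return float(d_across - d_within)


def rdsi(
    counts_by_direction: dict,
    category_fn,
    n_shuffles: int = 200,
    rng: np.random.Generator | None = None,
) -> float:
    """Shuffle-corrected maximum within-category direction discriminability."""
    rng = np.random.default_rng(0) if rng is None else rng
    dirs = list(counts_by_direction)
    within, _ = _split_pairs(dirs, category_fn)
    if not within:
        raise ValueError("need at least two directions within a category")
    raw = max(_pairwise_discriminability(counts_by_direction, within))
    # shuffle direction labels across trials, recompute the statistic
    all_counts = np.concatenate([np.asarray(counts_by_direction[d]) for d in dirs])
    sizes = [len(counts_by_direction[d]) for d in dirs]
    null = np.zeros(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(all_counts)
        shuffled = {}
        i = 0
        for d, m in zip(dirs, sizes):
            shuffled[d] = perm[i : i + m]
            i += m
        null[s] = max(_pairwise_discriminability(shuffled, within))
    return float(raw - null.mean())


@dataclass
class TuningCurveFit:
    beta0: float
    beta_cat: float
    beta_sin: float
    beta_cos: float
    category_magnitude: float  # shuffle-corrected |beta_cat|
    direction_magnitude: float  # shuffle-corrected peak-to-trough
    converged: bool


def direction_magnitude(beta_sin: float, beta_cos: float) -> float:
    """Peak-to-trough modulation of the cosine tuning term.

    max_theta [b_s sin + b_c cos] - [same at theta + 180 deg]
    = 2 sqrt(b_s^2 + b_c^2).
    """
    return 2.0 * float(np.hypot(beta_sin, beta_cos))


def _poisson_tuning_fit(counts, directions, categories, cap: float = 20.0):
    import statsmodels.api as sm

    c = np.where(np.asarray(categories) == 1, 0.5, -0.5)
    rad = np.deg2rad(np.asarray(directions, dtype=float))
    X = np.column_stack([np.ones_like(rad), c, np.sin(rad), np.cos(rad)])
    converged = True
    try:
        model = sm.GLM(np.asarray(counts, dtype=float), X, family=sm.families.Poisson())
        res = model.fit(maxiter=200)
        b = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(b)) or np.any(np.abs(b[1:]) > cap):
            raise ValueError
    except Exception:
        converged = False
        b = np.clip(np.nan_to_num(b if "b" in dir() else np.zeros(4)), -cap, cap)
        logger.warning("tuning-curve fit diverged; coefficients capped")
    return b, converged


def fit_tuning_curve(
    counts: np.ndarray,
    directions: np.ndarray,
    categories: np.ndarray,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
) -> TuningCurveFit:
    """Poisson tuning-curve fit with shuffle-corrected magnitudes."""
    rng = np.random.default_rng(0) if rng is None else rng
    b, converged = _poisson_tuning_fit(counts, directions, categories)
    cat_raw = abs(b[1])
    dir_raw = direction_magnitude(b[2], b[3])
    null_cat = np.zeros(n_shuffles)
    null_dir = np.zeros(n_shuffles)
    idx = np.arange(len(counts))
    for s in range(n_shuffles):
        perm = rng.permutation(idx)
        bs, _ = _poisson_tuning_fit(
            counts, np.asarray(directions)[perm], np.asarray(categories)[perm]
        )
        null_cat[s] = abs(bs[1])
        null_dir[s] = direction_magnitude(bs[2], bs[3])
    return TuningCurveFit(
        beta0=float(b[0]),
        beta_cat=float(b[1]),
        beta_sin=float(b[2]),
        beta_cos=float(b[3]),
        category_magnitude=float(cat_raw - null_cat.mean()),
        direction_magnitude=float(dir_raw - null_dir.mean()),
        converged=converged,
    )


def beta_binomial_performance(
    successes: int, n: int, cri: float = 0.99
) -> tuple[float, tuple[float, float]]:
    """Posterior mean and central credible interval of the success fraction.

    With a Beta(1, 1) prior the posterior is Beta(1 + k, 1 + n - k), mean
    (k + 1)/(n + 2).
    """
    if not (0 <= successes <= n):
        raise ValueError("need 0 <= successes <= n")
    a, b = 1 + successes, 1 + n - successes
    mean = a / (a + b)
    lo = float(beta_dist.ppf((1 - cri) / 2, a, b))
    hi = float(beta_dist.ppf(1 - (1 - cri) / 2, a, b))
    return float(mean), (lo, hi)


def bootstrap_index(
    counts_by_direction: dict,
    statistic,
    n_boot: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Bootstrap a tuning index, resampling trials within each direction."""
    rng = np.random.default_rng(seed)
    out = np.zeros(n_boot)
    for b in range(n_boot):
        resampled = {
            d: np.asarray(c)[rng.integers(len(c), size=len(c))]
            for d, c in counts_by_direction.items()
        }
        out[b] = statistic(resampled)
    return out
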