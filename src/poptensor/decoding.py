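"""Pseudopopulation construction and linear category decoders.

Because neurons were recorded one at a time, population "trials" are
assembled by resampling: a pseudopopulation trial for a condition draws
one real trial (with replacement) from every neuron, giving a trials x
neurons count matrix. Decoders are binary logistic-regression classifiers
on z-scored spike counts with an L2 penalty of 0.1 on the weights
(z-scoring statistics come from the training set only).

Two analyses:

* direction-split category generalization — two decoders are each trained
  on category-labeled trials from a subset of motion directions and
  validated only on the withheld directions; a population that encodes
  direction purely circularly cannot generalize (chance = 50%), while a
  direction-independent category signal can.
* match-condition decoding — decoders trained on match (or non-match)
  trials and validated on the other condition, for sample- or test-
  category labels; sample and test decoders are mirror images on
  non-match-validated trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .core_data import Trial, TrialDataset, category_of

logger = logging.getLogger(__name__)

#: L2 coefficient on 0.5 * ||w||^2 in the total (summed) log-loss objective
RIDGE_PENALTY = 0.1

# direction-split schemes: two training sets; validation = complement
SPLIT_SCHEMES = {
    6: [
        ({15.0, 195.0}, {75.0, 255.0, 135.0, 315.0}),
        ({75.0, 255.0}, {15.0, 195.0, 135.0, 315.0}),
    ],
    8: [
        (
            {67.5, 112.5, 247.5, 292.5},
            {157.5, 202.5, 337.5, 22.5},
        ),
        (
            {157.5, 202.5, 337.5, 22.5},
            {67.5, 112.5, 247.5, 292.5},
        ),
    ],
}


@dataclass
class Pseudopopulation:
    """Pseudotrial count matrices per condition.

    ``X[cond]`` is (n_per_cond, n_neurons); condition keys are whatever
    the caller grouped by (typically sample direction).
    """

    X: dict


def window_count(trial: Trial, start_bin: int, n_bins: int) -> float:
    stop = min(start_bin + n_bins, trial.n_bins)
    if start_bin >= trial.n_bins:
        return 0.0
    return float(trial.counts[max(start_bin, 0) : stop].sum())


def make_pseudopopulation(
    dataset: TrialDataset,
    conditions: dict,
    window: tuple[int, int],
    n_per_condition: int,
    rng: np.random.Generator,
) -> Pseudopopulation:
    """Resample one trial per neuron per pseudotrial within each condition.

    ``conditions`` maps a condition key to a predicate over trials;
    ``window`` is (start_bin, n_bins) and may be anchored by the caller to
    any event (bins are trial-relative). Raises if any neuron lacks a
    qualifying trial for some condition.
    """
    start_bin, n_bins = window
    X = {}
    for key, pred in conditions.items():
        per_neuron = []
        for nid in dataset.neuron_ids:
            pool = [t for t in dataset.trials_of(nid) if pred(t)]
            if not pool:
                raise ValueError(f"neuron {nid!r} has no trials in condition {key!r}")
            idx = rng.integers(len(pool), size=n_per_condition)
            per_neuron.append([window_count(pool[i], start_bin, n_bins) for i in idx])
        X[key] = np.array(per_neuron).T  # (n_per_condition, N)
    return Pseudopopulation(X)


@dataclass
class LinearDecoder:
    scaler: StandardScaler
    clf: LogisticRegression

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict(self.scaler.transform(X))

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == y))


def train_decoder(X: np.ndarray, labels: np.ndarray, penalty: float = RIDGE_PENALTY) -> LinearDecoder:
    """Logistic decoder on z-scored features with L2 penalty on the weights.

    The objective is sum-of-log-losses + penalty/2 * ||w||^2, i.e.
    scikit-learn's C = 1/penalty. z-scoring parameters are estimated on
    the training set only; zero-variance features are floored.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    scaler = StandardScaler()
    scaler.fit(X)
    scaler.scale_ = np.maximum(scaler.scale_, 1e-6)
    clf = LogisticRegression(C=1.0 / penalty, tol=1e-8, max_iter=5000)
    clf.fit(scaler.transform(X), labels)
    return LinearDecoder(scaler=scaler, clf=clf)


def _direction_conditions(dataset: TrialDataset, anchor: str = "sample"):
    dirs = sorted({t.theta_sample for t in dataset.trials})
    return dirs


def category_generalization(
    dataset: TrialDataset,
    window: tuple[int, int],
    n_per_direction: int = 50,
    rng: np.random.Generator | None = None,
    boundary: tuple[float, float] = (45.0, 225.0),
) -> float:
    """One pseudopopulation's direction-split generalization accuracy.

    Builds a pseudopopulation of ``n_per_direction`` trials per sample
    direction with counts in ``window`` (bins relative to trial start),
    trains the two complementary direction-split decoders and returns
    their mean validation accuracy on the withheld directions.
    """
    rng = np.random.default_rng() if rng is None else rng
    dirs = _direction_conditions(dataset)
    scheme = SPLIT_SCHEMES.get(len(dirs))
    if scheme is None or not all(
        d in {x for tr, va in scheme for x in (tr | va)} for d in dirs
    ):
        raise ValueError(f"no direction-split scheme covers directions {dirs}")
    conditions = {d: (lambda t, d=d: t.theta_sample == d) for d in dirs}
    pseudo = make_pseudopopulation(dataset, conditions, window, n_per_direction, rng)
    accs = []
    for train_dirs, valid_dirs in scheme:
        assert not (train_dirs & valid_dirs)
        Xtr = np.vstack([pseudo.X[d] for d in sorted(train_dirs)])
        ytr = np.concatenate(
            [np.full(n_per_direction, category_of(d, boundary)) for d in sorted(train_dirs)]
        )
        Xva = np.vstack([pseudo.X[d] for d in sorted(valid_dirs)])
        yva = np.concatenate(
            [np.full(n_per_direction, category_of(d, boundary)) for d in sorted(valid_dirs)]
        )
        dec = train_decoder(Xtr, ytr)
        accs.append(dec.score(Xva, yva))
    return float(np.mean(accs))


def category_generalization_timecourse(
    dataset: TrialDataset,
    times_bins: np.ndarray,
    window_bins: int = 40,
    n_per_direction: int = 50,
    n_boot: int = 1000,
    seed: int = 0,
    boundary: tuple[float, float] = (45.0, 225.0),
) -> dict:
    """Sliding-window generalization accuracy with bootstrap intervals.

    ``times_bins`` are window centers (bins from sample onset); each
    bootstrap draws a fresh pseudopopulation. Returns median and the 99%
    interval per time plus one-sided bootstrap p-values against chance.
    """
    rng = np.random.default_rng(seed)
    acc = np.zeros((n_boot, len(times_bins)))
    for b in range(n_boot):
        for i, c in enumerate(times_bins):
            start = int(c) - window_bins // 2
            acc[b, i] = category_generalization(
                dataset, (start, window_bins), n_per_direction, rng, boundary
            )
    p_above_chance = np.mean(acc <= 0.5, axis=0)  # one-sided bootstrap test
    return {
        "times_bins": np.asarray(times_bins),
        "accuracy": acc,
        "median": np.median(acc, axis=0),
        "lo99": np.quantile(acc, 0.005, axis=0),
        "hi99": np.quantile(acc, 0.995, axis=0),
        "p_value": p_above_chance,
    }


def match_condition_decoding(
    dataset: TrialDataset,
    window: tuple[int, int],
    target: str = "sample",
    n_per_direction: int = 50,
    n_boot: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Match/non-match cross-condition category decoding accuracies.

    For each bootstrap pseudopopulation, one decoder is trained on match
    trials and validated on non-match trials and vice versa; accuracy is
    the average of the two. ``target`` selects the decoded label: the
    sample or the test category. Counts are taken in ``window`` (bins
    relative to each trial's test onset by the caller's choice of window).
    """
    if target not in ("sample", "test"):
        raise ValueError("target must be 'sample' or 'test'")
    rng = np.random.default_rng(seed)
    dirs = sorted({t.theta_sample for t in dataset.trials})
    accs = np.zeros(n_boot)
    label_of = (lambda t: t.c_sample) if target == "sample" else (lambda t: t.c_test)
    for b in range(n_boot):
        both = []
        for train_match in (True, False):
            conditions = {}
            for d in dirs:
                for is_match in (True, False):
                    conditions[(d, is_match)] = (
                        lambda t, d=d, m=is_match: t.theta_sample == d and t.is_match == m
                    )
            pseudo = make_pseudopopulation(dataset, conditions, window, n_per_direction, rng)
            # labels per condition: category of sample (or test) direction
            def block(m):
                X, y = [], []
                for d in dirs:
                    X.append(pseudo.X[(d, m)])
                    pool = [
                        t
                        for t in dataset.trials
                        if t.theta_sample == d and t.is_match == m
                    ]
                    y.append(np.full(n_per_direction, label_of(pool[0])))
                return np.vstack(X), np.concatenate(y)

            Xtr, ytr = block(train_match)
            Xva, yva = block(not train_match)
            dec = train_decoder(Xtr, ytr)
            both.append(dec.score(Xva, yva))
        accs[b] = np.mean(both)
    return accs


def benjamini_hochberg(pvals: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    """BH-rejection mask (used to flag significant decoding time points)."""
    from statsmodels.stats.multitest import multipletests

    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject
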