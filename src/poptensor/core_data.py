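"""Trial and spike-train containers for delayed-match tasks.

Spike trains are discretized into fixed-width bins (5 ms by default). Each
:class:`Trial` belongs to a single neuron: the populations this package
targets were recorded one cell at a time, so there are no simultaneous
observations and no noise correlations in the data model. The modeled
window of every trial starts at sample-stimulus onset and ends 50 ms after
the touch-bar release (on release trials) or 50 ms after test-motion
offset.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.005
#: window pad after touch-bar release / test offset, seconds
WINDOW_PAD = 0.050
#: category boundary for motion directions, degrees
CATEGORY_BOUNDARY_DEG = (45.0, 225.0)


def category_of(theta_deg: float, boundary: tuple[float, float] = CATEGORY_BOUNDARY_DEG) -> int:
    """Category (1 or 2) of a motion direction under a two-sided boundary.

    Directions strictly inside (boundary[0], boundary[1]) are category 1,
    directions strictly outside are category 2. Directions exactly on the
    boundary are ambiguous and raise ``ValueError`` (such trials are never
    modeled).
    """
    t = float(theta_deg) % 360.0
    lo, hi = boundary
    if math.isclose(t, lo % 360.0) or math.isclose(t, hi % 360.0):
        raise ValueError(f"direction {theta_deg} lies on the category boundary")
    return 1 if lo < t < hi else 2


@dataclass
class Trial:
    """One trial of one neuron: binned counts plus task-event metadata.

    Event times are stored as bin indices into ``counts``; ``t_tbar`` is
    ``None`` on trials without a touch-bar release. Directions are degrees
    in [0, 360); categories are in {1, 2}.
    """

    neuron_id: str
    counts: np.ndarray
    t_sample_on: int
    t_test_on: int
    theta_sample: float
    theta_test: float
    c_sample: int
    c_test: int
    t_tbar: int | None = None
    correct: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-d array")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be nonnegative")
        if not (0 <= self.t_sample_on < self.t_test_on):
            raise ValueError("require 0 <= t_sample_on < t_test_on")
        if self.t_tbar is not None and not (0 <= self.t_tbar < len(self.counts)):
            raise ValueError("t_tbar outside the trial window")
        if self.c_sample not in (1, 2) or self.c_test not in (1, 2):
            raise ValueError("categories must be in {1, 2}")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def is_match(self) -> bool:
        return self.c_sample == self.c_test


@dataclass
class TrialDataset:
    """A population of (non-simultaneously recorded) neurons.

    ``trials`` holds every trial of every neuron; ``neuron_ids`` fixes the
    neuron ordering used by the population model.
    """

    neuron_ids: list[str]
    trials: list[Trial]
    bin_width: float = DEFAULT_BIN_WIDTH
    simultaneity_flag: bool = False
    direction_set_deg: tuple[float, ...] = ()
    boundary_deg: tuple[float, float] = CATEGORY_BOUNDARY_DEG

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        known = set(self.neuron_ids)
        for tr in self.trials:
            if tr.neuron_id not in known:
                raise ValueError(f"trial references unknown neuron {tr.neuron_id!r}")

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    def trials_of(self, neuron_id: str) -> list[Trial]:
        return [t for t in self.trials if t.neuron_id == neuron_id]

    def neuron_index(self, neuron_id: str) -> int:
        return self.neuron_ids.index(neuron_id)

    def subset(self, indices: Sequence[int]) -> "TrialDataset":
        """Dataset restricted to the trials at ``indices`` (all neurons kept)."""
        return replace(self, trials=[self.trials[i] for i in indices])


@dataclass
class FoldAssignment:
    """Stratified cross-validation folds (1..K) over the trials of a dataset."""

    K: int
    fold_of_trial: np.ndarray  # per-trial integer in 1..K

    def train_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_trial != k)

    def test_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_trial == k)


def bin_spikes(spike_times: np.ndarray, window: tuple[float, float], bin_width: float) -> np.ndarray:
    """Count spikes in half-open bins [t, t+Δ) covering ``window``.

    Spikes exactly at the window end are excluded (half-open convention);
    the total of the returned counts equals the number of spikes inside
    [start, end).
    """
    if bin_width <= 0 or not np.isfinite(bin_width):
        raise ValueError("bin_width must be positive and finite")
    start, end = window
    if not (np.isfinite(start) and np.isfinite(end)) or end < start:
        raise ValueError("invalid window")
    n_bins = int(math.ceil((end - start) / bin_width))
    edges = start + bin_width * np.arange(n_bins + 1)
    spike_times = np.asarray(spike_times, dtype=float)
    inside = spike_times[(spike_times >= start) & (spike_times < end)]
    counts, _ = np.histogram(inside, bins=edges)
    # histogram's last bin is closed on the right; the half-open rule already
    # excluded spikes at `end`, but a spike exactly at edges[-1] < end must be
    # counted in the final bin, which histogram does.
    return counts.astype(np.int64)


def trial_window(
    t_sample_on: float,
    t_test_off: float,
    t_tbar: float | None = None,
    pad: float = WINDOW_PAD,
) -> tuple[float, float]:
    """Modeled window [start, end): sample onset to 50 ms past release/offset."""
    if t_tbar is not None:
        if t_tbar < t_sample_on:
            raise ValueError("touch-bar release precedes sample onset")
        end = t_tbar + pad
    else:
        end = t_test_off + pad
    return (t_sample_on, end)


def mean_rate(trial: Trial, bin_width: float, t_test_off: int | None = None) -> float:
    """Mean firing rate (sp/s) from sample onset to test offset for one trial."""
    stop = t_test_off if t_test_off is not None else trial.n_bins
    stop = min(stop, trial.n_bins)
    n = trial.counts[trial.t_sample_on : stop].sum()
    dur = (stop - trial.t_sample_on) * bin_width
    return float(n) / dur if dur > 0 else 0.0


def filter_neurons(dataset: TrialDataset, rate_threshold: float = 2.0) -> TrialDataset:
    """Keep neurons whose trial-averaged mean rate is >= ``rate_threshold`` sp/s."""
    if rate_threshold < 0:
        raise ValueError("rate_threshold must be >= 0")
    if not dataset.trials:
        logger.warning("filter_neurons called on an empty dataset")
        return replace(dataset, neuron_ids=[], trials=[])
    keep = []
    for nid in dataset.neuron_ids:
        trs = dataset.trials_of(nid)
        if not trs:
            continue
        rates = [mean_rate(t, dataset.bin_width) for t in trs]
        if float(np.mean(rates)) >= rate_threshold:
            keep.append(nid)
    kept = set(keep)
    return replace(
        dataset,
        neuron_ids=keep,
        trials=[t for t in dataset.trials if t.neuron_id in kept],
    )


def make_folds(dataset: TrialDataset, K: int, seed: int = 0) -> FoldAssignment:
    """Assign trials to K folds, stratified by (neuron, sample direction).

    Within each stratum, trials are shuffled with a seeded RNG and dealt
    round-robin, so per-stratum fold sizes differ by at most one. Strata
    with fewer than K trials are spread as evenly as possible (some folds
    receive none) with a warning.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    fold = np.zeros(len(dataset.trials), dtype=np.int64)
    strata: dict[tuple[str, float], list[int]] = {}
    for i, tr in enumerate(dataset.trials):
        strata.setdefault((tr.neuron_id, tr.theta_sample), []).append(i)
    for key in sorted(strata, key=lambda k: (k[0], k[1])):
        idx = np.array(strata[key])
        if len(idx) < K:
            logger.warning("stratum %s has %d < K=%d trials", key, len(idx), K)
        rng.shuffle(idx)
        offset = int(rng.integers(K))
        for j, i in enumerate(idx):
            fold[i] = 1 + (j + offset) % K
    return FoldAssignment(K=K, fold_of_trial=fold)


def smooth_psth(
    dataset: TrialDataset,
    condition,
    kernel_sd: float = 0.030,
    n_bins: int | None = None,
) -> np.ndarray:
    """Trial-averaged firing rate (sp/s) smoothed with a Gaussian kernel.

    ``condition`` is a predicate over trials (e.g. selecting one motion
    direction). Trials of unequal length are averaged over the bins where
    they are defined. ``kernel_sd`` is the Gaussian width in seconds; 0
    returns the raw PSTH.
    """
    trials = [t for t in dataset.trials if condition(t)]
    if not trials:
        raise ValueError("condition selects zero trials")
    T = n_bins if n_bins is not None else max(t.n_bins for t in trials)
    acc = np.zeros(T)
    cnt = np.zeros(T)
    for t in trials:
        m = min(t.n_bins, T)
        acc[:m] += t.counts[:m]
        cnt[:m] += 1
    valid = cnt > 0
    rate = np.zeros(T)
    rate[valid] = acc[valid] / (cnt[valid] * dataset.bin_width)
    if kernel_sd <= 0:
        return rate
    half = int(math.ceil(4 * kernel_sd / dataset.bin_width))
    x = np.arange(-half, half + 1) * dataset.bin_width
    kern = np.exp(-0.5 * (x / kernel_sd) ** 2)
    kern /= kern.sum()
    # normalized convolution so the edges are not biased toward zero
    num = np.convolve(np.where(valid, rate, 0.0), kern, mode="same")
    den = np.convolve(valid.astype(float), kern, mode="same")
    out = np.zeros(T)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    return out


# ---------------------------------------------------------------------------
# serialization


def save_hdf5(dataset: TrialDataset, path: str) -> None:
    """Write a dataset to HDF5 (/neurons/<id>/trials/<k> layout)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["bin_width"] = dataset.bin_width
        f.attrs["category_boundary_deg"] = list(dataset.boundary_deg)
        f.attrs["simultaneity_flag"] = dataset.simultaneity_flag
        f.attrs["direction_set_deg"] = list(dataset.direction_set_deg)
        grp = f.create_group("neurons")
        for nid in dataset.neuron_ids:
            g = grp.create_group(str(nid)).create_group("trials")
            for k, tr in enumerate(dataset.trials_of(nid)):
                d = g.create_dataset(str(k), data=tr.counts.astype(np.int32))
                d.attrs["t_sample_on"] = tr.t_sample_on
                d.attrs["t_test_on"] = tr.t_test_on
                d.attrs["theta_sample"] = tr.theta_sample
                d.attrs["theta_test"] = tr.theta_test
                d.attrs["c_sample"] = tr.c_sample
                d.attrs["c_test"] = tr.c_test
                d.attrs["t_tbar"] = -1 if tr.t_tbar is None else tr.t_tbar
                d.attrs["correct"] = tr.correct


def load_hdf5(path: str) -> TrialDataset:
    import h5py

    with h5py.File(path, "r") as f:
        trials: list[Trial] = []
        neuron_ids = sorted(f["neurons"].keys())
        for nid in neuron_ids:
            g = f["neurons"][nid]["trials"]
            for k in sorted(g.keys(), key=int):
                d = g[k]
                tbar = int(d.attrs["t_tbar"])
                trials.append(
                    Trial(
                        neuron_id=nid,
                        counts=d[()],
                        t_sample_on=int(d.attrs["t_sample_on"]),
                        t_test_on=int(d.attrs["t_test_on"]),
                        theta_sample=float(d.attrs["theta_sample"]),
                        theta_test=float(d.attrs["theta_test"]),
                        c_sample=int(d.attrs["c_sample"]),
                        c_test=int(d.attrs["c_test"]),
                        t_tbar=None if tbar < 0 else tbar,
                        correct=bool(d.attrs["correct"]),
                    )
                )
        return TrialDataset(
            neuron_ids=neuron_ids,
            trials=trials,
            bin_width=float(f.attrs["bin_width"]),
            simultaneity_flag=bool(f.attrs["simultaneity_flag"]),
            direction_set_deg=tuple(f.attrs["direction_set_deg"]),
            boundary_deg=tuple(f.attrs["category_boundary_deg"]),
        )


def save_jsonl(dataset: TrialDataset, path: str) -> None:
    """Plain JSON-lines alternative for tiny fixtures."""
    with open(path, "w") as f:
        header = {
            "bin_width": dataset.bin_width,
            "neuron_ids": dataset.neuron_ids,
            "boundary_deg": list(dataset.boundary_deg),
            "direction_set_deg": list(dataset.direction_set_deg),
        }
        f.write(json.dumps(header) + "\n")
        for tr in dataset.trials:
            rec = {
                "neuron_id": tr.neuron_id,
                "counts": tr.counts.tolist(),
                "t_sample_on": tr.t_sample_on,
                "t_test_on": tr.t_test_on,
                "theta_sample": tr.theta_sample,
                "theta_test": tr.theta_test,
                "c_sample": tr.c_sample,
                "c_test": tr.c_test,
                "t_tbar": tr.t_tbar,
                "correct": tr.correct,
            }
            f.write(json.dumps(rec) + "\n")


def load_jsonl(path: str) -> TrialDataset:
    with open(path) as f:
        header = json.loads(f.readline())
        trials = []
        for line in f:
            rec = json.loads(line)
            trials.append(Trial(**{**rec, "counts": np.array(rec["counts"])}))
    return TrialDataset(
        neuron_ids=header["neuron_ids"],
        trials=trials,
        bin_width=header["bin_width"],
        boundary_deg=tuple(header["boundary_deg"]),
        direction_set_deg=tuple(header["direction_set_deg"]),
    )
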