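"""Population tensor point-process model (GMLM).

The stimulus kernels of all N neurons are tied together through a CP
(PARAFAC) decomposition: the kernel of neuron n for stimulus coefficient s
is K(t, s, n) = sum_r T_r(t) U_{s,r} V_{n,r}, so the population's stimulus
response lives in the R-dimensional subspace spanned by the columns of the
neuron-loading matrix V. The per-neuron log rate on a trial is

    lambda_n(t) = w_n + (H^spk_n * Y_n)(t)
                  + sum_q (T^tbar_q * x^tbar)(t) V^tbar_{n,q}
                  + sum_s sum_r Z^{(s)}_r(t) V^stim_{n,r},
    Z^{(s)}_r(t) = (x^{(direction,s)} . U^stim_r) (T^stim_r * x^{(timing,s)})(t),

with counts Y_n(t) ~ Poisson(exp(lambda_n(t)) * Delta). Neurons contribute
independently (no noise correlations), so non-simultaneous recordings are
handled naturally. An optional low-rank *dynamic* spike-history extension
multiplies a shared filtered-history trace by stimulus- or touch-bar-locked
gain kernels, letting the effective post-spike filter change over the
course of a trial.

Implementation notes: trials are padded to a common length and masked;
trials that share event times are grouped so the time-shifted basis
matrices are computed once per group; and when the model has no (dynamic)
spike-history term, trials that also share direction coefficients, neuron
and touch-bar timing are collapsed into sufficient statistics (summed
counts plus a multiplicity weight), which leaves every likelihood and
gradient formula unchanged because both are linear in the per-bin residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .bases import BasisSet, history_design, place_basis
from .core_data import TrialDataset
from .priors import (
    StimulusPrior,
    half_t_logpdf,
    half_t_dlogpdf_dlogh,
    stim_hyper_names,
)
from .task_design import DesignSpec, modelable, stimulus_coefficients

logger = logging.getLogger(__name__)

LOGRATE_CLIP = 30.0  # guard on log mean count during optimization


@dataclass
class DynamicHistoryParams:
    """Low-rank dynamic spike-history factors (shared across the population)."""

    H_dspk: np.ndarray  # (P_spk, R_h) shared history kernels (stimulus-locked)
    T_dspk: np.ndarray  # (P_stim, R_h) gain kernels relative to stimulus onset
    U_dspk: np.ndarray  # (2, R_h) sample/test weights
    V_dspk: np.ndarray  # (N, R_h) neuron loadings
    H_bdspk: np.ndarray  # (P_spk, R_bh) touch-bar-locked history kernels
    T_bdspk: np.ndarray  # (P_tbar, R_bh) gain kernels relative to release
    V_bdspk: np.ndarray  # (N, R_bh)


@dataclass
class GmlmParams:
    """All fitted parameters of the population model."""

    w: np.ndarray  # (N,)
    H_spk: np.ndarray | None  # (P_spk, N)
    T_tbar: np.ndarray | None  # (P_tbar, R_l)
    V_tbar: np.ndarray | None  # (N, R_l)
    T_stim: np.ndarray  # (P_stim, R)
    U_stim: np.ndarray  # (S, R)
    V_stim: np.ndarray  # (N, R)
    dyn: DynamicHistoryParams | None = None

    def copy(self) -> "GmlmParams":
        d = None
        if self.dyn is not None:
            d = DynamicHistoryParams(
                **{k: getattr(self.dyn, k).copy() for k in vars(self.dyn)}
            )
        return GmlmParams(
            w=self.w.copy(),
            H_spk=None if self.H_spk is None else self.H_spk.copy(),
            T_tbar=None if self.T_tbar is None else self.T_tbar.copy(),
            V_tbar=None if self.V_tbar is None else self.V_tbar.copy(),
            T_stim=self.T_stim.copy(),
            U_stim=self.U_stim.copy(),
            V_stim=self.V_stim.copy(),
            dyn=d,
        )


def rescale_component(params: GmlmParams, r: int, a: float, b: float) -> GmlmParams:
    """Rescale stimulus component r: U *= a, T *= b, V /= a*b (tensor unchanged)."""
    if a == 0 or b == 0:
        raise ValueError("rescaling factors must be nonzero")
    out = params.copy()
    out.U_stim[:, r] *= a
    out.T_stim[:, r] *= b
    out.V_stim[:, r] /= a * b
    return out


def kernel_tensor(params: GmlmParams, bases: BasisSet) -> np.ndarray:
    """Dense (lags, S, N) stimulus kernel tensor: exact CP reconstruction."""
    Tk = bases.stim.B @ params.T_stim  # (L, R)
    return np.einsum("lr,sr,nr->lsn", Tk, params.U_stim, params.V_stim)


# ---------------------------------------------------------------------------
# design


@dataclass
class PopulationDesign:
    """Vectorized (optionally collapsed) design over the trials of a dataset."""

    spec: DesignSpec
    n_neurons: int
    Tmax: int
    bin_width: float
    Y: np.ndarray  # (M, Tmax) summed counts per row
    wgt: np.ndarray  # (M,) number of raw trials per row
    mask: np.ndarray  # (M, Tmax) valid-bin mask
    neuron: np.ndarray  # (M,)
    cs: np.ndarray  # (M, S) sample-direction coefficients
    ct: np.ndarray  # (M, S)
    group_of_row: np.ndarray  # (M,)
    group_rows: list[np.ndarray]
    group_AS: list[np.ndarray]  # (Tmax, P_stim) sample-aligned stimulus basis
    group_AT: list[np.ndarray]
    Xb: np.ndarray | None  # (M, Tmax, P_tbar) or None
    Xh: np.ndarray | None  # (M, Tmax, P_spk) or None
    const_gammaln: float  # sum over raw bins of log(y!)
    raw_counts: list[np.ndarray]
    raw_row: np.ndarray  # raw trial -> design row
    raw_neuron: np.ndarray
    collapsed: bool

    @property
    def n_rows(self) -> int:
        return self.Y.shape[0]

    @property
    def n_raw_trials(self) -> int:
        return len(self.raw_counts)

    def total_bins(self) -> int:
        return int(sum(len(c) for c in self.raw_counts))


def build_population_design(
    dataset: TrialDataset,
    spec: DesignSpec,
    bases: BasisSet,
    need_history: bool,
    need_tbar: bool,
) -> PopulationDesign:
    """Compile a dataset into padded, grouped (and possibly collapsed) arrays."""
    trials = [t for t in dataset.trials if modelable(t, spec)]
    if not trials:
        raise ValueError("no modelable trials (correct, off-boundary)")
    nid_index = {nid: i for i, nid in enumerate(dataset.neuron_ids)}
    Tmax = max(t.n_bins for t in trials)
    can_collapse = not need_history

    rows: dict[tuple, int] = {}
    row_data: list[dict] = []
    raw_row = np.zeros(len(trials), dtype=np.int64)
    raw_neuron = np.zeros(len(trials), dtype=np.int64)
    raw_counts: list[np.ndarray] = []
    const_gl = 0.0
    for j, tr in enumerate(trials):
        n = nid_index[tr.neuron_id]
        cs = stimulus_coefficients(tr.theta_sample, tr.c_sample, "sample", spec)
        ct = stimulus_coefficients(tr.theta_test, tr.c_test, "test", spec)
        tb = tr.t_tbar if need_tbar else None
        key = (
            (n, tr.t_sample_on, tr.t_test_on, tr.n_bins, tb, tuple(cs), tuple(ct))
            if can_collapse
            else ("trial", j)
        )
        if key not in rows:
            rows[key] = len(row_data)
            row_data.append(
                dict(
                    neuron=n,
                    s_on=tr.t_sample_on,
                    t_on=tr.t_test_on,
                    T=tr.n_bins,
                    tbar=tb,
                    cs=cs,
                    ct=ct,
                    Y=np.zeros(Tmax),
                    wgt=0.0,
                    counts=None,
                )
            )
        m = rows[key]
        row_data[m]["Y"][: tr.n_bins] += tr.counts
        row_data[m]["wgt"] += 1.0
        if not can_collapse:
            row_data[m]["counts"] = tr.counts
        raw_row[j] = m
        raw_neuron[j] = n
        raw_counts.append(tr.counts)
        const_gl += float(gammaln(tr.counts + 1).sum())

    M = len(row_data)
    S = spec.S
    Y = np.stack([r["Y"] for r in row_data])
    wgt = np.array([r["wgt"] for r in row_data])
    mask = np.zeros((M, Tmax), dtype=bool)
    for m, r in enumerate(row_data):
        mask[m, : r["T"]] = True
    neuron = np.array([r["neuron"] for r in row_data], dtype=np.int64)
    cs = np.stack([r["cs"] for r in row_data])
    ct = np.stack([r["ct"] for r in row_data])

    groups: dict[tuple[int, int], int] = {}
    group_of_row = np.zeros(M, dtype=np.int64)
    for m, r in enumerate(row_data):
        gk = (r["s_on"], r["t_on"])
        if gk not in groups:
            groups[gk] = len(groups)
        group_of_row[m] = groups[gk]
    group_rows = [np.flatnonzero(group_of_row == g) for g in range(len(groups))]
    group_AS, group_AT = [], []
    for (s_on, t_on), g in sorted(groups.items(), key=lambda kv: kv[1]):
        group_AS.append(place_basis(bases.stim, s_on, Tmax))
        group_AT.append(place_basis(bases.stim, t_on, Tmax))

    Xb = None
    if need_tbar:
        P_tbar = bases.tbar.n_functions
        Xb = np.zeros((M, Tmax, P_tbar))
        for m, r in enumerate(row_data):
            if r["tbar"] is not None:
                Xb[m] = place_basis(bases.tbar, r["tbar"], Tmax)
    Xh = None
    if need_history:
        P_spk = bases.hist.n_functions
        Xh = np.zeros((M, Tmax, P_spk))
        for m, r in enumerate(row_data):
            Xh[m, : r["T"]] = history_design(bases.hist, r["counts"])

    return PopulationDesign(
        spec=spec,
        n_neurons=len(dataset.neuron_ids),
        Tmax=Tmax,
        bin_width=dataset.bin_width,
        Y=Y,
        wgt=wgt,
        mask=mask,
        neuron=neuron,
        cs=cs,
        ct=ct,
        group_of_row=group_of_row,
        group_rows=group_rows,
        group_AS=group_AS,
        group_AT=group_AT,
        Xb=Xb,
        Xh=Xh,
        const_gammaln=const_gl,
        raw_counts=raw_counts,
        raw_row=raw_row,
        raw_neuron=raw_neuron,
        collapsed=can_collapse,
    )


# ---------------------------------------------------------------------------
# the model


class GmlmModel:
    """Model configuration: which terms exist and at what ranks."""

    def __init__(
        self,
        spec: DesignSpec,
        bases: BasisSet,
        n_neurons: int,
        rank: int,
        rank_tbar: int = 3,
        include_history: bool = True,
        include_tbar: bool = True,
        rank_dyn: int = 0,
        rank_bdyn: int = 0,
        bin_width: float = 0.005,
    ):
        if rank < 0 or rank_tbar < 0:
            raise ValueError("ranks must be nonnegative")
        if (rank_dyn > 0 or rank_bdyn > 0) and not include_history:
            raise ValueError("dynamic spike history requires the history term")
        if rank_bdyn > 0 and not include_tbar:
            raise ValueError("touch-bar dynamic history requires the touch-bar term")
        self.spec = spec
        self.bases = bases
        self.N = n_neurons
        self.rank = rank
        self.rank_tbar = rank_tbar if include_tbar else 0
        self.include_history = include_history
        self.include_tbar = include_tbar
        self.rank_dyn = rank_dyn
        self.rank_bdyn = rank_bdyn
        self.bin_width = bin_width
        self.P_stim = bases.stim.n_functions
        self.P_tbar = bases.tbar.n_functions
        self.P_spk = bases.hist.n_functions

    # -- parameter layout ---------------------------------------------------

    def _blocks(self) -> list[tuple[str, tuple[int, ...]]]:
        b: list[tuple[str, tuple[int, ...]]] = [("w", (self.N,))]
        if self.include_history:
            b.append(("H_spk", (self.P_spk, self.N)))
        if self.include_tbar:
            b.append(("T_tbar", (self.P_tbar, self.rank_tbar)))
            b.append(("V_tbar", (self.N, self.rank_tbar)))
        b += [
            ("T_stim", (self.P_stim, self.rank)),
            ("U_stim", (self.spec.S, self.rank)),
            ("V_stim", (self.N, self.rank)),
        ]
        if self.rank_dyn > 0:
            b += [
                ("dyn.H_dspk", (self.P_spk, self.rank_dyn)),
                ("dyn.T_dspk", (self.P_stim, self.rank_dyn)),
                ("dyn.U_dspk", (2, self.rank_dyn)),
                ("dyn.V_dspk", (self.N, self.rank_dyn)),
            ]
        if self.rank_bdyn > 0:
            b += [
                ("dyn.H_bdspk", (self.P_spk, self.rank_bdyn)),
                ("dyn.T_bdspk", (self.P_tbar, self.rank_bdyn)),
                ("dyn.V_bdspk", (self.N, self.rank_bdyn)),
            ]
        return b

    @property
    def n_params(self) -> int:
        return sum(int(np.prod(shape)) for _, shape in self._blocks())

    def _get_block(self, params: GmlmParams, name: str) -> np.ndarray:
        if name.startswith("dyn."):
            return getattr(params.dyn, name[4:])
        return getattr(params, name)

    def pack(self, params: GmlmParams) -> np.ndarray:
        return np.concatenate(
            [np.ravel(self._get_block(params, name)) for name, _ in self._blocks()]
        )

    def unpack(self, vec: np.ndarray) -> GmlmParams:
        vals: dict[str, np.ndarray] = {}
        i = 0
        for name, shape in self._blocks():
            n = int(np.prod(shape))
            vals[name] = vec[i : i + n].reshape(shape)
            i += n
        dyn = None
        if self.rank_dyn > 0 or self.rank_bdyn > 0:
            dyn = DynamicHistoryParams(
                H_dspk=vals.get("dyn.H_dspk", np.zeros((self.P_spk, 0))),
                T_dspk=vals.get("dyn.T_dspk", np.zeros((self.P_stim, 0))),
                U_dspk=vals.get("dyn.U_dspk", np.zeros((2, 0))),
                V_dspk=vals.get("dyn.V_dspk", np.zeros((self.N, 0))),
                H_bdspk=vals.get("dyn.H_bdspk", np.zeros((self.P_spk, 0))),
                T_bdspk=vals.get("dyn.T_bdspk", np.zeros((self.P_tbar, 0))),
                V_bdspk=vals.get("dyn.V_bdspk", np.zeros((self.N, 0))),
            )
        return GmlmParams(
            w=vals["w"],
            H_spk=vals.get("H_spk"),
            T_tbar=vals.get("T_tbar"),
            V_tbar=vals.get("V_tbar"),
            T_stim=vals["T_stim"],
            U_stim=vals["U_stim"],
            V_stim=vals["V_stim"],
            dyn=dyn,
        )

    def grad_template(self) -> GmlmParams:
        return self.unpack(np.zeros(self.n_params))

    # -- initialization -----------------------------------------------------

    def init_params(
        self, rng: np.random.Generator, design: PopulationDesign | None = None
    ) -> GmlmParams:
        """Random initialization: normal loadings, orthonormal temporal factors.

        Neuron loadings (V matrices), stimulus weights U and history
        coefficients start standard normal; the temporal coefficient
        matrices are random orthonormal; baselines are normal, centered on
        each neuron's empirical log mean rate when a design is supplied.
        """

        def orth(p, r):
            if r == 0:
                return np.zeros((p, r))
            A = rng.standard_normal((p, max(r, 1)))
            Q, _ = np.linalg.qr(A)
            return Q[:, :r]

        if design is not None:
            # center baselines on the empirical log mean rate (sp/s) per neuron
            tot = np.zeros(self.N)
            nb = np.zeros(self.N)
            np.add.at(tot, design.neuron, design.Y.sum(axis=1))
            np.add.at(nb, design.neuron, design.wgt * design.mask.sum(axis=1))
            w = np.log(np.maximum(tot / np.maximum(nb, 1.0) / design.bin_width, 1e-2))
            w = w + 0.1 * rng.standard_normal(self.N)
        else:
            w = rng.standard_normal(self.N)
        dyn = None
        if self.rank_dyn > 0 or self.rank_bdyn > 0:
            dyn = DynamicHistoryParams(
                H_dspk=rng.standard_normal((self.P_spk, self.rank_dyn)) * 0.1,
                T_dspk=orth(self.P_stim, self.rank_dyn) * 0.1,
                U_dspk=rng.standard_normal((2, self.rank_dyn)) * 0.1,
                V_dspk=rng.standard_normal((self.N, self.rank_dyn)) * 0.1,
                H_bdspk=rng.standard_normal((self.P_spk, self.rank_bdyn)) * 0.1,
                T_bdspk=orth(self.P_tbar, self.rank_bdyn) * 0.1,
                V_bdspk=rng.standard_normal((self.N, self.rank_bdyn)) * 0.1,
            )
        return GmlmParams(
            w=w,
            H_spk=rng.standard_normal((self.P_spk, self.N)) * 0.1
            if self.include_history
            else None,
            T_tbar=orth(self.P_tbar, self.rank_tbar) if self.include_tbar else None,
            V_tbar=rng.standard_normal((self.N, self.rank_tbar))
            if self.include_tbar
            else None,
            T_stim=orth(self.P_stim, self.rank),
            U_stim=rng.standard_normal((self.spec.S, self.rank)),
            V_stim=rng.standard_normal((self.N, self.rank)),
            dyn=dyn,
        )

    def build_design(self, dataset: TrialDataset) -> PopulationDesign:
        return build_population_design(
            dataset,
            self.spec,
            self.bases,
            need_history=self.include_history,
            need_tbar=self.include_tbar,
        )

    # -- log rates ----------------------------------------------------------

    def log_rates(self, params: GmlmParams, design: PopulationDesign) -> np.ndarray:
        """(M, Tmax) log-rate matrix over design rows (mask applies later)."""
        lam = np.repeat(params.w[design.neuron][:, None], design.Tmax, axis=1)
        if self.include_history and params.H_spk is not None:
            Hn = params.H_spk[:, design.neuron].T  # (M, P_spk)
            lam += np.einsum("mtp,mp->mt", design.Xh, Hn)
        if self.include_tbar and params.T_tbar is not None and design.Xb is not None:
            prof = np.einsum("mtp,pq->mtq", design.Xb, params.T_tbar)
            lam += np.einsum("mtq,mq->mt", prof, params.V_tbar[design.neuron])
        if self.rank > 0:
            Vn = params.V_stim[design.neuron]  # (M, R)
            CU_s = design.cs @ params.U_stim
            CU_t = design.ct @ params.U_stim
            for g, rows in enumerate(design.group_rows):
                PS = design.group_AS[g] @ params.T_stim  # (Tmax, R)
                PT = design.group_AT[g] @ params.T_stim
                Ws = CU_s[rows] * Vn[rows]
                Wt = CU_t[rows] * Vn[rows]
                lam[rows] += Ws @ PS.T + Wt @ PT.T
        if params.dyn is not None:
            lam += self._dynamic_term(params, design)
        return lam

    def _dynamic_gain_profiles(self, params: GmlmParams, design: PopulationDesign):
        """Per-row stimulus-locked gain a(t, r) and touch-bar gain (m, t, q)."""
        d = params.dyn
        a = np.zeros((design.n_rows, design.Tmax, self.rank_dyn))
        if self.rank_dyn > 0:
            for g, rows in enumerate(design.group_rows):
                PSd = design.group_AS[g] @ d.T_dspk  # (Tmax, R_h)
                PTd = design.group_AT[g] @ d.T_dspk
                a[rows] = (
                    d.U_dspk[0][None, None, :] * PSd[None, :, :]
                    + d.U_dspk[1][None, None, :] * PTd[None, :, :]
                )
        bgain = None
        if self.rank_bdyn > 0 and design.Xb is not None:
            bgain = np.einsum("mtp,pq->mtq", design.Xb, d.T_bdspk)
        return a, bgain

    def _dynamic_term(self, params: GmlmParams, design: PopulationDesign) -> np.ndarray:
        d = params.dyn
        out = np.zeros((design.n_rows, design.Tmax))
        a, bgain = self._dynamic_gain_profiles(params, design)
        if self.rank_dyn > 0:
            fh = np.einsum("mtp,pr->mtr", design.Xh, d.H_dspk)
            out += np.einsum("mtr,mtr,mr->mt", a, fh, d.V_dspk[design.neuron])
        if self.rank_bdyn > 0 and bgain is not None:
            fhb = np.einsum("mtp,pq->mtq", design.Xh, d.H_bdspk)
            out += np.einsum("mtq,mtq,mq->mt", bgain, fhb, d.V_bdspk[design.neuron])
        return out

    def effective_history_kernel(
        self,
        params: GmlmParams,
        design: PopulationDesign,
        row: int,
        t: int,
        neuron: int | None = None,
    ) -> np.ndarray:
        """Effective post-spike kernel (lag profile) for a row's neuron at bin t.

        Constant kernel plus the gain-weighted dynamic kernels evaluated at
        trial time t.
        """
        n = design.neuron[row] if neuron is None else neuron
        B = self.bases.hist.B
        kern = B @ params.H_spk[:, n]
        if params.dyn is None:
            return kern
        d = params.dyn
        a, bgain = self._dynamic_gain_profiles(params, design)
        if self.rank_dyn > 0:
            kern = kern + (B @ d.H_dspk) @ (a[row, t] * d.V_dspk[n])
        if self.rank_bdyn > 0 and bgain is not None:
            kern = kern + (B @ d.H_bdspk) @ (bgain[row, t] * d.V_bdspk[n])
        return kern

    # -- likelihood and gradient -------------------------------------------

    def log_likelihood(self, params: GmlmParams, design: PopulationDesign) -> float:
        lam = self.log_rates(params, design)
        mu_log = np.clip(lam + np.log(design.bin_width), None, LOGRATE_CLIP)
        term = design.Y * mu_log - design.wgt[:, None] * np.exp(mu_log)
        return float(term[design.mask].sum()) - design.const_gammaln

    def log_likelihood_per_trial(
        self, params: GmlmParams, design: PopulationDesign
    ) -> np.ndarray:
        """Held-out-style per-raw-trial log probability (full Poisson pmf)."""
        lam = self.log_rates(params, design)
        out = np.zeros(design.n_raw_trials)
        logd = np.log(design.bin_width)
        for j in range(design.n_raw_trials):
            m = design.raw_row[j]
            y = design.raw_counts[j]
            T = len(y)
            ml = np.clip(lam[m, :T] + logd, None, LOGRATE_CLIP)
            out[j] = float(np.sum(y * ml - np.exp(ml) - gammaln(y + 1)))
        return out

    def log_likelihood_and_grad(
        self, params: GmlmParams, design: PopulationDesign
    ) -> tuple[float, GmlmParams]:
        lam = self.log_rates(params, design)
        mu_log = np.clip(lam + np.log(design.bin_width), None, LOGRATE_CLIP)
        mu = np.exp(mu_log)
        term = design.Y * mu_log - design.wgt[:, None] * mu
        ll = float(term[design.mask].sum()) - design.const_gammaln
        g = np.where(design.mask, design.Y - design.wgt[:, None] * mu, 0.0)

        grad = self.grad_template()
        np.add.at(grad.w, design.neuron, g.sum(axis=1))
        if self.include_history:
            gh = np.einsum("mtp,mt->mp", design.Xh, g)
            acc = np.zeros((self.N, self.P_spk))
            np.add.at(acc, design.neuron, gh)
            grad.H_spk[...] = acc.T
        if self.include_tbar and design.Xb is not None:
            Vb = params.V_tbar[design.neuron]
            grad.T_tbar[...] = np.einsum("mtp,mt,mq->pq", design.Xb, g, Vb)
            gv = np.einsum("mtp,pq,mt->mq", design.Xb, params.T_tbar, g)
            accv = np.zeros((self.N, self.rank_tbar))
            np.add.at(accv, design.neuron, gv)
            grad.V_tbar[...] = accv
        if self.rank > 0:
            Vn = params.V_stim[design.neuron]
            CU_s = design.cs @ params.U_stim
            CU_t = design.ct @ params.U_stim
            accV = np.zeros((self.N, self.rank))
            for gi, rows in enumerate(design.group_rows):
                PS = design.group_AS[gi] @ params.T_stim
                PT = design.group_AT[gi] @ params.T_stim
                gg = g[rows]
                qs = gg @ PS  # (mg, R)
                qt = gg @ PT
                Vr = Vn[rows]
                grad.U_stim += design.cs[rows].T @ (qs * Vr) + design.ct[rows].T @ (qt * Vr)
                accVrows = CU_s[rows] * qs + CU_t[rows] * qt
                np.add.at(accV, design.neuron[rows], accVrows)
                Ws = CU_s[rows] * Vr
                Wt = CU_t[rows] * Vr
                grad.T_stim += design.group_AS[gi].T @ (gg.T @ Ws) + design.group_AT[gi].T @ (
                    gg.T @ Wt
                )
            grad.V_stim[...] = accV
        if params.dyn is not None:
            self._dynamic_grad(params, design, g, grad)
        return ll, grad

    def _dynamic_grad(self, params, design, g, grad):
        d = params.dyn
        a, bgain = self._dynamic_gain_profiles(params, design)
        if self.rank_dyn > 0:
            fh = np.einsum("mtp,pr->mtr", design.Xh, d.H_dspk)
            Vd = d.V_dspk[design.neuron]  # (M, R_h)
            # dV
            gv = np.einsum("mt,mtr,mtr->mr", g, a, fh)
            accv = np.zeros((self.N, self.rank_dyn))
            np.add.at(accv, design.neuron, gv)
            grad.dyn.V_dspk[...] = accv
            # dH (through the filtered-history factor)
            wgt_tr = np.einsum("mt,mtr,mr->mtr", g, a, Vd)
            grad.dyn.H_dspk[...] = np.einsum("mtp,mtr->pr", design.Xh, wgt_tr)
            # dT and dU (through the gain profile)
            wb = np.einsum("mt,mtr,mr->mtr", g, fh, Vd)  # weight on a[m,t,r]
            for gi, rows in enumerate(design.group_rows):
                PSd = design.group_AS[gi] @ d.T_dspk
                PTd = design.group_AT[gi] @ d.T_dspk
                wrows = wb[rows]
                grad.dyn.U_dspk[0] += np.einsum("mtr,tr->r", wrows, PSd)
                grad.dyn.U_dspk[1] += np.einsum("mtr,tr->r", wrows, PTd)
                ws = np.einsum("mtr->tr", wrows)
                grad.dyn.T_dspk += design.group_AS[gi].T @ (ws * d.U_dspk[0][None, :])
                grad.dyn.T_dspk += design.group_AT[gi].T @ (ws * d.U_dspk[1][None, :])
        if self.rank_bdyn > 0 and bgain is not None:
            fhb = np.einsum("mtp,pq->mtq", design.Xh, d.H_bdspk)
            Vb = d.V_bdspk[design.neuron]
            gv = np.einsum("mt,mtq,mtq->mq", g, bgain, fhb)
            accv = np.zeros((self.N, self.rank_bdyn))
            np.add.at(accv, design.neuron, gv)
            grad.dyn.V_bdspk[...] = accv
            wq = np.einsum("mt,mtq,mq->mtq", g, bgain, Vb)
            grad.dyn.H_bdspk[...] = np.einsum("mtp,mtq->pq", design.Xh, wq)
            wT = np.einsum("mt,mtq,mq->mtq", g, fhb, Vb)
            grad.dyn.T_bdspk[...] = np.einsum("mtp,mtq->pq", design.Xb, wT)

    # -- priors -------------------------------------------------------------

    def hyper_names(self) -> list[str]:
        names = list(stim_hyper_names(self.spec))
        if self.include_tbar:
            names.append("psi_tbar")
        if self.include_history:
            names.append("psi_spk")
        if self.rank_bdyn > 0:
            names.append("psi_bdspk")
        if self.rank_dyn > 0:
            names += ["psi_0_dyn", "psi_s_dyn"]
        return names

    def default_hyper(self) -> dict[str, float]:
        return {n: 1.0 for n in self.hyper_names()}

    def _dyn_U_cov(self, hyper) -> np.ndarray:
        # sample/test weights share a latent (no-category construction)
        return hyper["psi_0_dyn"] ** 2 * np.ones((2, 2)) + hyper["psi_s_dyn"] ** 2 * np.eye(2)

    def log_prior(self, params: GmlmParams, hyper: dict[str, float]) -> float:
        """Log prior over parameters (flat on w) plus nothing on hypers."""
        lp = 0.0
        sp = StimulusPrior.build(self.spec, hyper)
        if self.rank > 0:
            lp += sp.logpdf(params.U_stim)
        for X in (params.T_stim, params.V_stim):
            lp += float(-0.5 * np.sum(X**2) - 0.5 * X.size * np.log(2 * np.pi))
        if self.include_tbar:
            psi = hyper["psi_tbar"]
            lp += float(
                -0.5 * np.sum(params.T_tbar**2) / psi**2
                - params.T_tbar.size * (np.log(psi) + 0.5 * np.log(2 * np.pi))
            )
            lp += float(
                -0.5 * np.sum(params.V_tbar**2) - 0.5 * params.V_tbar.size * np.log(2 * np.pi)
            )
        if self.include_history:
            psi = hyper["psi_spk"]
            lp += float(
                -0.5 * np.sum(params.H_spk**2) / psi**2
                - params.H_spk.size * (np.log(psi) + 0.5 * np.log(2 * np.pi))
            )
        if params.dyn is not None:
            d = params.dyn
            for X in (d.V_dspk, d.H_dspk, d.T_dspk, d.V_bdspk, d.H_bdspk):
                lp += float(-0.5 * np.sum(X**2) - 0.5 * X.size * np.log(2 * np.pi))
            if self.rank_bdyn > 0:
                psi = hyper["psi_bdspk"]
                lp += float(
                    -0.5 * np.sum(d.T_bdspk**2) / psi**2
                    - d.T_bdspk.size * (np.log(psi) + 0.5 * np.log(2 * np.pi))
                )
            if self.rank_dyn > 0:
                C = self._dyn_U_cov(hyper) + 1e-10 * np.eye(2)
                cinv = np.linalg.inv(C)
                _, logdet = np.linalg.slogdet(C)
                lp += float(
                    -0.5 * np.einsum("sr,st,tr->", d.U_dspk, cinv, d.U_dspk)
                    - 0.5 * self.rank_dyn * (logdet + 2 * np.log(2 * np.pi))
                )
        return lp

    def log_prior_grad(
        self, params: GmlmParams, hyper: dict[str, float]
    ) -> tuple[float, GmlmParams, dict[str, float]]:
        """Log prior, its parameter gradient, and its log-hyper gradient."""
        lp = self.log_prior(params, hyper)
        grad = self.grad_template()
        hgrad = {n: 0.0 for n in self.hyper_names()}
        sp = StimulusPrior.build(self.spec, hyper)
        if self.rank > 0:
            grad.U_stim[...] = sp.grad_logpdf(params.U_stim)
            for k, v in sp.dlogpdf_dloghyper(params.U_stim).items():
                hgrad[k] += v
        grad.T_stim[...] = -params.T_stim
        grad.V_stim[...] = -params.V_stim
        if self.include_tbar:
            psi = hyper["psi_tbar"]
            grad.T_tbar[...] = -params.T_tbar / psi**2
            grad.V_tbar[...] = -params.V_tbar
            hgrad["psi_tbar"] += float(np.sum(params.T_tbar**2) / psi**2 - params.T_tbar.size)
        if self.include_history:
            psi = hyper["psi_spk"]
            grad.H_spk[...] = -params.H_spk / psi**2
            hgrad["psi_spk"] += float(np.sum(params.H_spk**2) / psi**2 - params.H_spk.size)
        if params.dyn is not None:
            d = params.dyn
            grad.dyn.V_dspk[...] = -d.V_dspk
            grad.dyn.H_dspk[...] = -d.H_dspk
            grad.dyn.T_dspk[...] = -d.T_dspk
            grad.dyn.V_bdspk[...] = -d.V_bdspk
            grad.dyn.H_bdspk[...] = -d.H_bdspk
            if self.rank_bdyn > 0:
                psi = hyper["psi_bdspk"]
                grad.dyn.T_bdspk[...] = -d.T_bdspk / psi**2
                hgrad["psi_bdspk"] += float(
                    np.sum(d.T_bdspk**2) / psi**2 - d.T_bdspk.size
                )
            if self.rank_dyn > 0:
                C = self._dyn_U_cov(hyper) + 1e-10 * np.eye(2)
                cinv = np.linalg.inv(C)
                grad.dyn.U_dspk[...] = -cinv @ d.U_dspk
                PU = cinv @ d.U_dspk
                for name, dC in (
                    ("psi_0_dyn", 2 * hyper["psi_0_dyn"] ** 2 * np.ones((2, 2))),
                    ("psi_s_dyn", 2 * hyper["psi_s_dyn"] ** 2 * np.eye(2)),
                ):
                    hgrad[name] += 0.5 * float(np.sum(PU * (dC @ PU))) - 0.5 * self.rank_dyn * float(
                        np.trace(cinv @ dC)
                    )
        return lp, grad, hgrad

    def log_hyperprior(self, hyper: dict[str, float]) -> float:
        """Half-t hyperprior plus the log-space Jacobian (for sampling log h)."""
        lp = 0.0
        for n in self.hyper_names():
            lp += float(half_t_logpdf(hyper[n])) + np.log(hyper[n])
        return lp

    def log_hyperprior_grad(self, hyper: dict[str, float]) -> dict[str, float]:
        return {
            n: float(half_t_dlogpdf_dlogh(hyper[n])) + 1.0 for n in self.hyper_names()
        }

    # -- joint posterior over (params, log hypers) --------------------------

    def log_posterior(
        self, params: GmlmParams, hyper: dict[str, float], design: PopulationDesign
    ) -> float:
        return (
            self.log_likelihood(params, design)
            + self.log_prior(params, hyper)
            + self.log_hyperprior(hyper)
        )

    def log_posterior_and_grad(
        self, params: GmlmParams, hyper: dict[str, float], design: PopulationDesign
    ) -> tuple[float, GmlmParams, dict[str, float]]:
        ll, gl = self.log_likelihood_and_grad(params, design)
        lp, gp, hg = self.log_prior_grad(params, hyper)
        hp = self.log_hyperprior(hyper)
        hpg = self.log_hyperprior_grad(hyper)
        total = ll + lp + hp
        gvec = self.pack(gl) + self.pack(gp)
        grad = self.unpack(gvec)
        hgrad = {n: hg[n] + hpg[n] for n in self.hyper_names()}
        return total, grad, hgrad

    # -- maximum likelihood / MAP fitting ------------------------------------

    def fit_mle(
        self,
        design: PopulationDesign,
        rng: np.random.Generator | None = None,
        params0: GmlmParams | None = None,
        max_iter: int = 500,
        gtol: float = 1e-6,
        ridge: float = 1e-3,
        n_restarts: int = 1,
    ) -> GmlmParams:
        """Gradient-based maximum-likelihood fit (used for rank selection).

        A small ridge on all non-baseline parameters keeps the optimum
        finite: Poisson ML otherwise diverges along kernel directions
        whose support only touches zero-count bins (rates driven to 0 at
        no likelihood cost). The default penalty is negligible relative to
        the data term everywhere except on those escape directions.
        CP factorizations are non-convex, so ``n_restarts`` random
        initializations are fit and the best likelihood kept.
        """
        from scipy.optimize import minimize

        rng = np.random.default_rng(0) if rng is None else rng
        pen_mask = np.ones(self.n_params)
        pen_mask[: self.N] = 0.0  # baselines unpenalized

        def fun(x):
            ll, grad = self.log_likelihood_and_grad(self.unpack(x), design)
            f = -ll + 0.5 * ridge * np.sum(pen_mask * x**2)
            g = -self.pack(grad) + ridge * pen_mask * x
            return f, g

        best_x, best_f = None, np.inf
        for rep in range(max(1, n_restarts)):
            if params0 is not None and rep == 0:
                x0 = self.pack(params0)
            else:
                x0 = self.pack(self.init_params(rng, design))
            res = minimize(
                fun, x0, jac=True, method="L-BFGS-B",
                options={"maxiter": max_iter, "gtol": gtol},
            )
            if res.fun < best_f:
                best_x, best_f = res.x, res.fun
        return self.unpack(best_x)

    def fit_map(
        self,
        design: PopulationDesign,
        hyper: dict[str, float],
        params0: GmlmParams | None = None,
        rng: np.random.Generator | None = None,
        max_iter: int = 500,
    ) -> GmlmParams:
        """MAP fit at fixed hyperparameters."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(0) if rng is None else rng
        x0 = self.pack(params0 if params0 is not None else self.init_params(rng, design))

        def fun(x):
            p = self.unpack(x)
            ll, gl = self.log_likelihood_and_grad(p, design)
            lp, gp, _ = self.log_prior_grad(p, hyper)
            return -(ll + lp), -(self.pack(gl) + self.pack(gp))

        res = minimize(fun, x0, jac=True, method="L-BFGS-B", options={"maxiter": max_iter})
        return self.unpack(res.x)
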