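import numpy as np
import pytest

from poptensor import glm as glm_mod
from poptensor.gmlm import (
    GmlmModel,
    build_population_design,
    kernel_tensor,
    rescale_component,
)
from poptensor.synthetic import TaskSchedule, sample_ground_truth, simulate_trials
from poptensor.task_design import modelable


class TestKernelTensor:
    def test_rank1_unit_factors(self, compact_bases):
        from poptensor.task_design import DesignSpec

        spec = DesignSpec(parameterization="cosine")
        model = GmlmModel(spec, compact_bases, 3, rank=1, include_history=False, include_tbar=False)
        p = model.unpack(np.zeros(model.n_params))
        p.T_stim[2, 0] = 1.0
        p.U_stim[1, 0] = 1.0
        p.V_stim[0, 0] = 1.0
        K = kernel_tensor(p, compact_bases)
        expected = np.zeros_like(K)
        expected[:, 1, 0] = compact_bases.stim.B[:, 2]
        assert np.allclose(K, expected)

    def test_matches_triple_loop(self, compact_bases):
        from poptensor.task_design import DesignSpec

        spec = DesignSpec(parameterization="cosine")
        model = GmlmModel(spec, compact_bases, 4, rank=2, include_history=False, include_tbar=False)
        rng = np.random.default_rng(0)
        p = model.unpack(rng.standard_normal(model.n_params))
        K = kernel_tensor(p, compact_bases)
        Tk = compact_bases.stim.B @ p.T_stim
        brute = np.zeros_like(K)
        for t in range(K.shape[0]):
            for s in range(K.shape[1]):
                for n in range(K.shape[2]):
                    brute[t, s, n] = sum(
                        Tk[t, r] * p.U_stim[s, r] * p.V_stim[n, r] for r in range(2)
                    )
        assert np.allclose(K, brute, atol=1e-12)

    def test_rescaling_leaves_tensor_unchanged(self, compact_bases):
        from poptensor.task_design import DesignSpec

        spec = DesignSpec(parameterization="cosine")
        model = GmlmModel(spec, compact_bases, 4, rank=2, include_history=False, include_tbar=False)
        rng = np.random.default_rng(1)
        p = model.unpack(rng.standard_normal(model.n_params))
        K0 = kernel_tensor(p, compact_bases)
        p2 = rescale_component(p, 0, a=2.0, b=3.0)
        assert np.allclose(kernel_tensor(p2, compact_bases), K0, atol=1e-12)

    def test_zero_rescale_rejected(self, compact_bases):
        from poptensor.task_design import DesignSpec

        spec = DesignSpec(parameterization="cosine")
        model = GmlmModel(spec, compact_bases, 2, rank=1, include_history=False, include_tbar=False)
        p = model.unpack(np.zeros(model.n_params))
        with pytest.raises(ValueError):
            rescale_component(p, 0, a=0.0, b=1.0)


class TestLogRates:
    def test_rank0_reduces_to_baseline_history(self, small_population):
        truth, data = small_population
        model = GmlmModel(
            truth.model.spec, truth.model.bases, 4, rank=0,
            include_history=True, include_tbar=False, bin_width=data.bin_width,
        )
        design = model.build_design(data)
        rng = np.random.default_rng(2)
        p = model.init_params(rng, design)
        lam = model.log_rates(p, design)
        Hn = p.H_spk[:, design.neuron].T
        expected = p.w[design.neuron][:, None] + np.einsum("mtp,mp->mt", design.Xh, Hn)
        assert np.allclose(lam, expected, atol=1e-12)

    def test_rank1_onehot_places_temporal_kernel(self, compact_schedule, compact_bases):
        """One-hot U on the sample-category coefficient and unit loading:
        log rate minus baseline is the temporal kernel at sample onset."""
        truth = sample_ground_truth("mixed", 2, 1, seed=61, schedule=compact_schedule)
        data = simulate_trials(truth, 2, seed=62)
        model = GmlmModel(
            truth.model.spec, compact_bases, 2, rank=1,
            include_history=False, include_tbar=False, bin_width=data.bin_width,
        )
        design = model.build_design(data)
        p = model.unpack(np.zeros(model.n_params))
        rng = np.random.default_rng(3)
        p.T_stim[:, 0] = rng.standard_normal(model.P_stim)
        labels = model.spec.coefficient_labels()
        p.U_stim[labels.index("cs1"), 0] = 1.0
        p.V_stim[:, 0] = 1.0
        lam = model.log_rates(p, design)
        kern = compact_bases.stim.B @ p.T_stim[:, 0]
        for m in range(design.n_rows):
            if design.cs[m][labels.index("cs1")] == 1.0:
                L = min(len(kern), design.Tmax)
                assert np.allclose(lam[m, :L], kern[:L], atol=1e-12)

    def test_glm_equivalence_oracle(self, small_population):
        """The population model evaluated at any parameters equals per-cell
        GLMs whose kernels come from the CP kernel tensor."""
        truth, data = small_population
        spec, bases = truth.model.spec, truth.model.bases
        model = GmlmModel(
            spec, bases, 4, rank=2, include_history=True,
            include_tbar=False, bin_width=data.bin_width,
        )
        design = model.build_design(data)
        rng = np.random.default_rng(4)
        p = model.init_params(rng, design)
        ll = model.log_likelihood(p, design)
        K = kernel_tensor(p, bases)
        total = 0.0
        for n, nid in enumerate(data.neuron_ids):
            trials = [t for t in data.trials_of(nid) if modelable(t, spec)]
            gd = glm_mod.build_design(trials, spec, bases, data.bin_width)
            gp = glm_mod.GlmParams(
                w=float(p.w[n]),
                h_coeffs=p.H_spk[:, n],
                tbar_coeffs=np.zeros(gd.P_tbar),
                stim_coeffs=(bases.stim.B.T @ K[:, :, n]).T,
            )
            total += glm_mod.log_likelihood(gp, gd)
        assert ll == pytest.approx(total, abs=1e-8)


class TestLikelihoodProperties:
    def test_rescaling_invariance_of_likelihood(self, fitted_small_model):
        model, design, params = fitted_small_model
        ll0 = model.log_likelihood(params, design)
        p2 = rescale_component(params, 1, a=-1.7, b=0.3)
        assert abs(model.log_likelihood(p2, design) - ll0) < 1e-10 * max(1, abs(ll0))

    def test_population_ll_is_sum_over_neurons(self, small_population):
        """Neurons contribute independently (no noise correlations)."""
        import dataclasses

        truth, data = small_population
        spec, bases = truth.model.spec, truth.model.bases
        model = GmlmModel(spec, bases, 4, rank=2, include_history=True,
                          include_tbar=False, bin_width=data.bin_width)
        design = model.build_design(data)
        rng = np.random.default_rng(5)
        p = model.init_params(rng, design)
        total = model.log_likelihood(p, design)
        acc = 0.0
        for n, nid in enumerate(data.neuron_ids):
            sub = dataclasses.replace(data, neuron_ids=[nid], trials=data.trials_of(nid))
            m1 = GmlmModel(spec, bases, 1, rank=2, include_history=True,
                           include_tbar=False, bin_width=data.bin_width)
            d1 = m1.build_design(sub)
            p1 = m1.unpack(np.zeros(m1.n_params))
            p1.w[0] = p.w[n]
            p1.H_spk[:, 0] = p.H_spk[:, n]
            p1.T_stim[...] = p.T_stim
            p1.U_stim[...] = p.U_stim
            p1.V_stim[0] = p.V_stim[n]
            acc += m1.log_likelihood(p1, d1)
        assert total == pytest.approx(acc, abs=1e-8)

    def test_duplicating_data_doubles_likelihood_not_prior(self, small_population):
        import dataclasses

        truth, data = small_population
        model = GmlmModel(truth.model.spec, truth.model.bases, 4, rank=1,
                          include_history=True, include_tbar=False, bin_width=data.bin_width)
        doubled = dataclasses.replace(data, trials=data.trials + data.trials)
        d1 = model.build_design(data)
        d2 = model.build_design(doubled)
        rng = np.random.default_rng(6)
        p = model.init_params(rng, d1)
        h = model.default_hyper()
        assert model.log_likelihood(p, d2) == pytest.approx(2 * model.log_likelihood(p, d1), rel=1e-12)
        assert model.log_prior(p, h) == model.log_prior(p, h)  # unchanged by data

    def test_collapsed_design_matches_uncollapsed(self, compact_schedule):
        """Sufficient-statistic collapse leaves the likelihood unchanged."""
        truth = sample_ground_truth("mixed", 3, 1, seed=71, schedule=compact_schedule)
        data = simulate_trials(truth, 6, seed=72)
        spec, bases = truth.model.spec, truth.model.bases
        m = GmlmModel(spec, bases, 3, rank=1, include_history=False,
                      include_tbar=False, bin_width=data.bin_width)
        d_fast = m.build_design(data)
        assert d_fast.collapsed
        d_slow = build_population_design(data, spec, bases, need_history=True, need_tbar=False)
        m2 = GmlmModel(spec, bases, 3, rank=1, include_history=True,
                       include_tbar=False, bin_width=data.bin_width)
        rng = np.random.default_rng(7)
        p = m.init_params(rng, d_fast)
        p2 = m2.unpack(np.zeros(m2.n_params))
        p2.w[...] = p.w
        p2.T_stim[...] = p.T_stim
        p2.U_stim[...] = p.U_stim
        p2.V_stim[...] = p.V_stim
        assert m.log_likelihood(p, d_fast) == pytest.approx(
            m2.log_likelihood(p2, d_slow), abs=1e-9
        )


class TestGradients:
    def test_likelihood_gradient_finite_difference(self, fitted_small_model):
        model, design, params = fitted_small_model
        _, grad = model.log_likelihood_and_grad(params, design)
        x = model.pack(params)
        gv = model.pack(grad)
        rng = np.random.default_rng(8)
        for i in rng.choice(len(x), size=12, replace=False):
            e = 1e-6
            xp, xm = x.copy(), x.copy()
            xp[i] += e
            xm[i] -= e
            fd = (
                model.log_likelihood(model.unpack(xp), design)
                - model.log_likelihood(model.unpack(xm), design)
            ) / (2 * e)
            assert gv[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_posterior_gradient_with_dynamics(self, small_population_tbar):
        """Joint gradient (params + log hypers) of the full model with
        dynamic spike history matches finite differences."""
        truth, data = small_population_tbar
        model = GmlmModel(
            truth.model.spec, truth.model.bases, 3, rank=1,
            include_history=True, include_tbar=True,
            rank_dyn=1, rank_bdyn=1, bin_width=data.bin_width,
        )
        design = model.build_design(data)
        rng = np.random.default_rng(9)
        p = model.init_params(rng, design)
        h = {n: float(np.exp(0.2 * rng.standard_normal())) for n in model.hyper_names()}
        _, grad, hgrad = model.log_posterior_and_grad(p, h, design)
        x = model.pack(p)
        gv = model.pack(grad)
        for i in rng.choice(len(x), size=10, replace=False):
            e = 1e-6
            xp, xm = x.copy(), x.copy()
            xp[i] += e
            xm[i] -= e
            fd = (
                model.log_posterior(model.unpack(xp), h, design)
                - model.log_posterior(model.unpack(xm), h, design)
            ) / (2 * e)
            assert gv[i] == pytest.approx(fd, rel=1e-5, abs=1e-6)
        for name in model.hyper_names():
            e = 1e-6
            hp, hm = dict(h), dict(h)
            hp[name] = float(np.exp(np.log(h[name]) + e))
            hm[name] = float(np.exp(np.log(h[name]) - e))
            fd = (
                model.log_posterior(p, hp, design) - model.log_posterior(p, hm, design)
            ) / (2 * e)
            assert hgrad[name] == pytest.approx(fd, rel=1e-4, abs=1e-6)


@pytest.fixture(scope="module")
def dyn_setup(small_population_tbar):
    truth, data = small_population_tbar
    model = GmlmModel(
        truth.model.spec, truth.model.bases, 3, rank=1,
        include_history=True, include_tbar=True,
        rank_dyn=1, rank_bdyn=1, bin_width=data.bin_width,
    )
    design = model.build_design(data)
    rng = np.random.default_rng(10)
    params = model.init_params(rng, design)
    return model, design, params


class TestDynamicHistory:
    def test_zero_dynamic_factors_contribute_nothing(self, dyn_setup):
        model, design, params = dyn_setup
        p = model.unpack(model.pack(params))
        p.dyn.V_dspk[...] = 0.0
        p.dyn.V_bdspk[...] = 0.0
        assert np.allclose(model._dynamic_term(p, design), 0.0)

    def test_no_spikes_no_dynamic_contribution(self, dyn_setup, small_population_tbar):
        """The dynamic term filters the spike train: silence in, zero out."""
        import dataclasses

        truth, data = small_population_tbar
        model, _, params = dyn_setup
        silent = dataclasses.replace(
            data,
            trials=[
                dataclasses.replace(t, counts=np.zeros_like(t.counts))
                for t in data.trials
            ],
        )
        d0 = model.build_design(silent)
        assert np.allclose(model._dynamic_term(params, d0), 0.0)

    def test_two_pass_oracle(self, dyn_setup):
        """Dynamic term equals the elementwise product of independently
        computed gain and filtered-history traces."""
        model, design, params = dyn_setup
        d = params.dyn
        out = model._dynamic_term(params, design)
        a, bgain = model._dynamic_gain_profiles(params, design)
        expected = np.zeros_like(out)
        for m in range(design.n_rows):
            fh = design.Xh[m] @ d.H_dspk  # (T, R_h)
            n = design.neuron[m]
            for r in range(model.rank_dyn):
                expected[m] += a[m, :, r] * fh[:, r] * d.V_dspk[n, r]
            fhb = design.Xh[m] @ d.H_bdspk
            for q in range(model.rank_bdyn):
                expected[m] += bgain[m, :, q] * fhb[:, q] * d.V_bdspk[n, q]
        assert np.allclose(out, expected, atol=1e-10)

    def test_doubling_loading_doubles_dynamic_part(self, dyn_setup):
        model, design, params = dyn_setup
        base = model._dynamic_term(params, design)
        p2 = model.unpack(model.pack(params))
        p2.dyn.V_dspk[...] *= 2.0
        p2.dyn.V_bdspk[...] *= 2.0
        assert np.allclose(model._dynamic_term(p2, design), 2 * base, atol=1e-10)

    def test_effective_kernel_reduces_to_constant_without_gains(self, dyn_setup):
        model, design, params = dyn_setup
        p = model.unpack(model.pack(params))
        p.dyn.V_dspk[...] = 0.0
        p.dyn.V_bdspk[...] = 0.0
        kern = model.effective_history_kernel(p, design, row=0, t=5)
        n = design.neuron[0]
        assert np.allclose(kern, model.bases.hist.B @ p.H_spk[:, n])

    def test_effective_kernel_reproduces_dynamic_rate(self, dyn_setup):
        """Convolving the spike train with the per-time effective kernel
        reproduces history + dynamic-history contributions to the rate."""
        model, design, params = dyn_setup
        lam = model.log_rates(params, design)
        # rate without any history terms
        p0 = model.unpack(model.pack(params))
        p0.H_spk[...] = 0.0
        p0.dyn.V_dspk[...] = 0.0
        p0.dyn.V_bdspk[...] = 0.0
        lam0 = model.log_rates(p0, design)
        m = next(i for i in range(design.n_rows) if design.Y[i].sum() > 2)
        y = design.Y[m]
        lags = model.bases.hist.lags
        T = int(design.mask[m].sum())
        for t in (10, T - 5):
            kern = model.effective_history_kernel(params, design, row=m, t=t)
            contrib = sum(
                y[t - lag] * kern[row]
                for row, lag in enumerate(lags)
                if 0 <= t - lag < T
            )
            assert lam[m, t] - lam0[m, t] == pytest.approx(contrib, abs=1e-8)


class TestFullRankEquivalence:
    def test_full_rank_gmlm_matches_per_cell_glm(self, compact_schedule):
        """An exact CP factorization of per-cell GLM kernels evaluates to
        the same likelihood as the GLMs themselves."""
        truth = sample_ground_truth("mixed", 3, 2, seed=81, schedule=compact_schedule)
        data = simulate_trials(truth, 5, seed=82)
        spec, bases = truth.model.spec, truth.model.bases
        rng = np.random.default_rng(11)
        # arbitrary per-cell GLM kernels (full-rank tensor)
        K = 0.3 * rng.standard_normal((len(bases.stim.B), spec.S, 3))
        coeffs = np.einsum("lp,lsn->psn", bases.stim.B, K)
        K_basis = np.einsum("lp,psn->lsn", bases.stim.B, coeffs)  # projection
        # CP-factorize exactly via unfolding SVD (rank = S * N is enough)
        mat = coeffs.reshape(coeffs.shape[0], -1)  # (P, S*N)
        U_, s_, Vt_ = np.linalg.svd(mat, full_matrices=False)
        R = int((s_ > 1e-12).sum())
        model = GmlmModel(spec, bases, 3, rank=R, include_history=False,
                          include_tbar=False, bin_width=data.bin_width)
        p = model.unpack(np.zeros(model.n_params))
        p.w[...] = truth.params.w
        p.T_stim[...] = U_[:, :R] * s_[:R]
        sv = Vt_[:R].reshape(R, spec.S, 3)
        # split the (S, N) part of each component into U and V legs:
        # each SVD component is a P x (S*N) rank-1 term, not S x N rank-1,
        # so expand further per component
        comps_T, comps_U, comps_V = [], [], []
        for r in range(R):
            u2, s2, v2 = np.linalg.svd(sv[r], full_matrices=False)
            for k in range(int((s2 > 1e-12).sum())):
                comps_T.append(p.T_stim[:, r])
                comps_U.append(u2[:, k] * s2[k])
                comps_V.append(v2[k])
        R_full = len(comps_T)
        model = GmlmModel(spec, bases, 3, rank=R_full, include_history=False,
                          include_tbar=False, bin_width=data.bin_width)
        p = model.unpack(np.zeros(model.n_params))
        p.w[...] = truth.params.w
        p.T_stim[...] = np.array(comps_T).T
        p.U_stim[...] = np.array(comps_U).T
        p.V_stim[...] = np.array(comps_V).T
        assert np.allclose(kernel_tensor(p, bases), K_basis, atol=1e-8)
        design = model.build_design(data)
        ll = model.log_likelihood(p, design)
        total = 0.0
        for n, nid in enumerate(data.neuron_ids):
            trials = [t for t in data.trials_of(nid) if modelable(t, spec)]
            gd = glm_mod.build_design(trials, spec, bases, data.bin_width)
            gp = glm_mod.GlmParams(
                w=float(truth.params.w[n]),
                h_coeffs=np.zeros(gd.P_spk),
                tbar_coeffs=np.zeros(gd.P_tbar),
                stim_coeffs=coeffs[:, :, n].T,
            )
            total += glm_mod.log_likelihood(gp, gd)
        assert ll == pytest.approx(total, abs=1e-8)
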