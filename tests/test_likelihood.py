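import copy

import numpy as np
import pytest
import scipy.linalg as sla
from scipy.stats import multivariate_normal, poisson

from agape.data_io import Recording, SpikeTrainBinned, VoltageTrace
from agape.fitting import _pack, _unpack
from agape.kernels import AdaptKernelParams, CovKernelParams, SpikeKernelParams
from agape.likelihood import (
    FreeFlags,
    Workspace,
    grad_hess,
    joint_loglik,
    joint_loglik_ws,
    loglik_gp_term,
    loglik_spike_term,
    param_names,
    residual_subthreshold,
)
from agape.simulator import AgapeParams, compose_usom, simulate


def _tiny_rec(u, counts, dt=1.0):
    return Recording([(VoltageTrace(np.asarray(u, float), dt), SpikeTrainBinned(counts, dt))])


def _perturbed_truth(truth):
    q = copy.deepcopy(truth)
    q.u_r += 0.4
    q.beta = 0.3
    q.cov = CovKernelParams(truth.cov.weights * 1.15, truth.cov.rates)
    q.spike_kernel = SpikeKernelParams(truth.spike_kernel.a * 0.9, 1.0)
    q.adapt = AdaptKernelParams(
        truth.adapt.weights * 0.7, truth.adapt.rise_rates, truth.adapt.decay_rates
    )
    return q


class TestResidual:
    def test_zero_kernel(self, small_rec, truth):
        res = residual_subthreshold(small_rec, truth.u_r, SpikeKernelParams(np.zeros(60)))
        np.testing.assert_allclose(
            res[0], small_rec.segments[0][0].values - truth.u_r, atol=1e-12
        )

    def test_hand_convolution(self):
        a = np.zeros(60)
        a[0] = 2.0  # a_1
        counts = np.zeros(5, int)
        counts[0] = 1
        rec = _tiny_rec([0.0, 1.0, 0.0, 0.0, 0.0], counts)
        res = residual_subthreshold(rec, 0.0, SpikeKernelParams(a))[0]
        assert res[1] == pytest.approx(1.0 - 2.0)

    def test_inverse_of_compose(self, rng):
        sk = SpikeKernelParams(rng.normal(size=60), 1.0)
        u = rng.normal(size=300)
        counts = rng.poisson(0.05, 300)
        usom = compose_usom(u, counts, -55.0, sk, 1.0)
        rec = _tiny_rec(usom, counts)
        np.testing.assert_allclose(residual_subthreshold(rec, -55.0, sk)[0], u, atol=1e-10)

    def test_no_carry_over_between_segments(self, rng):
        sk = SpikeKernelParams(np.ones(60), 1.0)
        counts = np.zeros(30, int)
        counts[29] = 1  # spike at the very end of segment 1
        tr = VoltageTrace(np.zeros(30), 1.0)
        rec = Recording([(tr, SpikeTrainBinned(counts, 1.0)), (tr, SpikeTrainBinned(np.zeros(30, int), 1.0))])
        res = residual_subthreshold(rec, 0.0, sk)
        np.testing.assert_array_equal(res[1], np.zeros(30))


class TestGPTerm:
    def test_single_segment_matches_gp_logpdf(self, rng):
        from agape.circulant_gp import circulant_from_toeplitz, gp_logpdf

        cov = CovKernelParams([1.0, 0.3], [0.4, 0.05])
        v = rng.normal(size=50)
        cm = circulant_from_toeplitz(cov.k_row(np.arange(50.0)), 50, 1.0)
        assert loglik_gp_term([v], cov) == pytest.approx(gp_logpdf(v, cm))

    def test_two_identical_segments_double(self, rng):
        cov = CovKernelParams([2.0], [0.2])
        v = rng.normal(size=40)
        assert loglik_gp_term([v, v], cov) == pytest.approx(2 * loglik_gp_term([v], cov))

    def test_dense_oracle_n8(self, rng):
        from agape.circulant_gp import circulant_from_toeplitz

        cov = CovKernelParams([1.5], [0.3])
        v = rng.normal(size=8)
        cm = circulant_from_toeplitz(cov.k_row(np.arange(8.0)), 8, 1.0)
        dense = multivariate_normal(cov=sla.circulant(cm.c).T).logpdf(v)
        assert loglik_gp_term([v], cov) == pytest.approx(dense, abs=1e-8)


class TestSpikeTerm:
    def test_void_probability(self):
        rec = _tiny_rec(np.zeros(100), np.zeros(100, int))
        res = [np.zeros(100)]
        ll = loglik_spike_term(res, rec, np.log(0.02), 0.0, None)
        assert ll == pytest.approx(-100 * 0.02)

    def test_single_spike_constant_rate(self):
        counts = np.zeros(50, int)
        counts[7] = 1
        rec = _tiny_rec(np.zeros(50), counts)
        ll = loglik_spike_term([np.zeros(50)], rec, np.log(0.01), 0.0, None)
        assert ll == pytest.approx(np.log(0.01) - 50 * 0.01)

    def test_poisson_pmf_oracle(self):
        counts = np.array([0, 1, 0, 2, 0])
        v = np.array([0.5, -0.2, 0.1, 0.8, 0.0])
        rec = _tiny_rec(v, counts)
        beta, log_r0 = 0.7, np.log(0.3)
        ll = loglik_spike_term([v], rec, log_r0, beta, None)
        mu = 0.3 * np.exp(beta * v)
        want = sum(poisson(m).logpmf(c) for m, c in zip(mu, counts))
        assert ll == pytest.approx(want)

    def test_logfactorial_always_included(self):
        counts = np.array([3, 0])
        rec = _tiny_rec(np.zeros(2), counts)
        ll = loglik_spike_term([np.zeros(2)], rec, np.log(0.5), 0.0, None)
        want = poisson(0.5).logpmf(3) + poisson(0.5).logpmf(0)
        assert ll == pytest.approx(want)


class TestJointLoglik:
    def test_additivity(self, small_rec, truth):
        res = residual_subthreshold(small_rec, truth.u_r, truth.spike_kernel)
        total = loglik_gp_term(res, truth.cov) + loglik_spike_term(
            res, small_rec, truth.log_r0, truth.beta, truth.adapt
        )
        assert joint_loglik(small_rec, truth) == total

    def test_translation_invariance(self, small_rec, truth):
        shifted = copy.deepcopy(truth)
        shifted.u_r += 3.7
        tr, sp = small_rec.segments[0]
        rec2 = Recording([(VoltageTrace(tr.values + 3.7, tr.dt), sp)])
        assert joint_loglik(rec2, shifted) == pytest.approx(
            joint_loglik(small_rec, truth), abs=1e-6
        )

    def test_ws_fast_path_agrees(self, small_rec, small_ws, truth):
        assert joint_loglik_ws(small_ws, truth) == pytest.approx(
            joint_loglik(small_rec, truth), abs=1e-6
        )

    def test_monte_carlo_stability_at_truth(self, truth):
        """Average per-bin log-likelihood at the generating parameters is a
        law-of-large-numbers quantity: spread over seeds shrinks with n."""
        vals = np.array(
            [
                joint_loglik(simulate(truth, 4000, 1.0, seed=s).recording, truth, per_bin=True)
                for s in range(12)
            ]
        )
        assert vals.std(ddof=1) / abs(vals.mean()) < 0.02

    def test_circulant_boundary_error_shrinks_with_n(self):
        """Mean per-bin discrepancy to the dense Toeplitz likelihood decays
        ~1/n: the wrap-around affects only an O(correlation length) boundary,
        so its per-realization cost does not grow with n."""
        cov = CovKernelParams([2.0], [0.05])
        rng = np.random.default_rng(6)
        errs = []
        for n in (128, 512, 2048):
            k = cov.k_row(np.arange(n, dtype=float))
            kmat = sla.toeplitz(k)
            chol = np.linalg.cholesky(kmat)
            dist = multivariate_normal(cov=kmat)
            per_bin = [
                abs(loglik_gp_term([u], cov) - dist.logpdf(u)) / n
                for u in (chol @ rng.standard_normal((n, 12))).T
            ]
            errs.append(np.mean(per_bin))
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < errs[0] / 4


class TestDerivatives:
    def test_gradient_hessian_vs_finite_differences(self, truth):
        out = simulate(truth, 2500, 1.0, seed=13)
        rec = out.recording
        ws = Workspace(rec, 60)
        free = FreeFlags()
        q = _perturbed_truth(truth)
        x0 = _pack(q, "all", free)
        g, h = grad_hess(rec, q, "all", ws, free)

        def f(x):
            return joint_loglik_ws(ws, _unpack(x, q, "all", free))

        n = x0.size
        idx = list(range(n))
        gfd = np.zeros(n)
        for i in idx:
            e = np.zeros(n)
            e[i] = 1e-5 * max(1.0, abs(x0[i]))
            gfd[i] = (f(x0 + e) - f(x0 - e)) / (2 * e[i])
        np.testing.assert_allclose(g, gfd, rtol=1e-5, atol=1e-4)

        # Hessian via finite differences of the analytic gradient
        some = [0, 3, 11, 40, 71, 72, 75]  # u_r, sigma2, a, log_r0, beta, w
        for i in some:
            e = np.zeros(n)
            e[i] = 1e-5 * max(1.0, abs(x0[i]))
            gp_, _ = grad_hess(rec, _unpack(x0 + e, q, "all", free), "all", ws, free)
            gm_, _ = grad_hess(rec, _unpack(x0 - e, q, "all", free), "all", ws, free)
            np.testing.assert_allclose(h[i], (gp_ - gm_) / (2 * e[i]), rtol=2e-5, atol=1e-4)

    def test_block_views_match_full(self, truth, small_rec, small_ws):
        q = _perturbed_truth(truth)
        free = FreeFlags()
        g_all, h_all = grad_hess(small_rec, q, "all", small_ws, free)
        names = param_names(q, "all", free)
        for block in ("gp", "spike_kernel", "spiking"):
            g_b, h_b = grad_hess(small_rec, q, block, small_ws, free)
            sel = [names.index(nm) for nm in param_names(q, block, free)]
            np.testing.assert_allclose(g_b, g_all[sel], rtol=1e-12, atol=1e-9)
            np.testing.assert_allclose(h_b, h_all[np.ix_(sel, sel)], rtol=1e-12, atol=1e-9)

    def test_spiking_hessian_negative_semidefinite(self, truth, rng):
        """Exponential gain => the spiking block is a concave Poisson GLM."""
        out = simulate(truth, 1000, 1.0, seed=17)
        rec = out.recording
        ws = Workspace(rec, 60)
        q = copy.deepcopy(truth)
        for _ in range(100):
            q.log_r0 = truth.log_r0 + rng.normal(0, 1)
            q.beta = abs(rng.normal(0.3, 0.3))
            q.adapt = AdaptKernelParams(
                rng.normal(0, 0.5, 10), truth.adapt.rise_rates, truth.adapt.decay_rates
            )
            _, h = grad_hess(rec, q, "spiking", ws)
            eigs = np.linalg.eigvalsh(h)
            assert eigs[-1] <= 1e-10 * max(1.0, abs(eigs[0]))

    def test_spike_kernel_spiking_subhessian_nsd(self, truth, rng):
        """The spiking contribution to the a-block Hessian is -beta^2 M' diag(mu) M <= 0."""
        out = simulate(truth, 1500, 1.0, seed=19)
        rec = out.recording
        ws = Workspace(rec, 60)
        seg = ws.segments[0]
        mu = rng.uniform(0.001, 0.05, seg.n)
        m = seg.mt_diag_m(mu)
        eigs = np.linalg.eigvalsh(0.5 * (m + m.T))
        assert eigs[0] >= -1e-10 * max(1.0, eigs[-1])

    def test_poisson_mle_closed_form_gradient(self):
        counts = np.zeros(200, int)
        counts[[5, 50, 120]] = 1
        rec = _tiny_rec(np.zeros(200), counts)
        mle_r0 = 3 / 200.0
        p = AgapeParams(
            u_r=0.0,
            log_r0=float(np.log(mle_r0)),
            beta=0.0,
            delta=0.0,
            cov=CovKernelParams([1.0], [0.5]),
            spike_kernel=SpikeKernelParams(np.zeros(60)),
            adapt=None,
        )
        g, _ = grad_hess(rec, p, "spiking", free=FreeFlags(adapt=False, beta=False))
        assert g[0] == pytest.approx(0.0, abs=1e-10)  # d/dlog_r0 at the MLE
        p.log_r0 = np.log(0.05)
        g2, _ = grad_hess(rec, p, "spiking", free=FreeFlags(adapt=False, beta=False))
        assert g2[0] == pytest.approx(3 - 200 * 0.05)


class TestGramShortcuts:
    """The FFT/gather Gram matrices must equal dense linear algebra."""

    def test_mt_cinv_m_and_mt_diag_m_vs_dense(self, rng):
        from agape.circulant_gp import circulant_from_toeplitz

        n, J = 300, 60
        counts = rng.poisson(0.08, n)
        rec = _tiny_rec(rng.normal(size=n), counts)
        ws = Workspace(rec, J)
        seg = ws.segments[0]
        cov = CovKernelParams([1.0, 0.4], [0.5, 0.05])
        cm = circulant_from_toeplitz(cov.k_row(np.arange(n, dtype=float)), n, 1.0)
        cmat = sla.circulant(cm.c).T
        m = np.zeros((n, J))
        s = counts.astype(float)
        for j in range(1, J + 1):
            m[j:, j - 1] = s[: n - j]
        np.testing.assert_allclose(
            seg.mt_cinv_m(cm.c_hat), m.T @ np.linalg.solve(cmat, m), rtol=1e-8, atol=1e-8
        )
        mu = rng.uniform(0.0, 0.1, n)
        np.testing.assert_allclose(seg.mt_diag_m(mu), m.T @ (mu[:, None] * m), atol=1e-10)
        x = rng.normal(size=n)
        np.testing.assert_allclose(seg.mt_dot(x), m.T @ x, atol=1e-10)
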