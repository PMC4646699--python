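import copy

import numpy as np
import pytest

from agape.data_io import Recording
from agape.fitting import (
    FitOptions,
    check_concavity,
    feasibility,
    fit,
    fit_fixed_delta,
    init_params,
)
from agape.kernels import CovKernelParams, SingleOUCov, SpikeKernelParams
from agape.likelihood import FreeFlags, Workspace, joint_loglik
from agape.preprocessing import nominal_spike_bins
from agape.simulator import AgapeParams, simulate


def _quick_opt(**kw):
    kw.setdefault("delta_grid", (4.0,))
    kw.setdefault("n_restarts", 1)
    kw.setdefault("compute_se", False)
    return FitOptions(**kw)


class TestInit:
    def test_single_ou_autocov_recovery(self):
        # data from one OU component: NNLS concentrates near its rate and
        # recovers the total variance within 20%
        p = AgapeParams(
            u_r=-60.0,
            log_r0=np.log(0.004),
            beta=0.0,
            delta=0.0,
            cov=CovKernelParams([4.0], [0.125]),
            spike_kernel=SpikeKernelParams(np.zeros(60)),
            adapt=None,
        )
        out = simulate(p, 60_000, 1.0, seed=23)
        init = init_params(out.recording)
        w = init.cov.weights
        assert abs(w.sum() - 4.0) / 4.0 < 0.2
        near = w[[1, 2, 3]].sum()  # rates 2^-2, 2^-3, 2^-4 straddle 0.125
        assert near / w.sum() > 0.8

    def test_white_noise_mean(self, rng):
        from agape.data_io import SpikeTrainBinned, VoltageTrace

        v = -52.0 + rng.normal(0, 1, 20_000)
        rec = Recording([(VoltageTrace(v, 1.0), SpikeTrainBinned(np.zeros(20_000, int), 1.0))])
        with pytest.warns(UserWarning, match="no spikes"):
            init = init_params(rec)
        assert init.u_r == pytest.approx(v.mean())

    def test_rate_from_counts(self, small_rec):
        init = init_params(small_rec)
        want = small_rec.n_spikes / small_rec.duration
        assert np.exp(init.log_r0) == pytest.approx(want)


class TestFeasibility:
    def test_nonnegative_weights_feasible(self):
        cov = CovKernelParams([0.5, 0.0, 2.0] + [0.0] * 7, 2.0 ** -np.arange(1, 11))
        assert feasibility(cov, 4096)

    def test_all_zero_infeasible(self):
        cov = CovKernelParams(np.zeros(10), 2.0 ** -np.arange(1, 11))
        assert not feasibility(cov, 64)

    def test_dominant_negative_weight_infeasible(self):
        cov = CovKernelParams([1.0, -5.0], [0.5, 0.25])
        assert not feasibility(cov, 256)


class TestFixedDeltaFit:
    @pytest.fixture(scope="class")
    def fitted(self, truth):
        out = simulate(truth, 30_000, 1.0, seed=29)
        rec = out.recording
        ws = Workspace(rec, 60)
        init = init_params(rec)
        res = fit_fixed_delta(rec, 4.0, init, _quick_opt(compute_se=True), ws=ws)
        return rec, res

    def test_loglik_trace_monotone(self, fitted):
        _, res = fitted
        assert np.all(np.diff(res.loglik_trace) >= -1e-6)

    def test_mle_dominates_truth(self, fitted, truth):
        rec, res = fitted
        assert res.loglik_per_bin * rec.n_bins >= joint_loglik(rec, truth) - 1e-6

    def test_concave_at_optimum(self, fitted):
        _, res = fitted
        assert res.concave_at_optimum
        assert res.converged

    def test_spike_kernel_coverage_when_zero(self):
        """Data simulated with a = 0: the fitted spike kernel is within 2 SE
        of zero for the large majority of its 60 bins."""
        p = AgapeParams(
            u_r=-60.0,
            log_r0=np.log(0.006),
            beta=0.3,
            delta=0.0,
            cov=CovKernelParams([2.0, 1.0], [0.25, 0.03125]),
            spike_kernel=SpikeKernelParams(np.zeros(60)),
            adapt=None,
        )
        out = simulate(p, 50_000, 1.0, seed=31)
        rec = out.recording
        init = init_params(rec, template=p)
        res = fit_fixed_delta(
            rec, 0.0, init, _quick_opt(delta_grid=(0.0,), compute_se=True),
            free=FreeFlags(adapt=False),
        )
        a_hat = res.params.spike_kernel.a
        se = np.array([res.se[f"a_{i + 1}"] for i in range(60)])
        assert np.sum(np.abs(a_hat) <= 2 * se) >= 55


class TestDeltaSweep:
    def test_flat_profile_without_alpha_beta(self, truth):
        """With a = 0, beta = 0 and eta = 0 imposed the likelihood cannot
        depend on delta: the spiking term reduces to a homogeneous Poisson
        model that sees only the (conserved) total count."""
        import agape.kernels as K

        p = copy.deepcopy(truth)
        p.beta = 0.0
        p.spike_kernel = SpikeKernelParams(np.zeros(60))
        p.adapt = K.AdaptKernelParams(
            np.zeros(10), truth.adapt.rise_rates, truth.adapt.decay_rates
        )
        out = simulate(p, 10_000, 1.0, seed=37)
        tr = out.recording.segments[0][0]
        # keep peaks away from the edges so no nominal time is dropped
        pk = out.peak_times.peak_times
        pk = pk[(pk > 10) & (pk < 9990)]
        from agape.data_io import SpikeTimes

        free = FreeFlags(spike_kernel=False, beta=False, adapt=False)
        res = fit(
            (tr, SpikeTimes(pk)),
            _quick_opt(delta_grid=(0.0, 2.0, 5.0), n_restarts=1),
            template=p,
            free=free,
        )
        vals = list(res.delta_profile.values())
        assert max(vals) - min(vals) < 1e-6

    def test_warm_sweep_at_least_as_good_as_single_delta(self, truth):
        out = simulate(truth, 12_000, 1.0, seed=41)
        tr = out.recording.segments[0][0]
        data = (tr, out.peak_times)
        opt = _quick_opt(delta_grid=(2.0, 4.0, 6.0), n_restarts=1, seed=3)
        swept = fit(data, opt)
        single = fit(data, _quick_opt(delta_grid=(4.0,), n_restarts=1, seed=3))
        assert swept.delta_profile[4.0] >= single.delta_profile[4.0] - 1e-9

    def test_profile_max_at_reported_delta(self, truth):
        out = simulate(truth, 12_000, 1.0, seed=43)
        tr = out.recording.segments[0][0]
        res = fit((tr, out.peak_times), _quick_opt(delta_grid=(3.0, 4.0, 5.0)))
        best = max(res.delta_profile, key=lambda d: (res.delta_profile[d], -d))
        assert res.params.delta == best

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            FitOptions(delta_grid=())


class TestConcavityCheck:
    def test_pure_poisson_always_concave(self, small_rec):
        p = AgapeParams(
            u_r=-60.0,
            log_r0=np.log(0.004),
            beta=0.0,
            delta=0.0,
            cov=CovKernelParams([8.0], [0.0625]),
            spike_kernel=SpikeKernelParams(np.zeros(60)),
            adapt=None,
        )
        flag, min_eig = check_concavity(
            small_rec, p, free=FreeFlags(spike_kernel=False, beta=False, adapt=False)
        )
        assert flag and min_eig < 0

    def test_adversarial_point_reported_not_raised(self, truth, small_rec, small_ws):
        q = copy.deepcopy(truth)
        q.spike_kernel = SpikeKernelParams(np.full(60, 40.0))
        q.beta = 1.5
        flag, _ = check_concavity(small_rec, q, small_ws)
        assert flag in (True, False)


class TestRecovery:
    def test_parameter_recovery_within_two_se(self, truth):
        """Fits to 100 s replicates at the true delta recover the generating
        parameters: headline scalars within 2 observed-Fisher SE, and >= 90%
        of all coordinates within 2 SE, in >= 3 of 4 replicates."""
        from agape.likelihood import param_names
        from agape.fitting import _pack

        good = 0
        for seed in (51, 52, 53, 54):
            out = simulate(truth, 100_000, 1.0, seed=seed)
            rec = out.recording
            ws = Workspace(rec, 60)
            init = init_params(rec)
            res = fit_fixed_delta(rec, 4.0, init, _quick_opt(compute_se=True), ws=ws)
            names = param_names(res.params, "all")
            x_hat = _pack(res.params, "all", FreeFlags())
            x_true = _pack(truth, "all", FreeFlags())
            se = np.array([res.se[nm] for nm in names])
            ok = np.abs(x_hat - x_true) <= 2 * se
            headline = [names.index(nm) for nm in ("beta", "log_r0", "u_r")]
            if ok.mean() >= 0.9 and all(ok[i] for i in headline):
                good += 1
        assert good >= 3
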