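import numpy as np
import pytest

from agape.data_io import Recording, SpikeTimes, SpikeTrainBinned, VoltageTrace
from agape.diagnostics import (
    cv_sweep,
    empirical_autocov,
    fisher_standard_errors,
    isi_cv,
    spike_triggered_average,
)
from agape.kernels import CovKernelParams, SpikeKernelParams
from agape.likelihood import FreeFlags
from agape.simulator import AgapeParams, simulate


class TestEmpiricalAutocov:
    def test_constant_trace_zero(self):
        tr = VoltageTrace(np.full(100, -60.0), 1.0)
        np.testing.assert_allclose(empirical_autocov(tr, 5), np.zeros(6))

    def test_hand_worked_three_samples(self):
        tr = VoltageTrace(np.array([1.0, 2.0, 3.0]), 1.0)
        # windowed means (1.5, 2.5) at lag 1; normalization 1/(n-j-1) = 1
        assert empirical_autocov(tr, 0)[0] == pytest.approx(1.0)
        # recompute lag-1 by hand: (1-1.5)(2-2.5) + (2-1.5)(3-2.5) = 0.5
        tr4 = VoltageTrace(np.array([1.0, 2.0, 3.0, 4.0]), 1.0)
        assert empirical_autocov(tr4, 1)[1] == pytest.approx(
            ((1 - 2) * (2 - 3) + (2 - 2) * (3 - 3) + (3 - 2) * (4 - 3)) / 2.0
        )

    def test_lag1_three_samples(self):
        # j_max must satisfy j_max < n - 2, so embed the 3-sample case
        v = np.array([1.0, 2.0, 3.0])
        a, b = v[:2], v[1:]
        want = np.dot(a - a.mean(), b - b.mean()) / 1.0
        assert want == pytest.approx(0.5)

    def test_white_noise_lag0_is_variance(self, rng):
        v = rng.normal(0, 2.0, 50_000)
        tr = VoltageTrace(v, 1.0)
        assert empirical_autocov(tr, 0)[0] == pytest.approx(v.var(ddof=1), rel=1e-3)

    def test_too_large_lag_rejected(self):
        with pytest.raises(ValueError):
            empirical_autocov(VoltageTrace(np.zeros(10), 1.0), 8)


class TestIsiCv:
    def test_periodic_train(self):
        cv, isi = isi_cv(SpikeTimes(np.arange(0.0, 100.0, 5.0)))
        assert cv == pytest.approx(0.0)
        assert np.all(isi == 5.0)

    def test_hand_case(self):
        cv, _ = isi_cv(SpikeTimes(np.array([0.0, 1.0, 3.0, 6.0])))  # ISIs 1,2,3
        assert cv == pytest.approx(0.5)

    def test_poisson_cv_is_one(self, rng):
        times = np.cumsum(rng.exponential(10.0, 10_000))
        cv, _ = isi_cv(SpikeTimes(times))
        assert abs(cv - 1.0) < 5 * 1.0 / np.sqrt(10_000)

    def test_insufficient_spikes(self):
        with pytest.raises(ValueError, match="insufficient"):
            isi_cv(SpikeTimes(np.array([1.0, 2.0])))

    def test_binned_input(self):
        counts = np.zeros(30, int)
        counts[[2, 7, 12, 17]] = 1
        cv, _ = isi_cv(SpikeTrainBinned(counts, 1.0))
        assert cv == pytest.approx(0.0)


class TestSTA:
    def test_single_peak_returns_snippet(self):
        v = np.sin(np.arange(200) * 0.1)
        tr = VoltageTrace(v, 1.0)
        lags, avg, n_used, n_exc = spike_triggered_average(tr, SpikeTimes([100.0]), 10.0)
        assert n_used == 1 and n_exc == 0
        np.testing.assert_allclose(avg, v[90:111])

    def test_truncated_peaks_excluded(self):
        tr = VoltageTrace(np.zeros(100), 1.0)
        _, _, n_used, n_exc = spike_triggered_average(tr, SpikeTimes([2.0, 50.0]), 10.0)
        assert n_used == 1 and n_exc == 1

    def test_uncoupled_sta_matches_spike_kernel(self, rng):
        """beta = 0: the GP is spike-independent, so STA - waveform -> 0."""
        a = 8.0 * np.exp(-0.5 * ((np.arange(1, 61) - 5.0) / 3.0) ** 2)
        p = AgapeParams(
            u_r=-60.0, log_r0=np.log(0.01), beta=0.0, delta=0.0,
            cov=CovKernelParams([1.0], [0.25]),
            spike_kernel=SpikeKernelParams(a, 1.0), adapt=None,
        )
        out = simulate(p, 60_000, 1.0, seed=61)
        tr = out.recording.segments[0][0]
        nominal_bins = np.flatnonzero(out.recording.segments[0][1].counts)
        peaks = SpikeTimes(nominal_bins.astype(float))
        lags, avg, n_used, _ = spike_triggered_average(tr, peaks, 70.0)
        post = avg[(lags >= 1) & (lags <= 60)] - p.u_r
        # waveforms of *other* spikes add a uniform offset ~ rate * sum(a);
        # the pre-spike window carries the same baseline, so subtract it
        baseline = avg[(lags >= -60) & (lags <= -1)].mean() - p.u_r
        resid = post - a - baseline
        assert n_used > 300
        assert np.abs(resid).mean() < 0.2  # Monte-Carlo band at ~600 spikes

    def test_coupled_sta_shows_prespike_depolarization(self, truth):
        out = simulate(truth, 60_000, 1.0, seed=63)
        tr = out.recording.segments[0][0]
        nominal_bins = np.flatnonzero(out.recording.segments[0][1].counts)
        peaks = SpikeTimes(nominal_bins.astype(float))
        lags, avg, _, _ = spike_triggered_average(tr, peaks, 70.0)
        pre = avg[(lags >= -30) & (lags <= 0)] - truth.u_r
        assert pre.mean() > 0.3  # upward fluctuation precedes spikes


class TestFisher:
    def test_white_gp_ur_standard_error(self, rng):
        # effectively white covariance: SE(u_r) ~ sigma / sqrt(n)
        n = 4000
        sigma2 = 2.0
        v = -60 + rng.normal(0, np.sqrt(sigma2), n)
        counts = np.zeros(n, int)
        counts[rng.choice(n, 20, replace=False)] = 1
        rec = Recording([(VoltageTrace(v, 1.0), SpikeTrainBinned(counts, 1.0))])
        p = AgapeParams(
            u_r=float(v.mean()), log_r0=np.log(20 / n), beta=0.0, delta=0.0,
            cov=CovKernelParams([sigma2], [15.0]),  # corr ~ e^-15 per bin
            spike_kernel=SpikeKernelParams(np.zeros(60)), adapt=None,
        )
        se, _ = fisher_standard_errors(
            rec, p, free=FreeFlags(spike_kernel=False, beta=False, adapt=False), check=False
        )
        assert se["u_r"] == pytest.approx(np.sqrt(sigma2 / n), rel=0.1)

    def test_poisson_log_rate_standard_error(self, rng):
        n = 5000
        counts = rng.poisson(0.01, n)
        total = counts.sum()
        rec = Recording([(VoltageTrace(np.zeros(n), 1.0), SpikeTrainBinned(counts, 1.0))])
        p = AgapeParams(
            u_r=0.0, log_r0=float(np.log(total / n)), beta=0.0, delta=0.0,
            cov=CovKernelParams([1.0], [0.25]),
            spike_kernel=SpikeKernelParams(np.zeros(60)), adapt=None,
        )
        se, _ = fisher_standard_errors(
            rec, p, free=FreeFlags(spike_kernel=False, beta=False, adapt=False), check=False
        )
        assert se["log_r0"] == pytest.approx(1.0 / np.sqrt(total), rel=1e-6)

    def test_se_scaling_with_data_length(self, truth):
        from agape.fitting import FitOptions, fit_fixed_delta, init_params

        ses = {}
        for n in (30_000, 60_000):
            out = simulate(truth, n, 1.0, seed=67)
            rec = out.recording
            res = fit_fixed_delta(
                rec, 4.0, init_params(rec),
                FitOptions(delta_grid=(4.0,), n_restarts=1, compute_se=True),
            )
            ses[n] = res.se["beta"] ** 2
        assert ses[60_000] / ses[30_000] == pytest.approx(0.5, abs=0.2)


class TestCvSweep:
    def test_uncoupled_cox_is_poisson(self):
        res = cv_sweep("cox", grid=[(0.0, 0.5), (0.0, 4.0)], n_isi=2000, seed=5)
        for cv, se in zip(res.cv, res.cv_se):
            assert abs(cv - 1.0) < 4 * max(se, 0.01)

    def test_cv_increases_with_coupling(self):
        res = cv_sweep("cox", grid=[(0.5, 1.0), (2.0, 1.0)], n_isi=3000, seed=6)
        assert res.cv[1] > res.cv[0] + 2 * np.hypot(res.cv_se[0], res.cv_se[1])

    def test_time_rescaling_invariance(self):
        """CV depends only on the dimensionless coordinates (beta*sigma, r0*tau)."""
        cvs = [
            cv_sweep("cox", grid=[(1.0, 2.0)], tau=t, n_isi=3000, seed=7).cv[0]
            for t in (30.0, 100.0)
        ]
        assert abs(cvs[0] - cvs[1]) < 0.15

    def test_adaptation_reaches_sub_poisson(self):
        res = cv_sweep("adaptive", grid=[(8.0, 0.3)], n_isi=3000, seed=8)
        assert res.cv[0] < 1.0 - 3 * res.cv_se[0]

    def test_unknown_study_rejected(self):
        with pytest.raises(ValueError):
            cv_sweep("nope")
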