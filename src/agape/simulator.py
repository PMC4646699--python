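"""Generative AGAPE process.

The model composes three layers on a regular grid of width dt:

1. subthreshold potential: u ~ GP(0, k), sampled exactly through the
   circulant spectrum;
2. spiking: per-bin Poisson counts with log-rate
   log r_i = log r0 + beta * u_i + sum_{j>=1} eta_j * s_{i-j}
   (the adaptation convolution is causal with lag >= 1, so simulation and
   likelihood share the same discretization);
3. somatic voltage: u_som,i = u_r + u_i + sum_{j=1}^{J} alpha_j * s_{i-j},
   the stereotyped spike waveform added after each nominal spike.

The nominal (decision) times sit delta ms before the waveform peak; the
simulator reports peak times at nominal-bin centers + delta so that
re-binning peaks at the generating delta recovers the spike train exactly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .circulant_gp import circulant_from_toeplitz, sample_gp
from .data_io import Recording, SpikeTimes, SpikeTrainBinned, VoltageTrace
from .kernels import (
    AdaptKernelParams,
    CovKernelParams,
    ExpAdaptParams,
    SpikeKernelParams,
    eval_spike_kernel,
)

__all__ = ["AgapeParams", "SimOutput", "simulate", "compose_usom", "firing_rate_path"]


@dataclass
class AgapeParams:
    """Full AGAPE parameter set Theta.

    u_r: reference potential (mV); log_r0: log baseline rate (log 1/ms);
    beta: voltage-to-rate coupling (1/mV, >= 0); delta: decision-to-peak
    offset (ms, non-negative multiple of the bin width); cov: GP covariance;
    spike_kernel: stereotyped waveform; adapt: spike-history kernel or None.
    """

    u_r: float
    log_r0: float
    beta: float
    delta: float
    cov: CovKernelParams
    spike_kernel: SpikeKernelParams
    adapt: AdaptKernelParams | ExpAdaptParams | None = None

    def validate(self, dt: float = 1.0) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if abs(self.delta / dt - round(self.delta / dt)) > 1e-9:
            raise ValueError("delta must be a non-negative multiple of dt")

    @property
    def r0(self) -> float:
        """Baseline rate in 1/ms."""
        return float(np.exp(self.log_r0))

    def effective_coupling(self) -> float:
        """beta * sigma with sigma = sqrt(k(0)), the dimensionless coupling."""
        return float(self.beta * np.sqrt(self.cov.variance()))


@dataclass
class SimOutput:
    recording: Recording
    latent_u: VoltageTrace
    rate_path: np.ndarray  # per-bin intensity, 1/ms
    peak_times: SpikeTimes


def adapt_exp_terms(adapt, dt: float):
    """(q, d) such that eta(j*dt) = sum_m q_m d_m^j for j >= 1.

    Alpha shapes contribute a (+w, exp(-nu dt)) and a (-w, exp(-omega dt))
    pair; the exponential kernel a single (-eta0, exp(-dt/tau_r)) term.
    """
    if adapt is None:
        return np.zeros(0), np.zeros(0)
    if isinstance(adapt, AdaptKernelParams):
        q = np.concatenate([adapt.weights, -adapt.weights])
        d = np.exp(-np.concatenate([adapt.rise_rates, adapt.decay_rates]) * dt)
        return q, d
    if isinstance(adapt, ExpAdaptParams):
        return np.array([-adapt.eta0]), np.array([np.exp(-dt / adapt.tau_r)])
    raise TypeError(f"unsupported adaptation parametrization: {type(adapt)!r}")


def _geometric_history(counts: np.ndarray, decay: float) -> np.ndarray:
    """y_i = sum_{j>=1} decay^j * counts[i-j] via the recursion y_i = decay*(y_{i-1}+s_{i-1})."""
    from scipy.signal import lfilter

    return lfilter([0.0, decay], [1.0, -decay], counts.astype(float))


def adaptation_path(counts: np.ndarray, adapt, dt: float) -> np.ndarray:
    """Causal adaptation variable A_i = sum_{j>=1} eta(j dt) * s_{i-j}."""
    q, d = adapt_exp_terms(adapt, dt)
    a = np.zeros(counts.size)
    for qm, dm in zip(q, d):
        a += qm * _geometric_history(counts, dm)
    return a


def firing_rate_path(u, s, p: AgapeParams, dt: float | None = None) -> np.ndarray:
    """Per-bin conditional intensity r_i (1/ms) given voltage u and spike history s."""
    if isinstance(s, SpikeTrainBinned):
        counts = s.counts
        dt = s.dt if dt is None else dt
    else:
        counts = np.asarray(s)
        if dt is None:
            raise ValueError("dt required when s is a plain array")
    u = np.asarray(u, dtype=float)
    if u.size != counts.size:
        raise ValueError("u and s must be aligned")
    ex = p.log_r0 + p.beta * u + adaptation_path(counts, p.adapt, dt)
    if np.any(ex > _engine.MAX_EXPONENT):
        bad = int(np.argmax(ex > _engine.MAX_EXPONENT))
        raise OverflowError(f"firing-rate exponent overflow at bin {bad}")
    return np.exp(ex)


def spike_kernel_lags(sk: SpikeKernelParams, dt: float, n_max: int | None = None) -> np.ndarray:
    """alpha evaluated at lags dt, 2dt, ... (support [dt, (n_bins+1) dt))."""
    n_lags = int(np.ceil((sk.n_bins + 1) * sk.dt / dt)) - 1
    if n_max is not None:
        n_lags = min(n_lags, n_max)
    return eval_spike_kernel(sk, dt * np.arange(1, n_lags + 1))


def compose_usom(u, s, u_r: float, sk: SpikeKernelParams, dt: float | None = None) -> np.ndarray:
    """u_som,i = u_r + u_i + sum_{j>=1} alpha_j s_{i-j} (exact inverse of the
    likelihood's residual operation)."""
    if isinstance(s, SpikeTrainBinned):
        counts, dt = s.counts, (s.dt if dt is None else dt)
    else:
        counts = np.asarray(s)
        if dt is None:
            raise ValueError("dt required when s is a plain array")
    u = np.asarray(u, dtype=float)
    n = u.size
    alpha = spike_kernel_lags(sk, dt, n_max=n - 1)
    kern = np.concatenate([[0.0], alpha])
    return u_r + u + np.convolve(counts.astype(float), kern)[:n]


def simulate(
    p: AgapeParams,
    n: int,
    dt: float = 1.0,
    seed=None,
    oversample: int = 1,
) -> SimOutput:
    """Draw one AGAPE realization of n bins at resolution dt (ms).

    ``oversample`` > 1 simulates the GP and the point process on a finer grid
    dt/oversample and re-bins counts (sum) and the latent voltage (left-edge
    sample) to the requested grid - needed when r * dt is not small.
    Deterministic given ``seed``; the GP and the spikes use independent
    streams spawned from it.
    """
    p.validate(dt)
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    gp_ss, spike_ss = ss.spawn(2)

    dt_f = dt / oversample
    n_f = n * oversample
    lags = dt_f * np.arange(n_f)
    cm = circulant_from_toeplitz(p.cov.k_row(lags), n_f, dt_f)
    u_f = sample_gp(cm, np.random.default_rng(gp_ss))

    q, d = adapt_exp_terms(p.adapt, dt_f)
    uniforms = np.random.default_rng(spike_ss).random(n_f)
    counts_f, rates_f, = _engine.poisson_counts_adaptive(
        p.beta * u_f, p.log_r0, dt_f, q, d, uniforms
    )
    frac_coarse = np.mean(rates_f * dt_f > 0.5)
    if frac_coarse > 0.01:
        warnings.warn(
            f"bin width too coarse: r*dt > 0.5 in {100 * frac_coarse:.1f}% of bins",
            stacklevel=2,
        )

    if oversample > 1:
        counts = counts_f.reshape(n, oversample).sum(axis=1)
        u = u_f[::oversample].copy()
        rate = rates_f.reshape(n, oversample).mean(axis=1)
    else:
        counts, u, rate = counts_f, u_f, rates_f

    spikes = SpikeTrainBinned(counts, dt)
    u_som = compose_usom(u, spikes, p.u_r, p.spike_kernel)
    trace = VoltageTrace(u_som, dt=dt)
    latent = VoltageTrace(u, dt=dt)

    # peak times: fine-bin centers of the nominal spikes, shifted by delta
    fine_idx = np.repeat(np.arange(n_f), counts_f)
    nominal = (fine_idx + 0.5) * dt_f
    nominal += dt_f * 1e-6 * _tie_break(counts_f, fine_idx)
    peaks = SpikeTimes(nominal + p.delta)

    rec = Recording(
        [(trace, spikes)],
        metadata={"source": "agape.simulator", "n": n, "dt_ms": dt, "oversample": oversample},
    )
    return SimOutput(recording=rec, latent_u=latent, rate_path=rate, peak_times=peaks)


def _tie_break(counts: np.ndarray, idx_repeated: np.ndarray) -> np.ndarray:
    """Within-bin ranks 0,1,2,... so multi-spike bins keep times strictly increasing."""
    if idx_repeated.size == 0:
        return np.zeros(0)
    first = np.flatnonzero(np.diff(idx_repeated, prepend=-1))
    group_of = np.repeat(first, np.diff(np.append(first, idx_repeated.size)))
    return np.arange(idx_repeated.size) - group_of


def sample_spike_times(
    p: AgapeParams, n: int, dt: float, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Spike times with exact within-bin placement, plus the latent u.

    Given the per-bin count, spike times inside a bin are iid uniform - exact
    for an intensity that is constant within the bin.  Used by the ISI sweep
    machinery where interval statistics must not inherit the grid.
    """
    if p.beta < 0:
        raise ValueError("beta must be >= 0")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    gp_ss, spike_ss, jitter_ss = ss.spawn(3)
    lags = dt * np.arange(n)
    cm = circulant_from_toeplitz(p.cov.k_row(lags), n, dt)
    u = sample_gp(cm, np.random.default_rng(gp_ss))
    q, d = adapt_exp_terms(p.adapt, dt)
    uniforms = np.random.default_rng(spike_ss).random(n)
    counts, _ = _engine.poisson_counts_adaptive(p.beta * u, p.log_r0, dt, q, d, uniforms)
    idx = np.repeat(np.arange(n), counts)
    jitter = np.random.default_rng(jitter_ss).random(idx.size)
    times = np.sort((idx + jitter) * dt)
    return times, u
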