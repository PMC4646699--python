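"""Canonical parameter sets.

``validation_params`` is the synthetic ground truth used throughout the
validation machinery: baseline rate 4.15 Hz, coupling beta = 0.374 /mV and
decision-to-peak offset delta = 4 ms, with smooth fixture kernels drawn from
the model's own parametric families (a ten-component OU mixture for the
covariance, a biphasic 60-bin spike waveform peaking at the delta lag, and a
mildly suppressing alpha-shape adaptation mixture).  All fixture weights are
interior points of their domains so that maximum-likelihood recovery is a
regular estimation problem.
"""
from __future__ import annotations

import numpy as np

from .data_io import hz_to_per_ms
from .kernels import AdaptKernelParams, CovKernelParams, SpikeKernelParams, default_bases
from .simulator import AgapeParams

__all__ = ["validation_params", "default_param_template"]


def validation_params() -> AgapeParams:
    """Ground-truth AGAPE parameters for synthetic-data validation."""
    cov_t, adapt_t, spike_t = default_bases()
    # OU mixture: substantial fast (ms-scale, synaptic-noise-like) variance on
    # top of slower network fluctuations; k(0) = 8.1 mV^2 (sigma ~ 2.8 mV).
    # The fast components are what make the decision-to-peak offset delta
    # identifiable: misaligning u by one bin must cost spiking likelihood.
    weights = np.array([1.50, 1.50, 1.30, 1.20, 1.00, 0.60, 0.40, 0.30, 0.20, 0.10])
    cov = CovKernelParams(weights, cov_t.rates)

    # spike-related kernel: truncated-AP depolarization peaking 4 ms after the
    # nominal (decision) time, with a shallow after-hyperpolarization
    lags = np.arange(1, spike_t.n_bins + 1, dtype=float)
    a = 11.0 * np.exp(-0.5 * ((lags - 4.0) / 2.2) ** 2) - 3.0 * np.exp(
        -0.5 * ((lags - 13.0) / 6.0) ** 2
    )
    spike = SpikeKernelParams(a, spike_t.dt)

    # adaptation: positive weights on the negative alpha shapes -> suppression
    # of firing over ~10-100 ms after each spike.  Components slower than the
    # typical inter-spike interval are left at zero: over the ISIs actually
    # observed they act as a constant rate shift and are degenerate with r0.
    w = np.array([0.10, 0.25, 0.50, 0.90, 0.70, 0.35, 0.10, 0.0, 0.0, 0.0])
    adapt = AdaptKernelParams(w, adapt_t.rise_rates, adapt_t.decay_rates)

    return AgapeParams(
        u_r=-60.0,
        log_r0=float(np.log(hz_to_per_ms(4.15))),
        beta=0.374,
        delta=4.0,
        cov=cov,
        spike_kernel=spike,
        adapt=adapt,
    )


def default_param_template(dt: float = 1.0) -> AgapeParams:
    """Zero-weight template carrying the default bases (used by ``init_params``)."""
    cov, adapt, spike = default_bases(dt=dt)
    return AgapeParams(
        u_r=0.0,
        log_r0=np.log(1e-3),
        beta=0.0,
        delta=0.0,
        cov=cov,
        spike_kernel=spike,
        adapt=adapt,
    )
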