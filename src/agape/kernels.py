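"""Parametric kernel families of the AGAPE model.

Three kernels enter the model, all evaluated on a millisecond time base:

* the Gaussian-process covariance ``k(t)``, a weighted sum of
  Ornstein-Uhlenbeck (exponential-decay) components,
* the spike-history adaptation kernel ``eta(t)``, either a linear
  combination of alpha shapes (differences of exponentials) or a single
  exponential, acting inside the exponential gain of the firing rate,
* the spike-related voltage kernel ``alpha(t)``, a piecewise-constant
  stereotyped waveform added to the subthreshold potential after each
  nominal spike.

All weights enter linearly, which is what makes the corresponding
likelihood blocks concave (adaptation) or quadratic-friendly (covariance).
Units: times in ms, rates in 1/ms, voltages in mV, covariances in mV^2.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CovKernelParams",
    "SingleOUCov",
    "AdaptKernelParams",
    "ExpAdaptParams",
    "SpikeKernelParams",
    "eval_cov_kernel",
    "eval_adapt_kernel",
    "eval_exp_adapt",
    "eval_spike_kernel",
    "default_bases",
]


def _as_1d(x, name: str) -> np.ndarray:
    a = np.atleast_1d(np.asarray(x, dtype=float))
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


@dataclass
class CovKernelParams:
    """OU-mixture covariance k(t) = sum_i sigma2_i * exp(-theta_i * t).

    ``rates`` (theta_i, 1/ms) are a fixed basis; ``weights`` (sigma2_i, mV^2)
    are the free parameters.  Non-negative weights are sufficient for a valid
    covariance; the weaker spectral feasibility condition is checked where the
    circulant spectrum is actually formed.
    """

    weights: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.weights = _as_1d(self.weights, "weights")
        self.rates = _as_1d(self.rates, "rates")
        if self.weights.shape != self.rates.shape:
            raise ValueError("weights and rates must have the same length")
        if np.any(self.rates <= 0):
            raise ValueError("rates must be strictly positive")

    @property
    def n_free(self) -> int:
        return self.weights.size

    def free_params(self) -> np.ndarray:
        return self.weights.copy()

    def with_free(self, vec) -> "CovKernelParams":
        return CovKernelParams(np.asarray(vec, dtype=float), self.rates)

    def k_row(self, lags: np.ndarray) -> np.ndarray:
        return eval_cov_kernel(self, lags)

    def k_row_jac(self, lags: np.ndarray) -> np.ndarray:
        """d k(t) / d sigma2_j, shape (n_free, len(lags))."""
        return np.exp(-np.outer(self.rates, lags))

    def k_row_hess(self, lags: np.ndarray) -> np.ndarray:
        return np.zeros((self.n_free, self.n_free, lags.size))

    def variance(self) -> float:
        """k(0) = total stationary variance of the GP (mV^2)."""
        return float(self.weights.sum())


@dataclass
class SingleOUCov:
    """Single OU covariance sigma2 * exp(-theta * t) with *both* parameters free.

    Used by the reduced models of the factorial comparison, where the
    time constant is fitted rather than spanned by a fixed basis.
    """

    sigma2: float
    theta: float

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be strictly positive")

    @property
    def n_free(self) -> int:
        return 2

    def free_params(self) -> np.ndarray:
        return np.array([self.sigma2, self.theta])

    def with_free(self, vec) -> "SingleOUCov":
        return SingleOUCov(float(vec[0]), float(vec[1]))

    def k_row(self, lags: np.ndarray) -> np.ndarray:
        lags = _as_1d(lags, "lags")
        if np.any(lags < 0):
            raise ValueError("lags must be non-negative")
        return self.sigma2 * np.exp(-self.theta * lags)

    def k_row_jac(self, lags: np.ndarray) -> np.ndarray:
        e = np.exp(-self.theta * lags)
        return np.stack([e, -self.sigma2 * lags * e])

    def k_row_hess(self, lags: np.ndarray) -> np.ndarray:
        e = np.exp(-self.theta * lags)
        h = np.zeros((2, 2, lags.size))
        h[0, 1] = h[1, 0] = -lags * e
        h[1, 1] = self.sigma2 * lags**2 * e
        return h

    def variance(self) -> float:
        return float(self.sigma2)


@dataclass
class AdaptKernelParams:
    """Adaptation kernel eta(t) = sum_i w_i (exp(-nu_i t) - exp(-omega_i t)), t > 0.

    With the default basis nu_i > omega_i, each alpha shape is negative for
    t > 0, so positive weights suppress firing after a spike.
    """

    weights: np.ndarray
    rise_rates: np.ndarray
    decay_rates: np.ndarray

    def __post_init__(self) -> None:
        self.weights = _as_1d(self.weights, "weights")
        self.rise_rates = _as_1d(self.rise_rates, "rise_rates")
        self.decay_rates = _as_1d(self.decay_rates, "decay_rates")
        if not (self.weights.shape == self.rise_rates.shape == self.decay_rates.shape):
            raise ValueError("weights, rise_rates and decay_rates must match in length")
        if np.any(self.rise_rates <= 0) or np.any(self.decay_rates <= 0):
            raise ValueError("rates must be strictly positive")
        if np.any(self.rise_rates == self.decay_rates):
            raise ValueError("rise and decay rates must differ")


@dataclass
class ExpAdaptParams:
    """Exponential adaptation eta(t) = -eta0 * exp(-t / tau_r), t > 0."""

    eta0: float
    tau_r: float

    def __post_init__(self) -> None:
        if self.eta0 < 0:
            raise ValueError("eta0 must be >= 0")
        if self.tau_r <= 0:
            raise ValueError("tau_r must be strictly positive")


@dataclass
class SpikeKernelParams:
    """Piecewise-constant spike-related kernel: alpha(t) = a_i on [i*dt, (i+1)*dt).

    The support starts one bin *after* the nominal spike time (i = 1, ..., n_bins),
    matching the causal discrete convolution used in the likelihood: the bin that
    contains the spike itself receives no waveform contribution.
    """

    a: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.a = _as_1d(self.a, "a")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_bins(self) -> int:
        return self.a.size


def eval_cov_kernel(p: CovKernelParams, lags) -> np.ndarray:
    """Evaluate k(t) = sum_i sigma2_i exp(-theta_i t) at non-negative lags (ms)."""
    lags = _as_1d(lags, "lags")
    if np.any(lags < 0):
        raise ValueError("lags must be non-negative")
    return np.exp(-np.outer(lags, p.rates)) @ p.weights


def eval_adapt_kernel(p: AdaptKernelParams, times) -> np.ndarray:
    """Evaluate the alpha-shape mixture; zero for t <= 0."""
    t = _as_1d(times, "times")
    pos = t > 0
    out = np.zeros_like(t)
    tp = t[pos]
    out[pos] = (
        np.exp(-np.outer(tp, p.rise_rates)) - np.exp(-np.outer(tp, p.decay_rates))
    ) @ p.weights
    return out


def eval_exp_adapt(p: ExpAdaptParams, times) -> np.ndarray:
    """Evaluate -eta0 * exp(-t/tau_r); zero for t <= 0."""
    t = _as_1d(times, "times")
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = -p.eta0 * np.exp(-t[pos] / p.tau_r)
    return out


def eval_spike_kernel(p: SpikeKernelParams, times) -> np.ndarray:
    """Evaluate the piecewise-constant waveform; zero outside [dt, (n_bins+1)*dt)."""
    t = _as_1d(times, "times")
    idx = np.floor(t / p.dt).astype(int)
    out = np.zeros_like(t)
    inside = (idx >= 1) & (idx <= p.n_bins)
    out[inside] = p.a[idx[inside] - 1]
    return out


def adapt_lag_values(adapt, lags) -> np.ndarray:
    """Adaptation kernel sampled at positive lags, for either parametrization."""
    if adapt is None:
        return np.zeros(np.size(lags))
    if isinstance(adapt, AdaptKernelParams):
        return eval_adapt_kernel(adapt, lags)
    if isinstance(adapt, ExpAdaptParams):
        return eval_exp_adapt(adapt, lags)
    raise TypeError(f"unsupported adaptation parametrization: {type(adapt)!r}")


def default_bases(
    n_cov: int = 10,
    n_adapt: int = 10,
    n_spike_bins: int = 60,
    dt: float = 1.0,
    flip_rates: bool = False,
):
    """Default fixed bases: cov rates theta_i = 2^-i /ms (i = 1..10), adaptation
    alpha shapes with nu_i = 2^-i /ms and omega_i = nu_i / 2, and a 60-bin
    spike-related kernel at 1 ms resolution.

    ``flip_rates`` selects the alternative reading omega_i = 2 * nu_i, which
    flips the sign of every basis function.
    """
    cov_rates = 2.0 ** -np.arange(1, n_cov + 1)
    cov = CovKernelParams(np.zeros(n_cov), cov_rates)
    nu = 2.0 ** -np.arange(1, n_adapt + 1)
    omega = 2.0 * nu if flip_rates else nu / 2.0
    adapt = AdaptKernelParams(np.zeros(n_adapt), nu, omega)
    spike = SpikeKernelParams(np.zeros(n_spike_bins), dt)
    return cov, adapt, spike
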