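"""Fast stationary-GP engine via the KL-optimal circulant approximation.

A stationary GP observed on a regular grid has a Toeplitz covariance K with
first row k_1..k_n.  Replacing K by the circulant matrix C that minimizes
D_KL(N(0,K) || N(0,C)) makes the log-density and exact sampling O(n log n):
circulants are diagonalized by the DFT, so the eigenvalues of C are the DFT
of its first row.

DFT convention used throughout: the unnormalized forward transform
u_hat_m = sum_j u_j exp(-2*pi*i*j*m/n) (numpy.fft.fft).  With a symmetric
first row c this gives det C = prod(c_hat) and
u^T C^-1 u = (1/n) * sum |u_hat|^2 / c_hat, so the log-density is

    log N(u | 0, C) = -1/2 * sum_i [ log(2*pi*c_hat_i) + |u_hat_i|^2 / (n*c_hat_i) ].

The convention is validated against a dense multivariate-normal oracle in the
test suite; any convention passing that oracle is equivalent.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CirculantModel",
    "SpectrumError",
    "circulant_from_toeplitz",
    "gp_logpdf",
    "sample_gp",
    "basis_spectra",
]

#: relative floor below which a spectrum is treated as infeasible (rejected,
#: never clipped: silent clipping corrupts gradients).
SPECTRUM_FLOOR = 1e-12


class SpectrumError(ValueError):
    """Raised when a circulant spectrum is non-positive (infeasible covariance)."""


@dataclass
class CirculantModel:
    """First row ``c`` and spectrum ``c_hat`` (eigenvalues) of a circulant covariance."""

    c: np.ndarray
    c_hat: np.ndarray
    n: int
    dt: float = 1.0

    def check_spectrum(self) -> None:
        if np.min(self.c_hat) <= SPECTRUM_FLOOR * np.max(np.abs(self.c_hat)):
            raise SpectrumError("non-positive spectrum: circulant covariance infeasible")


def circulant_row(k_row: np.ndarray) -> np.ndarray:
    """First row of the KL-optimal circulant for Toeplitz first row ``k_row``.

    In 1-based terms c_i = [(n-i+1) k_i + (i-1) k_{n-i+2}] / n with k_{n+1} = 0:
    each circulant diagonal averages the two Toeplitz diagonals it wraps
    together, weighted by how many matrix entries each contributes.
    """
    k = np.asarray(k_row, dtype=float)
    n = k.size
    if n == 0:
        raise ValueError("k_row must have length >= 1")
    i = np.arange(n)
    c = (n - i) * k
    c[1:] += i[1:] * k[::-1][: n - 1]
    return c / n


def circulant_from_toeplitz(k_row, n: int | None = None, dt: float = 1.0) -> CirculantModel:
    """Build the KL-optimal circulant model from Toeplitz covariance row ``k_row``."""
    k = np.asarray(k_row, dtype=float)
    if n is None:
        n = k.size
    if n == 0:
        raise ValueError("n must be >= 1")
    if k.size != n:
        raise ValueError("k_row must have length n")
    c = circulant_row(k)
    c_hat = np.fft.fft(c)
    scale = np.max(np.abs(c_hat)) or 1.0
    if np.max(np.abs(c_hat.imag)) > 1e-10 * scale:
        raise ValueError("spectrum has a non-negligible imaginary part")
    return CirculantModel(c=c, c_hat=c_hat.real, n=n, dt=dt)


_LOG_2PI = np.log(2.0 * np.pi)


def gp_logpdf(u, cm: CirculantModel) -> float:
    """Zero-mean Gaussian log-density of ``u`` under the circulant covariance (nats)."""
    u = np.asarray(u, dtype=float)
    if u.size != cm.n:
        raise ValueError(f"u has length {u.size}, expected {cm.n}")
    cm.check_spectrum()
    u_hat = np.fft.fft(u)
    power = np.abs(u_hat) ** 2
    return float(
        -0.5 * (np.sum(np.log(cm.c_hat)) + cm.n * _LOG_2PI + np.sum(power / cm.c_hat) / cm.n)
    )


def sample_gp(cm: CirculantModel, seed=None) -> np.ndarray:
    """Draw one exact sample of the circulant GP (length n, mV).

    Filters white noise in the Fourier domain: u = ifft(sqrt(c_hat) * fft(g))
    with g ~ N(0, I).  The result is real (the filter is symmetric) and has
    covariance exactly C = F^H diag(c_hat) F / n.
    """
    cm.check_spectrum()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = rng.standard_normal(cm.n)
    u = np.fft.ifft(np.sqrt(cm.c_hat) * np.fft.fft(g))
    return np.ascontiguousarray(u.real)


def basis_spectra(rates, n: int, dt: float = 1.0) -> np.ndarray:
    """Spectra of the unit-weight OU basis circulants, shape (len(rates), n).

    The spectrum of a weighted OU mixture is the same weighted combination of
    these rows (the circulant construction and the DFT are linear in k), which
    is what turns spectral positivity into linear constraints on the weights.
    """
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(rates <= 0):
        raise ValueError("rates must be strictly positive")
    lags = np.arange(n) * dt
    out = np.empty((rates.size, n))
    for j, th in enumerate(rates):
        row = circulant_row(np.exp(-th * lags))
        out[j] = np.fft.fft(row).real
    return out


def rows_to_spectra(rows: np.ndarray) -> np.ndarray:
    """DFT (real part) of one or more circulant first rows."""
    return np.fft.fft(np.atleast_2d(rows), axis=-1).real
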