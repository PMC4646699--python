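"""Joint log-likelihood of the AGAPE model, with analytic derivatives.

The joint density factorizes exactly (the composition of the somatic voltage
is deterministic given the latent GP and the spikes):

    L = log p_GP(u*) + log p(s | u*)

where u*_i = u_som,i - u_r - sum_{j>=1} alpha_j s_{i-j} is the residual after
removing the reference potential and the spike-related waveform, the GP term
is the circulant Gaussian log-density of u*, and the spiking term is a
per-bin Poisson likelihood with log-rate log r0 + beta u*_i + (eta * s)_i.
Segments of a recording are independent: every convolution is truncated at
segment boundaries and each segment gets its own circulant approximation.

The spike-related kernel appears in *both* terms - removing more waveform
makes u* more Gaussian but also removes the depolarization that explains the
spikes - which is exactly why the full problem is non-concave while the
spiking block (log r0, beta, w) alone is a concave Poisson GLM.

Analytic gradients and Hessians are assembled blockwise; every formula here
is checked against central finite differences in the test suite, and the
Gram-matrix shortcuts against dense linear algebra.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .circulant_gp import (
    SPECTRUM_FLOOR,
    SpectrumError,
    circulant_from_toeplitz,
    circulant_row,
    gp_logpdf,
)
from .data_io import Recording
from .kernels import AdaptKernelParams, ExpAdaptParams, SpikeKernelParams
from .simulator import AgapeParams, adaptation_path, spike_kernel_lags, _geometric_history

__all__ = [
    "residual_subthreshold",
    "loglik_gp_term",
    "loglik_spike_term",
    "joint_loglik",
    "grad_hess",
    "Workspace",
    "FreeFlags",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class FreeFlags:
    """Which parameter groups are free (used by restricted models)."""

    spike_kernel: bool = True
    beta: bool = True
    adapt: bool = True


# ---------------------------------------------------------------------------
# per-segment cached structures


class _Segment:
    def __init__(self, trace, spikes, n_spike_lags: int):
        self.y = trace.values
        self.s = spikes.counts.astype(float)
        self.n = trace.n
        self.dt = trace.dt
        self.J = n_spike_lags
        idx = np.flatnonzero(spikes.counts)
        self.spike_idx = idx
        self.spike_wts = spikes.counts[idx].astype(float)
        # gather positions for M^T products: pos[p, j-1] = spike_p + j
        self.pos = idx[:, None] + np.arange(1, self.J + 1)
        self.valid = self.pos < self.n
        self.pos_c = np.minimum(self.pos, self.n - 1)
        self.mt_one = (self.valid * self.spike_wts[:, None]).sum(axis=0)
        self.s_hat = np.fft.fft(self.s)
        self.s_pow = np.abs(self.s_hat) ** 2
        # spikes within J bins of the segment end (boundary corrections)
        self.end_idx = idx[idx >= self.n - self.J]
        self.end_wts = spikes.counts[self.end_idx].astype(float)
        self._spectra_cache: dict = {}
        self._adapt_cache: dict = {}

    # -- design matrices -------------------------------------------------
    def mt_dot(self, x: np.ndarray) -> np.ndarray:
        """M^T x with M_{ij} = s_{i-j}: (M^T x)_j = sum_p w_p x[p + j]."""
        if self.spike_idx.size == 0:
            return np.zeros(self.J)
        vals = np.where(self.valid, x[self.pos_c], 0.0)
        return self.spike_wts @ vals

    def m_dot(self, a_lags: np.ndarray) -> np.ndarray:
        """M a = causal convolution of the spike train with kernel values at lags >= 1."""
        kern = np.concatenate([[0.0], a_lags])
        return np.convolve(self.s, kern)[: self.n]

    def mt_diag_m(self, mu: np.ndarray) -> np.ndarray:
        """M^T diag(mu) M, exploiting that M's columns are shifts of the spike train."""
        if self.spike_idx.size == 0:
            return np.zeros((self.J, self.J))
        a = np.where(self.valid, mu[self.pos_c] * self.spike_wts[:, None], 0.0)
        rel = self.pos[:, :, None] - np.arange(1, self.J + 1)[None, None, :]
        ok = (rel >= 0) & self.valid[:, :, None]
        svals = np.where(ok, self.s[np.clip(rel, 0, self.n - 1)], 0.0)
        return np.einsum("pj,pjk->jk", a, svals)

    def mt_cinv_m(self, c_hat: np.ndarray) -> np.ndarray:
        """M^T C^-1 M through the circulant structure (3 FFTs + boundary terms).

        Columns of M are *truncated* shifts of s; writing them as circular
        shifts minus the wrapped tail reduces the Gram matrix to a circular
        correlation plus corrections involving only spikes within J bins of
        the segment end.  Validated against dense linear algebra in tests.
        """
        n, J = self.n, self.J
        t_row = np.fft.fft(self.s_pow / c_hat).real / n
        x = np.fft.ifft(self.s_hat / c_hat).real
        rho = np.fft.ifft(1.0 / c_hat).real
        jk = np.arange(1, J + 1)
        diff = (jk[None, :] - jk[:, None]) % n  # (k - j) mod n
        g = t_row[diff]
        if self.end_idx.size:
            p = self.end_idx
            w = self.end_wts
            # term2_{jk} = sum_{p >= n-j} w_p x[(p + j - k) mod n]
            for jj in range(1, J + 1):
                sel = p >= n - jj
                if not np.any(sel):
                    continue
                contrib = w[sel] @ x[(p[sel, None] + jj - jk[None, :]) % n]
                g[jj - 1, :] -= contrib  # term2
                g[:, jj - 1] -= contrib  # term3 (symmetric)
            # term4: pairs of end spikes
            for jj in range(1, J + 1):
                sel_p = p >= n - jj
                if not np.any(sel_p):
                    continue
                for kk in range(1, J + 1):
                    sel_q = p >= n - kk
                    if not np.any(sel_q):
                        continue
                    dd = (p[sel_p, None] + jj - p[None, sel_q] - kk) % n
                    g[jj - 1, kk - 1] += w[sel_p] @ rho[dd] @ w[sel_q]
        return g

    # -- adaptation design ------------------------------------------------
    def adapt_design(self, adapt: AdaptKernelParams) -> np.ndarray:
        """B with B_{im} = (basis_m * s)_i, the causal alpha-shape histories."""
        key = (adapt.rise_rates.tobytes(), adapt.decay_rates.tobytes())
        if key not in self._adapt_cache:
            cols = []
            for nu, om in zip(adapt.rise_rates, adapt.decay_rates):
                cols.append(
                    _geometric_history(self.s, np.exp(-nu * self.dt))
                    - _geometric_history(self.s, np.exp(-om * self.dt))
                )
            self._adapt_cache[key] = np.column_stack(cols) if cols else np.zeros((self.n, 0))
        return self._adapt_cache[key]

    # -- covariance spectra -----------------------------------------------
    def cov_spectra(self, cov):
        """(c_hat, D, E): model spectrum, its Jacobian and Hessian w.r.t. the
        covariance's free parameters.  For the fixed-rate OU mixture the
        Jacobian rows are the cached basis spectra and E is zero."""
        lags = self.dt * np.arange(self.n)
        from .kernels import CovKernelParams

        if isinstance(cov, CovKernelParams):
            key = cov.rates.tobytes()
            if key not in self._spectra_cache:
                rows = np.stack([circulant_row(r) for r in cov.k_row_jac(lags)])
                self._spectra_cache[key] = np.fft.fft(rows, axis=-1).real
            d = self._spectra_cache[key]
            c_hat = cov.weights @ d
            e = None
        else:
            d = np.fft.fft(
                np.stack([circulant_row(r) for r in cov.k_row_jac(lags)]), axis=-1
            ).real
            c_hat = np.fft.fft(circulant_row(cov.k_row(lags))).real
            hrows = cov.k_row_hess(lags)
            nf = hrows.shape[0]
            e = np.zeros((nf, nf, self.n))
            for j in range(nf):
                for l in range(j, nf):
                    if np.any(hrows[j, l]):
                        e[j, l] = e[l, j] = np.fft.fft(circulant_row(hrows[j, l])).real
        if np.min(c_hat) <= SPECTRUM_FLOOR * np.max(np.abs(c_hat)):
            raise SpectrumError("non-positive spectrum: covariance weights infeasible")
        return c_hat, d, e


class Workspace:
    """Caches per-segment designs that depend only on the data and the fixed
    bases (spike-train shifts, adaptation histories, basis spectra)."""

    def __init__(self, rec: Recording, n_spike_lags: int = 60):
        self.rec = rec
        self.segments = [_Segment(tr, sp, n_spike_lags) for tr, sp in rec.segments]
        self.n_total = rec.n_bins


def _get_ws(rec, ws, sk: SpikeKernelParams | None = None):
    if ws is not None:
        return ws
    n_lags = sk.n_bins if sk is not None else 60
    return Workspace(rec, n_lags)


# ---------------------------------------------------------------------------
# likelihood terms


def residual_subthreshold(rec: Recording, u_r: float, sk: SpikeKernelParams):
    """Per-segment residuals u*_i = u_som,i - u_r - sum_{j>=1} alpha_j s_{i-j}."""
    out = []
    for tr, sp in rec.segments:
        alpha = spike_kernel_lags(sk, tr.dt, n_max=tr.n - 1)
        kern = np.concatenate([[0.0], alpha])
        out.append(tr.values - u_r - np.convolve(sp.counts.astype(float), kern)[: tr.n])
    return out


def loglik_gp_term(residuals, cov, dt: float = 1.0) -> float:
    """Sum over segments of the circulant GP log-density of the residuals."""
    total = 0.0
    for v in residuals:
        cm = circulant_from_toeplitz(cov.k_row(dt * np.arange(v.size)), v.size, dt)
        total += gp_logpdf(v, cm)
    return float(total)


def loglik_spike_term(residuals, rec: Recording, log_r0: float, beta: float, adapt) -> float:
    """Binned Poisson spiking log-likelihood given the residual voltage.

    Always includes the log(s!) term so per-bin scores remain proper
    log-probabilities with multi-spike bins.  Returns -inf (not an exception)
    if a bin with spikes has zero rate.
    """
    total = 0.0
    for v, (tr, sp) in zip(residuals, rec.segments):
        dt = tr.dt
        s = sp.counts
        log_mu = log_r0 + beta * v + adaptation_path(s, adapt, dt) + np.log(dt)
        if np.any(log_mu > 700.0):
            bad = int(np.argmax(log_mu > 700.0))
            raise OverflowError(f"firing-rate exponent overflow at bin {bad}")
        mu = np.exp(log_mu)
        if np.any((s > 0) & (mu == 0.0)):
            return float("-inf")
        total += float(s @ log_mu - mu.sum() - gammaln(s + 1.0).sum())
    return total


def joint_loglik(rec: Recording, p: AgapeParams, per_bin: bool = False) -> float:
    """L = GP term + spiking term on the shared residual u* (nats)."""
    res = residual_subthreshold(rec, p.u_r, p.spike_kernel)
    total = loglik_gp_term(res, p.cov, rec.dt) + loglik_spike_term(
        res, rec, p.log_r0, p.beta, p.adapt
    )
    return total / rec.n_bins if per_bin else total


# fast path used by the optimizer: same value as joint_loglik, cached designs
def joint_loglik_ws(ws: Workspace, p: AgapeParams, free: FreeFlags | None = None) -> float:
    total = 0.0
    for seg in ws.segments:
        alpha = spike_kernel_lags(p.spike_kernel, seg.dt, n_max=seg.n - 1)
        v = seg.y - p.u_r - seg.m_dot(alpha)
        c_hat, _, _ = seg.cov_spectra(p.cov)
        v_hat = np.fft.fft(v)
        total += -0.5 * (
            np.sum(np.log(c_hat)) + seg.n * _LOG_2PI + np.sum(np.abs(v_hat) ** 2 / c_hat) / seg.n
        )
        if isinstance(p.adapt, AdaptKernelParams):
            a_path = seg.adapt_design(p.adapt) @ p.adapt.weights
        else:
            a_path = adaptation_path(seg.s, p.adapt, seg.dt)
        log_mu = p.log_r0 + p.beta * v + a_path + np.log(seg.dt)
        if np.any(log_mu > 700.0):
            raise OverflowError("firing-rate exponent overflow")
        total += float(seg.s @ log_mu - np.exp(log_mu).sum() - gammaln(seg.s + 1.0).sum())
    return float(total)


# ---------------------------------------------------------------------------
# analytic derivatives


def param_names(p: AgapeParams, block: str = "all", free: FreeFlags = FreeFlags()):
    """Flat coordinate names for the requested block, in packing order."""
    from .kernels import CovKernelParams

    gp = ["u_r"] + (
        [f"sigma2_{i + 1}" for i in range(p.cov.n_free)]
        if isinstance(p.cov, CovKernelParams)
        else ["sigma2", "theta"]
    )
    sk = [f"a_{i + 1}" for i in range(p.spike_kernel.n_bins)] if free.spike_kernel else []
    spiking = ["log_r0"]
    if free.beta:
        spiking.append("beta")
    if free.adapt and isinstance(p.adapt, AdaptKernelParams):
        spiking += [f"w_{i + 1}" for i in range(p.adapt.weights.size)]
    return {"gp": gp, "spike_kernel": sk, "spiking": spiking, "all": gp + sk + spiking}[block]


def grad_hess(
    rec: Recording,
    p: AgapeParams,
    block: str = "all",
    ws: Workspace | None = None,
    free: FreeFlags = FreeFlags(),
):
    """Analytic gradient and Hessian of the joint log-likelihood.

    ``block`` selects the coordinates: 'gp' = (u_r, covariance parameters),
    'spike_kernel' = a, 'spiking' = (log r0 [, beta] [, w]), or 'all'.
    Returns (gradient, Hessian) on those coordinates, Hessian symmetric.
    """
    if block not in ("gp", "spike_kernel", "spiking", "all"):
        raise ValueError(f"unknown block {block!r}")
    if free.adapt and p.adapt is not None and not isinstance(p.adapt, AdaptKernelParams):
        raise TypeError("analytic derivatives require the alpha-shape adaptation basis")
    ws = _get_ws(rec, ws, p.spike_kernel)

    names = param_names(p, block, free)
    npar = len(names)
    g = np.zeros(npar)
    h = np.zeros((npar, npar))

    n_c = p.cov.n_free
    want_gp = block in ("gp", "all")
    want_a = free.spike_kernel and block in ("spike_kernel", "all")
    want_sp = block in ("spiking", "all")
    # index slices within the flat vector
    i_ur = 0 if want_gp else None
    sl_rho = slice(1, 1 + n_c) if want_gp else None
    ofs = (1 + n_c) if want_gp else 0
    jn = p.spike_kernel.n_bins
    sl_a = slice(ofs, ofs + jn) if want_a else None
    ofs2 = ofs + (jn if want_a else 0)
    i_r0 = ofs2 if want_sp else None
    i_b = (ofs2 + 1) if (want_sp and free.beta) else None
    n_w = p.adapt.weights.size if (free.adapt and isinstance(p.adapt, AdaptKernelParams)) else 0
    sl_w = slice(ofs2 + 1 + int(free.beta), npar) if (want_sp and n_w) else None

    beta = p.beta
    for seg in ws.segments:
        n, dt = seg.n, seg.dt
        alpha = spike_kernel_lags(p.spike_kernel, dt, n_max=n - 1)
        v = seg.y - p.u_r - seg.m_dot(alpha)
        c_hat, d_rows, e_rows = seg.cov_spectra(p.cov)
        v_hat = np.fft.fft(v)
        power = np.abs(v_hat) ** 2

        b_mat = (
            seg.adapt_design(p.adapt)
            if isinstance(p.adapt, AdaptKernelParams)
            else np.zeros((n, 0))
        )
        w_vec = p.adapt.weights if isinstance(p.adapt, AdaptKernelParams) else np.zeros(0)
        log_mu = p.log_r0 + beta * v + (b_mat @ w_vec if b_mat.size else 0.0) + np.log(dt)
        if np.any(log_mu > 700.0):
            raise OverflowError("firing-rate exponent overflow")
        mu = np.exp(log_mu)
        s = seg.s
        resid = s - mu

        cinv_v = np.fft.ifft(v_hat / c_hat).real  # C^-1 u*

        if want_gp:
            g[i_ur] += v_hat[0].real / c_hat[0] - beta * resid.sum()
            g[sl_rho] += -0.5 * (d_rows @ (1.0 / c_hat) - (d_rows @ (power / c_hat**2)) / n)
            h[i_ur, i_ur] += -n / c_hat[0] - beta**2 * mu.sum()
            h[i_ur, sl_rho] += -v_hat[0].real * d_rows[:, 0] / c_hat[0] ** 2
            hrr = -0.5 * (
                np.einsum("ji,li->jl", d_rows, d_rows * (-1.0 / c_hat**2 + 2.0 * power / (n * c_hat**3)))
            )
            if e_rows is not None:
                hrr += -0.5 * np.einsum("jli,i->jl", e_rows, 1.0 / c_hat - power / (n * c_hat**2))
            h[sl_rho, sl_rho] += hrr

        if want_a:
            g[sl_a] += -seg.mt_dot(-cinv_v + beta * resid)
            h[sl_a, sl_a] += -seg.mt_cinv_m(c_hat) - beta**2 * seg.mt_diag_m(mu)
            if want_gp:
                h[i_ur, sl_a] += -seg.mt_one / c_hat[0] - beta**2 * seg.mt_dot(mu)
                for j in range(n_c):
                    x_j = np.fft.ifft(v_hat * d_rows[j] / c_hat**2).real
                    h[1 + j, sl_a] += -seg.mt_dot(x_j)

        if want_sp:
            g[i_r0] += resid.sum()
            h[i_r0, i_r0] += -mu.sum()
            if free.beta:
                g[i_b] += resid @ v
                h[i_r0, i_b] += -(mu @ v)
                h[i_b, i_b] += -(mu @ v**2)
            if n_w:
                g[sl_w] += b_mat.T @ resid
                h[i_r0, sl_w] += -(b_mat.T @ mu)
                if free.beta:
                    h[i_b, sl_w] += -(b_mat.T @ (mu * v))
                h[sl_w, sl_w] += -(b_mat.T @ (b_mat * mu[:, None]))
            if want_gp:
                h[i_ur, i_r0] += beta * mu.sum()
                if free.beta:
                    h[i_ur, i_b] += -resid.sum() + beta * (mu @ v)
                if n_w:
                    h[i_ur, sl_w] += beta * (b_mat.T @ mu)
            if want_a:
                h[sl_a, i_r0] += beta * seg.mt_dot(mu)
                if free.beta:
                    h[sl_a, i_b] += -seg.mt_dot(resid) + beta * seg.mt_dot(mu * v)
                if n_w:
                    for m in range(n_w):
                        h[sl_a, sl_w][:, m] += beta * seg.mt_dot(mu * b_mat[:, m])

    # symmetrize (we filled the upper-right cross blocks only)
    h = np.triu(h) + np.triu(h, 1).T
    return g, h
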