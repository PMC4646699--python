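"""Maximum-likelihood estimation by alternating block optimization.

The full likelihood is non-concave (the spike-related kernel trades off
between the GP and spiking terms), but splits into three subspaces:

1. GP block (u_r, covariance weights): non-concave -> preconditioned
   projected gradient ascent with backtracking, rejecting spectrally
   infeasible steps;
2. spike-kernel block (a): concave (spiking part analytically, GP part by
   numerical inspection) -> damped Newton;
3. spiking block (log r0, beta, w): a Poisson GLM with exponential gain ->
   concave, damped Newton.

The cycle repeats until the full-space Hessian is negative definite, after
which a full-space (projected, active-set) Newton phase runs to convergence.
Every accepted step increases the log-likelihood.

The decision-to-peak offset delta is discrete: ``fit`` re-bins the nominal
spikes for each candidate delta and sweeps the grid up and then down,
warm-starting each delta from its neighbour and keeping per delta the best
of the warm-started and fresh-initialized runs.
"""
from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .circulant_gp import SpectrumError, basis_spectra
from .data_io import Recording, SpikeTimes, VoltageTrace
from .kernels import AdaptKernelParams, CovKernelParams, SingleOUCov, SpikeKernelParams
from .likelihood import FreeFlags, Workspace, grad_hess, joint_loglik_ws, param_names
from .preprocessing import nominal_spike_bins
from .simulator import AgapeParams

__all__ = [
    "FitOptions",
    "FitResult",
    "init_params",
    "fit_fixed_delta",
    "fit",
    "check_concavity",
    "feasibility",
]


@dataclass
class FitOptions:
    delta_grid: tuple = (0.0,)
    n_restarts: int = 5
    max_cycles: int = 100
    tol_per_bin: float = 1e-8
    seed: int = 0
    restart_scale: float = 0.3
    gp_inner_iters: int = 8
    newton_inner_iters: int = 4
    max_full_iters: int = 40
    compute_se: bool = True

    def __post_init__(self) -> None:
        if self.tol_per_bin <= 0:
            raise ValueError("tol_per_bin must be positive")
        if len(self.delta_grid) == 0:
            raise ValueError("delta grid must not be empty")
        if any(d < 0 for d in self.delta_grid):
            raise ValueError("delta values must be non-negative")


@dataclass
class FitResult:
    params: AgapeParams
    loglik_per_bin: float
    delta_profile: dict
    se: dict
    converged: bool
    concave_at_optimum: bool
    n_cycles: int
    effective_coupling: float
    loglik_trace: list = field(default_factory=list)
    se_flags: dict = field(default_factory=dict)

    @property
    def r0_hz(self) -> float:
        return float(np.exp(self.params.log_r0) * 1e3)


# ---------------------------------------------------------------------------
# initialization


def init_params(
    rec: Recording,
    template: AgapeParams | None = None,
    j_max: int | None = None,
) -> AgapeParams:
    """Moment-based starting point: u_r from the mean trace, covariance
    weights from a non-negative least-squares fit of the OU mixture to the
    empirical autocovariance, kernels at zero, r0 from the mean rate."""
    from .diagnostics import empirical_autocov
    from .presets import default_param_template

    p = copy.deepcopy(template) if template is not None else default_param_template()
    dt = rec.dt
    u_r = float(np.mean(np.concatenate([tr.values for tr, _ in rec.segments])))

    tr_long = max((tr for tr, _ in rec.segments), key=lambda t: t.n)
    if j_max is None:
        j_max = int(min(tr_long.n // 4, 1024))
    k_emp = empirical_autocov(tr_long, j_max)
    lags = dt * np.arange(j_max + 1)

    if isinstance(p.cov, CovKernelParams):
        design = np.exp(-np.outer(lags, p.cov.rates))
        w, _ = nnls(design, k_emp)
        if not np.any(w > 0):
            w = np.zeros_like(w)
            w[0] = max(float(np.var(tr_long.values)), 1e-6)
        cov = CovKernelParams(w, p.cov.rates)
    else:
        sigma2 = max(float(k_emp[0]), 1e-6)
        below = np.flatnonzero(k_emp < sigma2 / np.e)
        tau = lags[below[0]] if below.size and below[0] > 0 else 10.0 * dt
        cov = SingleOUCov(sigma2, 1.0 / max(tau, dt))

    total_spikes = rec.n_spikes
    total_time = rec.n_bins * dt
    if total_spikes == 0:
        warnings.warn("recording has no spikes; r0 initialized at 0.5/T", stacklevel=2)
        log_r0 = float(np.log(0.5 / total_time))
    else:
        log_r0 = float(np.log(total_spikes / total_time))

    adapt = None
    if isinstance(p.adapt, AdaptKernelParams):
        adapt = AdaptKernelParams(
            np.zeros_like(p.adapt.weights), p.adapt.rise_rates, p.adapt.decay_rates
        )
    return AgapeParams(
        u_r=u_r,
        log_r0=log_r0,
        beta=0.0,
        delta=p.delta,
        cov=cov,
        spike_kernel=SpikeKernelParams(np.zeros(p.spike_kernel.n_bins), p.spike_kernel.dt),
        adapt=adapt,
    )


def feasibility(cov, n: int, dt: float = 1.0) -> bool:
    """Spectral feasibility of the covariance at segment length n (all
    circulant eigenvalues strictly positive)."""
    if isinstance(cov, CovKernelParams):
        spectra = basis_spectra(cov.rates, n, dt)
        c_hat = cov.weights @ spectra
    else:
        from .circulant_gp import circulant_from_toeplitz

        try:
            cm = circulant_from_toeplitz(cov.k_row(dt * np.arange(n)), n, dt)
        except ValueError:
            return False
        c_hat = cm.c_hat
    return bool(np.min(c_hat) > 0)


# ---------------------------------------------------------------------------
# parameter packing


def _pack(p: AgapeParams, block: str, free: FreeFlags) -> np.ndarray:
    parts = []
    if block in ("gp", "all"):
        parts.append([p.u_r])
        parts.append(p.cov.free_params())
    if free.spike_kernel and block in ("spike_kernel", "all"):
        parts.append(p.spike_kernel.a)
    if block in ("spiking", "all"):
        parts.append([p.log_r0])
        if free.beta:
            parts.append([p.beta])
        if free.adapt and isinstance(p.adapt, AdaptKernelParams):
            parts.append(p.adapt.weights)
    return np.concatenate([np.asarray(x, dtype=float) for x in parts])


def _unpack(x: np.ndarray, p: AgapeParams, block: str, free: FreeFlags) -> AgapeParams:
    q = copy.copy(p)
    i = 0
    if block in ("gp", "all"):
        q.u_r = float(x[i])
        i += 1
        q.cov = p.cov.with_free(x[i : i + p.cov.n_free])
        i += p.cov.n_free
    if free.spike_kernel and block in ("spike_kernel", "all"):
        nb = p.spike_kernel.n_bins
        q.spike_kernel = SpikeKernelParams(x[i : i + nb].copy(), p.spike_kernel.dt)
        i += nb
    if block in ("spiking", "all"):
        q.log_r0 = float(x[i])
        i += 1
        if free.beta:
            q.beta = float(x[i])
            i += 1
        if free.adapt and isinstance(p.adapt, AdaptKernelParams):
            nw = p.adapt.weights.size
            q.adapt = AdaptKernelParams(
                x[i : i + nw].copy(), p.adapt.rise_rates, p.adapt.decay_rates
            )
            i += nw
    return q


def _project(x: np.ndarray, p: AgapeParams, block: str, free: FreeFlags) -> np.ndarray:
    """Clamp constrained coordinates: sigma2 >= 0 (OU mixture), sigma2 > 0 and
    theta > 0 (single OU), beta >= 0."""
    x = x.copy()
    i = 0
    if block in ("gp", "all"):
        i += 1
        if isinstance(p.cov, CovKernelParams):
            x[i : i + p.cov.n_free] = np.maximum(x[i : i + p.cov.n_free], 0.0)
        else:
            x[i] = max(x[i], 1e-10)
            x[i + 1] = max(x[i + 1], 1e-8)
        i += p.cov.n_free
    if free.spike_kernel and block in ("spike_kernel", "all"):
        i += p.spike_kernel.n_bins
    if block in ("spiking", "all"):
        i += 1
        if free.beta:
            x[i] = max(x[i], 0.0)
    return x


def _try_loglik(ws: Workspace, p: AgapeParams):
    try:
        return joint_loglik_ws(ws, p)
    except (SpectrumError, OverflowError):
        return -np.inf


# ---------------------------------------------------------------------------
# block steps


def _backtrack(ws, p, block, free, x0, direction, ll0):
    """Largest step along ``direction`` (halving) that improves the loglik;
    infeasible candidates (negative spectrum, rate overflow) are rejected the
    same way as non-improving ones."""
    t = 1.0
    for _ in range(40):
        x = _project(x0 + t * direction, p, block, free)
        q = _unpack(x, p, block, free)
        ll = _try_loglik(ws, q)
        if ll > ll0:
            return q, ll, True
        t *= 0.5
    return p, ll0, False


class _GPObjective:
    """Closed-form GP-block objective for the fixed-rate OU mixture.

    With the spike kernel and spiking parameters held fixed, moving u_r only
    shifts the residual by a constant - its DFT changes at frequency 0 alone -
    and the covariance weights do not touch the residual at all, so the whole
    block objective (GP + spiking terms) is evaluated without any FFT.
    """

    def __init__(self, ws: Workspace, p: AgapeParams):
        from scipy.special import gammaln
        from .simulator import adaptation_path, spike_kernel_lags

        self.segs = []
        self.const = 0.0
        self.beta = p.beta
        for seg in ws.segments:
            alpha = spike_kernel_lags(p.spike_kernel, seg.dt, n_max=seg.n - 1)
            v_base = seg.y - seg.m_dot(alpha)
            v_hat = np.fft.fft(v_base)
            p_base = np.abs(v_hat) ** 2
            _, d_rows, _ = seg.cov_spectra(p.cov)
            if isinstance(p.adapt, AdaptKernelParams):
                a_path = seg.adapt_design(p.adapt) @ p.adapt.weights
            else:
                a_path = adaptation_path(seg.s, p.adapt, seg.dt)
            e_base = p.log_r0 + p.beta * v_base + a_path + np.log(seg.dt)
            self.segs.append(
                dict(
                    n=seg.n,
                    u0=float(v_hat[0].real),
                    p_base=p_base,
                    d=d_rows,
                    mu_base=float(np.exp(e_base).sum()),
                    s_e=float(seg.s @ e_base),
                    s_tot=float(seg.s.sum()),
                )
            )
            self.const += -float(gammaln(seg.s + 1.0).sum()) - 0.5 * seg.n * np.log(2 * np.pi)

    def value_grad(self, x, with_grad=True):
        u_r, wts = x[0], x[1:]
        total = self.const
        g = np.zeros_like(x)
        scale = np.zeros_like(x)
        for sg in self.segs:
            n, d = sg["n"], sg["d"]
            c_hat = wts @ d
            if np.min(c_hat) <= 1e-12 * np.max(np.abs(c_hat)):
                return -np.inf, g, scale
            pwr = sg["p_base"].copy()
            u0 = sg["u0"] - n * u_r
            pwr[0] = u0 * u0
            inv_c = 1.0 / c_hat
            total += -0.5 * (np.sum(np.log(c_hat)) + np.sum(pwr * inv_c) / n)
            damp = float(np.exp(-self.beta * u_r))
            mu_sum = sg["mu_base"] * damp
            total += sg["s_e"] - self.beta * u_r * sg["s_tot"] - mu_sum
            if with_grad:
                g[0] += u0 * inv_c[0] - self.beta * (sg["s_tot"] - mu_sum)
                g[1:] += -0.5 * (d @ inv_c - (d @ (pwr * inv_c**2)) / n)
                scale[0] += n * inv_c[0] + self.beta**2 * mu_sum
                scale[1:] += np.abs(
                    -0.5 * ((d**2) @ (-(inv_c**2) + 2.0 * pwr * inv_c**3 / n))
                )
        return float(total), g, scale


def _gp_block(ws, p, ll, free, opt: FitOptions):
    """Preconditioned projected gradient ascent on (u_r, covariance params)."""
    if not isinstance(p.cov, CovKernelParams):
        return _gp_block_generic(ws, p, ll, free, opt)
    obj = _GPObjective(ws, p)
    x = np.concatenate([[p.u_r], p.cov.weights])
    ll_x, g, scale = obj.value_grad(x)
    for _ in range(opt.gp_inner_iters):
        floor = max(scale.max(), 1.0)
        scale[scale < 1e-12 * floor] = floor
        direction = g / scale
        direction[1:][(x[1:] <= 0.0) & (direction[1:] < 0.0)] = 0.0
        if not np.any(direction):
            break
        t, improved = 1.0, False
        for _ in range(40):
            x_new = x + t * direction
            x_new[1:] = np.maximum(x_new[1:], 0.0)
            ll_new, g_new, scale_new = obj.value_grad(x_new)
            if ll_new > ll_x:
                x, ll_x, g, scale = x_new, ll_new, g_new, scale_new
                improved = True
                break
            t *= 0.5
        if not improved or t * np.abs(direction @ g) < 0.01 * opt.tol_per_bin * ws.n_total:
            break
    q = copy.copy(p)
    q.u_r = float(x[0])
    q.cov = CovKernelParams(x[1:].copy(), p.cov.rates)
    ll_q = _try_loglik(ws, q)
    return (q, ll_q) if ll_q > ll else (p, ll)


def _gp_block_generic(ws, p, ll, free, opt: FitOptions):
    for _ in range(opt.gp_inner_iters):
        g, h = grad_hess(ws.rec, p, "gp", ws, free)
        scale = np.abs(np.diag(h))
        scale[scale < 1e-12 * max(scale.max(), 1.0)] = max(scale.max(), 1.0)
        direction = g / scale
        x0 = _pack(p, "gp", free)
        if not np.any(direction):
            break
        p_new, ll_new, ok = _backtrack(ws, p, "gp", free, x0, direction, ll)
        if not ok or ll_new - ll < 0.05 * opt.tol_per_bin * ws.n_total:
            p, ll = (p_new, ll_new) if ok else (p, ll)
            break
        p, ll = p_new, ll_new
    return p, ll


def _spiking_block(ws, p, ll, free, opt: FitOptions):
    """Damped Newton on the concave spiking GLM (log r0 [, beta] [, w]).

    The residual is fixed here, so the GP term is a constant and the block
    reduces to a plain Poisson regression evaluated without FFTs.
    """
    from scipy.special import gammaln
    from .simulator import spike_kernel_lags

    cols, svec, offs = [], [], []
    gp_const = 0.0
    n_w = p.adapt.weights.size if (free.adapt and isinstance(p.adapt, AdaptKernelParams)) else 0
    for seg in ws.segments:
        alpha = spike_kernel_lags(p.spike_kernel, seg.dt, n_max=seg.n - 1)
        v = seg.y - p.u_r - seg.m_dot(alpha)
        c_hat, _, _ = seg.cov_spectra(p.cov)
        v_hat = np.fft.fft(v)
        gp_const += -0.5 * (
            np.sum(np.log(c_hat)) + seg.n * np.log(2 * np.pi)
            + np.sum(np.abs(v_hat) ** 2 / c_hat) / seg.n
        )
        gp_const += -float(gammaln(seg.s + 1.0).sum())
        parts = [np.ones(seg.n)]
        if free.beta:
            parts.append(v)
        if n_w:
            parts.append(seg.adapt_design(p.adapt))
        cols.append(np.column_stack(parts))
        svec.append(seg.s)
        base = np.log(seg.dt)
        if not free.beta:
            base = base + p.beta * v
        if not n_w and isinstance(p.adapt, AdaptKernelParams):
            base = base + seg.adapt_design(p.adapt) @ p.adapt.weights
        offs.append(base if np.ndim(base) else np.full(seg.n, base))
    x_mat = np.concatenate(cols)
    s_all = np.concatenate(svec)
    off_all = np.concatenate([np.broadcast_to(o, (c.shape[0],)) for o, c in zip(offs, cols)])
    theta = np.concatenate(
        [[p.log_r0], [p.beta] if free.beta else [], p.adapt.weights if n_w else []]
    )

    def f(th):
        e = x_mat @ th + off_all
        if np.any(e > 700.0):
            return -np.inf, None
        mu = np.exp(e)
        return float(s_all @ e - mu.sum()), mu

    ll_sp, mu = f(theta)
    for _ in range(opt.newton_inner_iters):
        resid = s_all - mu
        g = x_mat.T @ resid
        h = -(x_mat.T * mu) @ x_mat
        direction = _ascent_direction(g, h)
        if direction is None:
            break
        t, stepped = 1.0, False
        for _ in range(40):
            cand = theta + t * direction
            if free.beta:
                cand[1] = max(cand[1], 0.0)
            ll_new, mu_new = f(cand)
            if ll_new > ll_sp:
                theta, ll_sp, mu = cand, ll_new, mu_new
                stepped = True
                break
            t *= 0.5
        if not stepped or t * abs(direction @ g) < 0.01 * opt.tol_per_bin * ws.n_total:
            break
    q = copy.copy(p)
    q.log_r0 = float(theta[0])
    if free.beta:
        q.beta = float(theta[1])
    if n_w:
        q.adapt = AdaptKernelParams(
            theta[1 + int(free.beta) :].copy(), p.adapt.rise_rates, p.adapt.decay_rates
        )
    ll_q = gp_const + ll_sp
    return (q, ll_q) if ll_q > ll + 1e-12 else (p, ll)


def _newton_block(ws, p, ll, block, free, opt: FitOptions):
    """Damped Newton on a concave block, with Levenberg shift as a safeguard."""
    if block == "spiking":
        return _spiking_block(ws, p, ll, free, opt)
    for _ in range(opt.newton_inner_iters):
        g, h = grad_hess(ws.rec, p, block, ws, free)
        direction = _ascent_direction(g, h)
        if direction is None:
            break
        x0 = _pack(p, block, free)
        p_new, ll_new, ok = _backtrack(ws, p, block, free, x0, direction, ll)
        if not ok:
            break
        gain = ll_new - ll
        p, ll = p_new, ll_new
        if gain < 0.05 * opt.tol_per_bin * ws.n_total:
            break
    return p, ll


def _ascent_direction(g, h):
    """Solve H d = -g, shifting H to be negative definite if needed."""
    if not np.any(g):
        return None
    hs = 0.5 * (h + h.T)
    lam = 0.0
    eigmax = None
    for _ in range(12):
        try:
            d = np.linalg.solve(hs - lam * np.eye(hs.shape[0]), -g)
        except np.linalg.LinAlgError:
            d = None
        if d is not None and g @ d > 0:
            return d
        if eigmax is None:
            eigmax = float(np.max(np.linalg.eigvalsh(hs)))
        lam = max(2.0 * lam, abs(eigmax) * 1e-3, 1e-10)
        lam *= 4.0
    return g / (np.max(np.abs(np.diag(hs))) + 1.0)


def _active_lower_bounds(x, g, p: AgapeParams, free: FreeFlags, names) -> np.ndarray:
    """Coordinates pinned at a non-negativity bound with an outward gradient."""
    mask = np.zeros(len(names), bool)
    lower = np.zeros(len(names), bool)
    if isinstance(p.cov, CovKernelParams):
        lower[1 : 1 + p.cov.n_free] = True
    if free.beta and "beta" in names:
        lower[names.index("beta")] = True
    mask[lower] = (x[lower] <= 0.0) & (g[lower] < 0.0)
    return mask


def check_concavity(
    rec: Recording,
    p: AgapeParams,
    ws=None,
    free: FreeFlags = FreeFlags(),
    eps_rel: float = 1e-10,
    constrained: bool = False,
):
    """Concavity test: True iff the largest Hessian eigenvalue is below
    -eps_rel * ||H||.  With ``constrained`` the test is restricted to the
    free subspace, excluding coordinates held at an active non-negativity
    bound (the correct local-maximum criterion under sigma2 >= 0, beta >= 0);
    by default the full-space Hessian is examined."""
    ws = ws or Workspace(rec, p.spike_kernel.n_bins)
    g, h = grad_hess(rec, p, "all", ws, free)
    if constrained:
        names = param_names(p, "all", free)
        keep = ~_active_lower_bounds(_pack(p, "all", free), g, p, free, names)
        h = h[np.ix_(keep, keep)]
    eigs = np.linalg.eigvalsh(0.5 * (h + h.T))
    norm = float(np.max(np.abs(eigs))) or 1.0
    return bool(eigs[-1] < -eps_rel * norm), float(eigs[0])


def _full_newton_phase(ws, p, ll, free, opt: FitOptions):
    """Projected full-space Newton with an active set on sigma2 >= 0 / beta >= 0."""
    names = param_names(p, "all", free)
    n_iter = 0
    for n_iter in range(1, opt.max_full_iters + 1):
        g, h = grad_hess(ws.rec, p, "all", ws, free)
        x0 = _pack(p, "all", free)
        fr = ~_active_lower_bounds(x0, g, p, free, names)
        d = np.zeros_like(x0)
        sub = _ascent_direction(g[fr], h[np.ix_(fr, fr)])
        if sub is None:
            break
        d[fr] = sub
        # quadratic estimate of the remaining gain: skip the step if the
        # Newton decrement already meets the convergence tolerance
        if 0.5 * float(g[fr] @ sub) < opt.tol_per_bin * ws.n_total:
            break
        p_new, ll_new, ok = _backtrack(ws, p, "all", free, x0, d, ll)
        if not ok:
            break
        gain = ll_new - ll
        p, ll = p_new, ll_new
        if gain < opt.tol_per_bin * ws.n_total:
            break
    return p, ll, n_iter


# ---------------------------------------------------------------------------
# fixed-delta fit and the delta sweep


def fit_fixed_delta(
    rec: Recording,
    delta: float,
    init: AgapeParams,
    opt: FitOptions,
    free: FreeFlags = FreeFlags(),
    ws: Workspace | None = None,
) -> FitResult:
    """Alternating-block ML fit at a fixed decision-to-peak offset.

    The recording must already be binned with nominal spikes at this delta.
    """
    ws = ws or Workspace(rec, init.spike_kernel.n_bins)
    p = copy.deepcopy(init)
    p.delta = float(delta)
    ll = _try_loglik(ws, p)
    if not np.isfinite(ll):
        raise ValueError("initial parameters are infeasible")
    trace = [ll]
    converged = False
    cycles = 0
    tol = opt.tol_per_bin * ws.n_total
    for cycles in range(1, opt.max_cycles + 1):
        ll_prev = ll
        p, ll = _gp_block(ws, p, ll, free, opt)
        if free.spike_kernel:
            p, ll = _newton_block(ws, p, ll, "spike_kernel", free, opt)
        p, ll = _newton_block(ws, p, ll, "spiking", free, opt)
        assert ll >= ll_prev - 1e-6, "accepted step decreased the log-likelihood"
        trace.append(ll)
        gain = ll - ll_prev
        # once the Hessian on the free coordinates is negative definite the
        # cycle stops and the optimization proceeds in the full space
        concave, _ = check_concavity(rec, p, ws, free, constrained=True)
        if concave or gain < tol:
            break
    p, ll, _ = _full_newton_phase(ws, p, ll, free, opt)
    trace.append(ll)
    converged = cycles < opt.max_cycles
    concave, _ = check_concavity(rec, p, ws, free, constrained=True)

    se, se_flags = {}, {}
    if opt.compute_se:
        from .diagnostics import fisher_standard_errors

        try:
            se, se_flags = fisher_standard_errors(rec, p, ws=ws, free=free, check=False)
        except np.linalg.LinAlgError:  # pragma: no cover
            se, se_flags = {}, {"failed": True}
    return FitResult(
        params=p,
        loglik_per_bin=ll / ws.n_total,
        delta_profile={float(delta): ll / ws.n_total},
        se=se,
        converged=converged,
        concave_at_optimum=concave,
        n_cycles=cycles,
        effective_coupling=p.effective_coupling(),
        loglik_trace=trace,
        se_flags=se_flags,
    )


def _as_segments(data):
    if isinstance(data, tuple) and len(data) == 2 and isinstance(data[0], VoltageTrace):
        return [data]
    return list(data)


def _bin_recording(segments, delta: float) -> Recording:
    segs = []
    for tr, peaks in segments:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            segs.append((tr, nominal_spike_bins(peaks, delta, tr.dt, tr.n, tr.t0)))
    return Recording(segs, metadata={"delta_ms": delta})


def _shifted_for_delta(p: AgapeParams, new_delta: float) -> AgapeParams:
    """Warm-start transfer across delta: moving delta by k bins moves the
    nominal spike times k bins earlier, so the same waveform sits k bins later
    relative to them - shift the spike-kernel amplitudes accordingly."""
    q = copy.deepcopy(p)
    k = int(round((new_delta - p.delta) / q.spike_kernel.dt))
    if k != 0:
        a = np.zeros_like(q.spike_kernel.a)
        if k > 0:
            a[k:] = q.spike_kernel.a[: a.size - k]
        else:
            a[:k] = q.spike_kernel.a[-k:]
        q.spike_kernel = SpikeKernelParams(a, q.spike_kernel.dt)
    q.delta = float(new_delta)
    return q


def _perturbed(init: AgapeParams, rng: np.random.Generator, scale: float) -> AgapeParams:
    q = copy.deepcopy(init)
    if isinstance(q.cov, CovKernelParams):
        w = q.cov.weights
        w = w * np.exp(scale * rng.standard_normal(w.size))
        q.cov = CovKernelParams(w, q.cov.rates)
    else:
        q.cov = SingleOUCov(
            q.cov.sigma2 * float(np.exp(scale * rng.standard_normal())),
            q.cov.theta * float(np.exp(scale * rng.standard_normal())),
        )
    q.spike_kernel = SpikeKernelParams(
        q.spike_kernel.a + scale * rng.standard_normal(q.spike_kernel.n_bins),
        q.spike_kernel.dt,
    )
    if isinstance(q.adapt, AdaptKernelParams):
        q.adapt = AdaptKernelParams(
            q.adapt.weights + scale * rng.standard_normal(q.adapt.weights.size),
            q.adapt.rise_rates,
            q.adapt.decay_rates,
        )
    return q


def fit(
    data,
    opt: FitOptions,
    template: AgapeParams | None = None,
    free: FreeFlags = FreeFlags(),
) -> FitResult:
    """Full ML fit with the delta grid sweep.

    ``data``: one (VoltageTrace, SpikeTimes) pair or a list of them; nominal
    spikes are re-binned per candidate delta.  The grid is swept ascending
    then descending with warm starts; per delta the best of the warm-started
    and ``n_restarts`` fresh-initialized runs is kept.  Ties in the profile
    break toward smaller delta.
    """
    segments = _as_segments(data)
    sk_support = (template.spike_kernel.n_bins * template.spike_kernel.dt) if template else 60.0
    if max(opt.delta_grid) >= sk_support:
        raise ValueError("delta_max must be below the spike-kernel support")
    deltas = sorted(set(float(d) for d in opt.delta_grid))
    rng = np.random.default_rng(opt.seed)
    sub_opt = copy.copy(opt)
    sub_opt.compute_se = False

    best_by_delta: dict[float, FitResult] = {}
    order = deltas + deltas[-2::-1]
    warm: AgapeParams | None = None

    def _visit(delta, ws_rec, warm_params, fresh: bool):
        rec, ws = ws_rec
        candidates = []
        if warm_params is not None:
            try:
                candidates.append(
                    fit_fixed_delta(rec, delta, _shifted_for_delta(warm_params, delta), sub_opt, free, ws)
                )
            except ValueError:
                pass
        if fresh:
            base = init_params(rec, template)
            base.delta = delta
            for r in range(opt.n_restarts):
                start = base if r == 0 else _perturbed(base, rng, opt.restart_scale)
                try:
                    candidates.append(fit_fixed_delta(rec, delta, start, sub_opt, free, ws))
                except ValueError:
                    continue
        prev = best_by_delta.get(delta)
        if prev is not None:
            candidates.append(prev)
        best_by_delta[delta] = max(candidates, key=lambda fr: fr.loglik_per_bin)

    def _workspace(delta):
        rec = _bin_recording(segments, delta)
        return rec, Workspace(rec, template.spike_kernel.n_bins if template else 60)

    for pos, delta in enumerate(order):
        _visit(delta, _workspace(delta), warm, fresh=pos < len(deltas))
        warm = best_by_delta[delta].params

    # polish pass: re-seed every delta from the current global best so the
    # profile values are comparable (same basin of the non-concave subspace)
    best_delta = max(deltas, key=lambda d: (best_by_delta[d].loglik_per_bin, -d))
    global_best = best_by_delta[best_delta].params
    for delta in deltas:
        if delta != global_best.delta:
            _visit(delta, _workspace(delta), global_best, fresh=False)

    profile = {d: best_by_delta[d].loglik_per_bin for d in deltas}
    best_delta = max(deltas, key=lambda d: (profile[d], -d))
    best = best_by_delta[best_delta]
    best.delta_profile = profile
    if opt.compute_se:
        from .diagnostics import fisher_standard_errors

        rec = _bin_recording(segments, best_delta)
        try:
            best.se, best.se_flags = fisher_standard_errors(
                rec, best.params, free=free, check=False
            )
        except np.linalg.LinAlgError:  # pragma: no cover
            pass
    return best
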