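"""Empirical statistics and uncertainty quantification.

Contains the windowed empirical autocovariance used to initialize the GP
fit, inter-spike-interval (ISI) statistics, the spike-triggered average,
observed-Fisher standard errors, and the coefficient-of-variation parameter
sweeps that map the model's dynamical repertoire:

* without adaptation the model is a log-Gaussian Cox process, so the ISI
  coefficient of variation CV = SD/mean is >= 1, growing with the effective
  coupling beta*sigma and the dimensionless rate r0*tau;
* with a suppressing adaptation kernel the CV also covers (0, 1).

Sweep simulations run on a fine grid (dt = tau/2000 for the Cox study)
with spikes placed uniformly *within* bins conditional on the per-bin Poisson
count - exact for piecewise-constant intensity - so ISI statistics do not
inherit the grid resolution.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import Recording, SpikeTimes, SpikeTrainBinned, VoltageTrace
from .kernels import CovKernelParams, ExpAdaptParams, SpikeKernelParams
from .likelihood import FreeFlags, Workspace, grad_hess, param_names
from .simulator import AgapeParams, sample_spike_times

__all__ = [
    "empirical_autocov",
    "isi_cv",
    "spike_triggered_average",
    "fisher_standard_errors",
    "cv_sweep",
    "CVSweepResult",
]


def empirical_autocov(trace: VoltageTrace, j_max: int) -> np.ndarray:
    """Windowed empirical autocovariance at lags 0..j_max bins.

    k_emp(j dt) = 1/(n-j-1) * sum_{i=1}^{n-j} (u_i - m1)(u_{i+j} - m2), where
    m1/m2 are the means of the leading/trailing windows of length n-j.  The
    two window means make the estimate exactly mean-free at every lag.
    """
    v = trace.values
    n = v.size
    if j_max >= n - 2:
        raise ValueError("j_max too large for the trace length")
    out = np.empty(j_max + 1)
    for j in range(j_max + 1):
        a = v[: n - j]
        b = v[j:]
        out[j] = np.dot(a - a.mean(), b - b.mean()) / (n - j - 1)
    return out


def _isi_from_input(spikes) -> np.ndarray:
    if isinstance(spikes, SpikeTimes):
        times = spikes.peak_times
    elif isinstance(spikes, SpikeTrainBinned):
        times = np.repeat(np.arange(spikes.n) * spikes.dt, spikes.counts)
    else:
        times = np.asarray(spikes, dtype=float)
    return np.diff(times)


def isi_cv(spikes):
    """(CV, ISIs): coefficient of variation SD/mean of the inter-spike
    intervals (SD with denominator n-1)."""
    isi = _isi_from_input(spikes)
    if isi.size < 2:
        raise ValueError("insufficient spikes: need >= 3 spikes for a CV")
    return float(np.std(isi, ddof=1) / np.mean(isi)), isi


def isi_density(spikes, bins="fd"):
    """Normalized ISI histogram (Freedman-Diaconis bins by default).

    Returns (bin_edges, density); density integrates to 1.
    """
    isi = _isi_from_input(spikes)
    if isi.size < 2:
        raise ValueError("insufficient spikes: need >= 3 spikes for a density")
    density, edges = np.histogram(isi, bins=bins, density=True)
    return edges, density


def spike_triggered_average(trace: VoltageTrace, peaks: SpikeTimes, window: float):
    """Mean trace snippet in [-window, +window] ms around each peak.

    Peaks whose window would be truncated are excluded (their count is
    returned).  Returns (lags_ms, average, n_used, n_excluded).
    """
    half = int(round(window / trace.dt))
    idx = np.round((peaks.peak_times - trace.t0) / trace.dt).astype(int)
    usable = idx[(idx - half >= 0) & (idx + half < trace.n)]
    if usable.size == 0:
        raise ValueError("no usable peaks fully inside the trace")
    snippets = trace.values[usable[:, None] + np.arange(-half, half + 1)]
    lags = trace.dt * np.arange(-half, half + 1)
    return lags, snippets.mean(axis=0), int(usable.size), int(idx.size - usable.size)


def fisher_standard_errors(
    rec: Recording,
    p: AgapeParams,
    ws: Workspace | None = None,
    free: FreeFlags = FreeFlags(),
    check: bool = True,
    cond_limit: float = 1e10,
):
    """Observed-Fisher standard errors sqrt(diag((-H)^-1)) at a local maximum.

    Near-singular information (condition number > cond_limit, e.g. boundary
    or unidentified coordinates) falls back to a pseudo-inverse and flags the
    affected parameters.  With ``check`` the Hessian must be negative
    semidefinite up to tolerance, else an error is raised.
    """
    ws = ws or Workspace(rec, p.spike_kernel.n_bins)
    _, h = grad_hess(rec, p, "all", ws, free)
    info = -0.5 * (h + h.T)
    eigs, vecs = np.linalg.eigh(info)
    scale = float(np.max(np.abs(eigs))) or 1.0
    if check and eigs[0] < -1e-6 * scale:
        raise ValueError("not at a maximum: Hessian has positive eigenvalues")
    names = param_names(p, "all", free)
    flags = {}
    if eigs[0] <= scale / cond_limit:
        keep = eigs > scale / cond_limit
        inv_diag = np.einsum("ij,j,ij->i", vecs[:, keep], 1.0 / eigs[keep], vecs[:, keep])
        bad = np.abs(vecs[:, ~keep]).max(axis=1) > 1e-3
        for nm, b in zip(names, bad):
            if b:
                flags[nm] = "near-singular information (pseudo-inverse)"
    else:
        inv_diag = np.diag(np.linalg.inv(info))
    se = {nm: float(np.sqrt(max(val, 0.0))) for nm, val in zip(names, inv_diag)}
    return se, flags


# ---------------------------------------------------------------------------
# CV parameter sweeps


@dataclass
class CVSweepResult:
    grid: list  # (beta*sigma, r0*tau) or (eta0, r0*tau_r) points
    cv: np.ndarray
    cv_se: np.ndarray
    n_isi: np.ndarray

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "coord1": [g[0] for g in self.grid],
                "coord2": [g[1] for g in self.grid],
                "cv": self.cv,
                "cv_se": self.cv_se,
                "n_isi": self.n_isi,
            }
        )


def _bootstrap_se(isi: np.ndarray, rng: np.random.Generator, n_boot: int = 500) -> float:
    n = isi.size
    idx = rng.integers(0, n, size=(n_boot, min(n, 200_000)))
    samples = isi[idx]
    cvs = samples.std(axis=1, ddof=1) / samples.mean(axis=1)
    return float(np.std(cvs, ddof=1))


def _collect_isis(p: AgapeParams, dt: float, seg_bins: int, n_isi: int, min_duration: float, ss):
    """Accumulate ISIs from independent segments until both the ISI count and
    the total-duration targets are met."""
    isis = []
    total = 0
    duration = 0.0
    max_segments = 2000
    children = ss.spawn(max_segments)
    for k in range(max_segments):
        times, _ = sample_spike_times(p, seg_bins, dt, children[k])
        if times.size >= 2:
            isis.append(np.diff(times))
            total += times.size - 1
        duration += seg_bins * dt
        if total >= n_isi and duration >= min_duration:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not collect the requested number of ISIs")
    return np.concatenate(isis) if isis else np.zeros(0)


def cv_sweep(
    study: str,
    grid=None,
    tau: float = 100.0,
    sigma: float = 2.0,
    n_isi: int = 5000,
    seed=None,
    n_boot: int = 500,
) -> CVSweepResult:
    """ISI coefficient of variation over a parameter grid.

    study='cox': grid points are (beta*sigma, r0*tau) for the single-OU,
    non-adaptive model (alpha = 0, eta = 0).  study='adaptive': beta*sigma =
    r0*tau = 1 fixed; grid points are (eta0, r0*tau_r) for the exponential
    adaptation kernel eta(t) = -eta0 exp(-t/tau_r).

    Everything is dimensionless in those coordinates; ``tau`` and ``sigma``
    set the (arbitrary) time and voltage scales of the simulation.
    """
    if study not in ("cox", "adaptive"):
        raise ValueError("study must be 'cox' or 'adaptive'")
    if grid is None:
        grid = (
            [(bs, rt) for bs in (0.0, 0.5, 1.0, 2.0) for rt in (0.25, 1.0, 16.0)]
            if study == "cox"
            else [(e0, rtr) for e0 in (1.0, 4.0) for rtr in (0.5, 2.0)]
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    point_seeds = ss.spawn(len(grid))
    boot_rng = np.random.default_rng(ss.spawn(1)[0])

    cvs, ses, counts = [], [], []
    spike_kernel = SpikeKernelParams(np.zeros(60), 1.0)
    for (c1, c2), pss in zip(grid, point_seeds):
        if study == "cox":
            bs, rt = c1, c2
            r0 = rt / tau
            p = AgapeParams(
                u_r=0.0,
                log_r0=float(np.log(r0)),
                beta=bs / sigma,
                delta=0.0,
                cov=CovKernelParams([sigma**2], [1.0 / tau]),
                spike_kernel=spike_kernel,
                adapt=None,
            )
            dt = tau / 2000.0
            # long enough that the slow-rate excursions driving the ISI tail
            # are represented; heavier coupling needs more correlation lengths
            min_duration = (2000.0 if bs >= 2.0 else 500.0) * tau
        else:
            eta0, rtr = c1, c2
            r0 = 1.0 / tau  # r0 * tau = 1
            tau_r = rtr / r0
            p = AgapeParams(
                u_r=0.0,
                log_r0=float(np.log(r0)),
                beta=1.0 / sigma,  # beta * sigma = 1
                delta=0.0,
                cov=CovKernelParams([sigma**2], [1.0 / tau]),
                spike_kernel=spike_kernel,
                adapt=ExpAdaptParams(eta0, tau_r),
            )
            dt = min(tau, tau_r) / 200.0
            min_duration = 300.0 * tau
        seg_bins = int(round(100.0 * tau / dt))
        isi = _collect_isis(p, dt, seg_bins, n_isi, min_duration, pss)
        if isi.size < 2:
            raise RuntimeError(f"grid point {(c1, c2)} produced too few ISIs")
        cvs.append(float(np.std(isi, ddof=1) / np.mean(isi)))
        ses.append(_bootstrap_se(isi, boot_rng, n_boot))
        counts.append(isi.size)
    return CVSweepResult(
        grid=list(grid), cv=np.array(cvs), cv_se=np.array(ses), n_isi=np.array(counts)
    )
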