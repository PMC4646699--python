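"""Sequential spike-sampling kernel (numba).

The adaptive point process is inherently sequential: the rate at bin i
depends on spikes in bins < i.  The compiled loop below walks the bins,
maintaining the adaptation state as a sum of geometric (exponential-decay)
components, and draws per-bin Poisson counts by inversion from pre-drawn
uniforms.  One uniform per bin makes the output deterministic given the
caller's seeded Generator and independent of numba's internal RNG.

Adaptation representation: eta(j*dt) = sum_m q[m] * d[m]**j with per-bin
decay factors d[m] = exp(-rate_m * dt); a spike in bin i first affects the
rate in bin i+1 (causal, lag >= 1).
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["poisson_counts_adaptive", "MAX_EXPONENT"]

#: exponents above this (nats) are treated as overflow, not clipped
MAX_EXPONENT = 700.0


@njit(cache=True)
def _counts_loop(bu, log_r0, dt, q, d, uniforms):  # pragma: no cover - compiled
    n = bu.shape[0]
    nm = q.shape[0]
    counts = np.zeros(n, dtype=np.int64)
    rates = np.zeros(n)
    z = np.zeros(nm)
    for i in range(n):
        a = 0.0
        for m in range(nm):
            a += q[m] * z[m]
        ex = log_r0 + bu[i] + a
        if ex > 700.0:
            return counts, rates, i
        r = math.exp(ex)
        rates[i] = r
        mean = r * dt
        u = uniforms[i]
        p = math.exp(-mean)
        cum = p
        k = 0
        while u > cum:
            k += 1
            p *= mean / k
            cum += p
            if k > 100000:
                return counts, rates, i
        counts[i] = k
        if k > 0:
            for m in range(nm):
                z[m] = (z[m] + k) * d[m]
        else:
            for m in range(nm):
                z[m] *= d[m]
    return counts, rates, -1


def poisson_counts_adaptive(bu, log_r0, dt, q, d, uniforms):
    """Per-bin Poisson counts and rates (per ms) for the adaptive process.

    Raises OverflowError naming the bin if the log-rate exceeds ~700 nats.
    """
    counts, rates, err = _counts_loop(
        np.ascontiguousarray(bu, dtype=np.float64),
        float(log_r0),
        float(dt),
        np.ascontiguousarray(q, dtype=np.float64),
        np.ascontiguousarray(d, dtype=np.float64),
        np.ascontiguousarray(uniforms, dtype=np.float64),
    )
    if err >= 0:
        raise OverflowError(f"firing-rate exponent overflow at bin {err}")
    return counts, rates
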