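"""Factorial model family and cross-validated comparison.

Four binary factors define 16 nested models: G (ten-component OU covariance
basis vs a single OU kernel with free time constant), alpha (spike-related
kernel), beta (voltage-to-rate coupling) and eta (adaptation).  M0 is the
simplest model (single OU, no kernels, 4 parameters: u_r, theta, sigma, r0);
the most complex, MGαβη, has all features.  The offset delta is a parameter
only for models with alpha or beta - for the others the likelihood does not
depend on where the nominal spikes sit relative to the peaks.

Comparison is by K-fold cross-validated per-bin log-likelihood: the data is
cut into equally sized chunks (in temporal order, treated as independent
samples), each model is trained on all-but-one chunk and scored on the
held-out chunk, and additionally on test chunks never used in training
(scored with the best-over-folds parameters).  The comparison currency is
the mean per-bin log-likelihood difference to the reference (full) model,
with its standard error over chunks.
"""
from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import Recording, SpikeTimes, VoltageTrace
from .fitting import FitOptions, fit
from .kernels import AdaptKernelParams, CovKernelParams, SingleOUCov, SpikeKernelParams
from .likelihood import FreeFlags, joint_loglik
from .preprocessing import nominal_spike_bins
from .presets import default_param_template
from .simulator import AgapeParams

__all__ = ["ModelSpec", "CVReport", "enumerate_models", "restrict", "crossvalidate"]


@dataclass(frozen=True)
class ModelSpec:
    multi_ou: bool = False
    use_alpha: bool = False
    use_beta: bool = False
    use_eta: bool = False

    @property
    def name(self) -> str:
        parts = "".join(
            s
            for s, flag in zip(
                ("G", "α", "β", "η"),
                (self.multi_ou, self.use_alpha, self.use_beta, self.use_eta),
            )
            if flag
        )
        return "M" + (parts or "0")

    @property
    def depends_on_delta(self) -> bool:
        return self.use_alpha or self.use_beta

    def param_count(self, n_cov: int = 10, n_spike: int = 60, n_eta: int = 10) -> int:
        """Free parameters including delta where it applies."""
        return (
            1  # u_r
            + (n_cov if self.multi_ou else 2)  # sigma2_i | (sigma2, theta)
            + (n_spike if self.use_alpha else 0)
            + 1  # log r0
            + (1 if self.use_beta else 0)
            + (n_eta if self.use_eta else 0)
            + (1 if self.depends_on_delta else 0)
        )


def enumerate_models() -> list[ModelSpec]:
    """All 16 flag combinations, M0 first, MGαβη last."""
    return [
        ModelSpec(bool(g), bool(a), bool(b), bool(e))
        for g in (0, 1)
        for a in (0, 1)
        for b in (0, 1)
        for e in (0, 1)
    ]


def restrict(p: AgapeParams, spec: ModelSpec) -> tuple[AgapeParams, FreeFlags]:
    """Constrain a full parameter set to a family member.

    Returns the pinned parameter template (a = 0 / beta = 0 / w = 0 as the
    flags dictate; single free-time-constant OU when multi_ou is off) and the
    matching free-parameter flags for the fitting machinery.
    """
    q = copy.deepcopy(p)
    if not spec.multi_ou:
        if isinstance(q.cov, CovKernelParams):
            var = max(q.cov.variance(), 1e-6)
            w = q.cov.weights
            rate = (
                float(np.sum(w * q.cov.rates) / np.sum(w)) if np.any(w > 0) else float(q.cov.rates[0])
            )
            q.cov = SingleOUCov(var, rate)
    if not spec.use_alpha:
        q.spike_kernel = SpikeKernelParams(np.zeros(q.spike_kernel.n_bins), q.spike_kernel.dt)
    if not spec.use_beta:
        q.beta = 0.0
    if not spec.use_eta:
        if isinstance(q.adapt, AdaptKernelParams):
            q.adapt = AdaptKernelParams(
                np.zeros_like(q.adapt.weights), q.adapt.rise_rates, q.adapt.decay_rates
            )
    free = FreeFlags(spike_kernel=spec.use_alpha, beta=spec.use_beta, adapt=spec.use_eta)
    return q, free


@dataclass
class CVReport:
    reference: str
    train: dict  # name -> (folds,) per-bin train log-likelihood
    valid: dict  # name -> (folds,)
    test: dict  # name -> (n_test,)
    fitted_delta: dict  # name -> (folds,)

    def delta_p(self, kind: str = "valid") -> dict:
        """Mean per-bin log-likelihood difference to the reference model and
        its SEM over chunks; the reference's own entry is exactly 0."""
        table = getattr(self, kind)
        ref = table[self.reference]
        out = {}
        for name, vals in table.items():
            d = np.asarray(vals) - np.asarray(ref)
            sem = float(np.std(d, ddof=1) / np.sqrt(d.size)) if d.size > 1 else 0.0
            out[name] = (float(np.mean(d)), sem)
        return out


def _cut_chunks(trace: VoltageTrace, peaks: SpikeTimes, starts, length: int):
    chunks = []
    for b in starts:
        t_lo = trace.t0 + b * trace.dt
        t_hi = trace.t0 + (b + length) * trace.dt
        sub = VoltageTrace(trace.values[b : b + length], trace.dt, t0=0.0)
        sel = (peaks.peak_times >= t_lo) & (peaks.peak_times < t_hi)
        chunks.append((sub, SpikeTimes(peaks.peak_times[sel] - t_lo)))
    return chunks


def _score(chunk, params: AgapeParams) -> float:
    tr, peaks = chunk
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sp = nominal_spike_bins(peaks, params.delta, tr.dt, tr.n, tr.t0)
    rec = Recording([(tr, sp)])
    return joint_loglik(rec, params, per_bin=True)


def crossvalidate(
    trace: VoltageTrace,
    peaks: SpikeTimes,
    specs=None,
    folds: int = 8,
    n_test_chunks: int = 6,
    opt: FitOptions | None = None,
    template: AgapeParams | None = None,
    train_chunk_len: int | None = None,
    test_chunk_len: int | None = None,
    reference: str | None = None,
) -> CVReport:
    """K-fold cross-validated model comparison on one recording.

    The first ``folds * train_chunk_len`` bins are cut into the training/
    validation chunks, the following ``n_test_chunks * test_chunk_len`` bins
    into held-out test chunks (default length ratio 5:1, as in an
    eight-fold / six-test-chunk partition).  Chunks are an exact partition:
    no bin appears in both roles.
    """
    specs = list(specs) if specs is not None else enumerate_models()
    opt = opt or FitOptions(delta_grid=(0.0,), n_restarts=1, compute_se=False)
    template = template or default_param_template(trace.dt)
    n = trace.n
    if train_chunk_len is None:
        train_chunk_len = int(5 * n // (5 * folds + n_test_chunks))
    if test_chunk_len is None:
        test_chunk_len = train_chunk_len // 5
    need = folds * train_chunk_len + n_test_chunks * test_chunk_len
    if need > n or folds < 2:
        raise ValueError("recording too short for the requested partition")

    train_chunks = _cut_chunks(
        trace, peaks, [k * train_chunk_len for k in range(folds)], train_chunk_len
    )
    base = folds * train_chunk_len
    test_chunks = _cut_chunks(
        trace, peaks, [base + k * test_chunk_len for k in range(n_test_chunks)], test_chunk_len
    )

    names = [s.name for s in specs]
    reference = reference or (
        "MGαβη" if "MGαβη" in names else names[-1]
    )
    report = CVReport(reference=reference, train={}, valid={}, test={}, fitted_delta={})
    sub_opt = copy.copy(opt)
    sub_opt.compute_se = False
    for spec in specs:
        p_tmpl, free = restrict(template, spec)
        grid = opt.delta_grid if spec.depends_on_delta else (0.0,)
        fold_opt = copy.copy(sub_opt)
        fold_opt.delta_grid = tuple(grid)
        tr_scores, va_scores, deltas_hat, fold_params = [], [], [], []
        for j in range(folds):
            train = [c for k, c in enumerate(train_chunks) if k != j]
            res = fit(train, fold_opt, template=p_tmpl, free=free)
            fold_params.append(res.params)
            tr_scores.append(res.loglik_per_bin)
            va_scores.append(_score(train_chunks[j], res.params))
            deltas_hat.append(res.params.delta)
        te_scores = [
            max(_score(chunk, par) for par in fold_params) for chunk in test_chunks
        ]
        report.train[spec.name] = np.array(tr_scores)
        report.valid[spec.name] = np.array(va_scores)
        report.test[spec.name] = np.array(te_scores)
        report.fitted_delta[spec.name] = np.array(deltas_hat)
    return report
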