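# Methods

## The model

The AGAPE (Adaptive GAussian Point Emission) process is a generative model
of an intracellular *in vivo* recording, i.e. of the joint distribution of a
somatic membrane-potential trace and the spike train it carries, without
reference to an (unobserved) input current. It composes three layers on a
regular time grid of width Δt (1 ms by default):

1. **Subthreshold potential.** u(t) is a stationary zero-mean Gaussian
   process with covariance k(t−t′) = Σᵢ σᵢ² e^(−θᵢ|t−t′|), a weighted sum of
   Ornstein–Uhlenbeck (OU) components on a fixed rate grid θᵢ = 2⁻ⁱ /ms,
   i = 1..10 (time constants 2 ms – 1.024 s). The weights σᵢ² ≥ 0 are free.
2. **Spiking.** Given u and the spike history, spikes form a point process
   with conditional intensity r(t) = exp(log r₀ + β u(t) + A(t)), where
   A(t) = (η ∗ s)(t) is the convolution of an adaptation kernel with the
   past spike train. η is a linear combination of ten alpha shapes
   e^(−νᵢt) − e^(−ωᵢt) with νᵢ = 2⁻ⁱ /ms and ωᵢ = νᵢ/2 (these basis
   functions are ≤ 0, so positive weights suppress firing after a spike);
   the sweep studies also use a single exponential η(t) = −η₀ e^(−t/τᵣ).
   Without adaptation the model is a log-Gaussian Cox process; β couples the
   voltage to the rate, and βσ (σ² = k(0)) is the dimensionless effective
   coupling.
3. **Spike waveform.** Each spike adds a stereotyped kernel α to the
   voltage: u_som(t) = u_r + u(t) + (α ∗ s)(t). α is piecewise constant on
   60 one-millisecond bins starting one bin after the *nominal* spike time.
   The nominal (decision) time sits a fixed offset δ ≥ 0 before the
   recorded action-potential peak; δ is a discrete parameter (a multiple of
   Δt) selected by profile likelihood.

Internally everything is in ms, mV and 1/ms; rates are reported in Hz at
the presentation layer (1 Hz = 10⁻³/ms).

## Likelihood and the circulant approximation

Because u_som is a deterministic composition of (u, s), the joint density
factorizes exactly into a Gaussian term for the residual
u*ᵢ = u_som,ᵢ − u_r − Σ_{j≥1} αⱼ s_{i−j} and a Poisson term for the binned
spike train with log-mean log r₀ + β u*ᵢ + (η ∗ s)ᵢ + log Δt. The log(s!)
term is always kept so per-bin scores remain proper log-probabilities when
a bin holds more than one spike. Segments of a recording are independent:
convolutions truncate at segment boundaries and each segment has its own
covariance structure at its own length.

The n×n Toeplitz covariance of the residual is replaced by the circulant
matrix minimizing the Kullback–Leibler divergence to it; its first row is
the closed-form diagonal-averaging of the Toeplitz first row, its
eigenvalues are the DFT of that row, and both the log-density and exact
sampling become O(n log n). The approximation is equivalent to periodic
boundary conditions; the per-bin error decays like (correlation length)/n
(verified against dense linear algebra in the tests). Spectral positivity
of the circulant eigenvalues — a set of constraints linear in the weights
σᵢ² — is the feasibility condition used throughout; non-negative weights
are sufficient but not necessary, and infeasible spectra are *rejected*
(never clipped, which would corrupt gradients).

All first and second derivatives of the log-likelihood are analytic. The
spike-shift structure of the waveform design matrix lets the Gram matrices
needed for the spike-kernel Newton step (MᵀC⁻¹M, Mᵀdiag(μ)M) be computed
from three FFTs plus boundary corrections involving only spikes within
60 ms of a segment end; all derivative code is validated against central
finite differences (relative error < 10⁻⁵) and dense-matrix oracles.

## Fitting

Maximum likelihood by alternating blocks: (1) the non-concave GP block
(u_r, σ²) by diagonally preconditioned projected gradient ascent with
backtracking; (2) the spike-kernel block (a₁..a₆₀) by damped Newton; (3)
the spiking block (log r₀, β, w) — a Poisson GLM with exponential gain,
hence concave — by damped Newton. Within block (1) the residual's DFT
changes only at frequency zero (u_r is a constant shift) and the covariance
weights do not touch the residual, and within block (3) the Gaussian term
is constant, so both block objectives are evaluated in closed form without
FFTs. After every cycle the Hessian restricted to the free coordinates
(excluding σᵢ² pinned at an active non-negativity bound) is tested for
negative definiteness; once concave, an active-set full-space Newton phase
runs to convergence. Every accepted step increases the log-likelihood.

δ is selected by re-binning the nominal spikes for each candidate and
sweeping the grid ascending then descending with warm starts; warm starts
across δ shift the spike-kernel amplitudes by the δ difference (the
waveform moves with the peak, not with the nominal time), each δ also gets
fresh moment-based initializations (u_r from the trace mean, σ² from a
non-negative least-squares fit of the OU mixture to the windowed empirical
autocovariance, kernels at zero, r₀ from the mean rate, perturbed with
seeded log-normal/Gaussian noise of scale 0.3 for restarts), and a final
polish pass re-seeds every δ from the global best so profile values are
compared within the same basin of the non-concave σ² subspace. Ties break
toward smaller δ. Defaults: tolerance 10⁻⁸ nats/bin, ≤100 cycles, 5
restarts (3 in the validation runs).

Standard errors come from the observed Fisher information (inverse negative
Hessian at the optimum); near-singular information (condition > 10¹⁰, e.g.
boundary or collinear coordinates) falls back to a pseudo-inverse with
per-parameter flags. Note the alpha-shape adaptation basis is strongly
collinear with log r₀ over typical inter-spike intervals, so individual w
estimates carry large, correlated errors while the kernel η(t) itself and
the headline scalars remain well determined.

## Synthetic validation conditions

The ground-truth parameter set (`agape.presets.validation_params`) uses
δ = 4 ms, r₀ = 4.15 Hz, β = 0.374 /mV, an OU mixture with k(0) = 8.1 mV²
(σ ≈ 2.8 mV, so βσ ≈ 1.06) carrying roughly a third of its variance at
millisecond time constants — fast synaptic-noise-like content, which is
precisely what makes the offset δ identifiable (misaligning u by one bin
must cost spiking likelihood that the free waveform cannot refund) — a smooth
biphasic 60-bin waveform peaking 4 ms after the nominal time (amplitude
≈ 10 mV with a shallow after-hyperpolarization, the scale of a
median-filtered action potential), and a mildly suppressing alpha-shape
adaptation mixture. All fixture weights are interior points so recovery is
a regular estimation problem. Recovery runs use 270 112 one-millisecond
bins (270.112 s); the δ-profile run uses 262 144 bins — at ~100 s the
profile's decline away from the true δ (a few nats) does not reliably clear
sampling noise, while at ~260 s it does.

What the simulator does *not* emulate: raw high-rate action-potential
waveforms (the model describes median-filtered, downsampled recordings;
the preprocessing tests add synthetic triangular templates on top of
simulator output to exercise that path), electrode drift and other
artifacts, non-Gaussian subthreshold marginals, and any stimulus or
network input. Passing recovery tests therefore demonstrates correctness
of the inference machinery under the model's own assumptions, not goodness
of fit to any particular biological recording.

## ISI sweeps

The coefficient of variation (CV = SD/mean of inter-spike intervals) is
estimated by simulation in dimensionless coordinates: (βσ, r₀τ) for the
non-adaptive single-OU model, (η₀, r₀τᵣ) with βσ = r₀τ = 1 fixed for the
adaptive study. The Cox study uses a grid of Δt = τ/2000 with spikes placed
*uniformly within bins conditional on the per-bin Poisson count* — exact
for piecewise-constant intensity — so interval statistics do not inherit
the grid; the adaptive study simulates sequentially (a compiled loop with
per-bin Poisson inversion from pre-drawn uniforms) at
Δt = min(τ, τᵣ)/200. Each grid point accumulates ≥ 5000 ISIs from
independent 100τ segments and additionally a minimum total duration (500τ;
2000τ when βσ ≥ 2, where rare slow-rate excursions dominate the ISI
variance). CV uncertainty is reported from 500 ISI bootstrap resamples;
the bootstrap treats ISIs as exchangeable and therefore understates the
error slightly when the rate is long-range correlated, which is why floor
tests use 3-SE margins.

## Numerical choices

- DFT convention: unnormalized forward transform (numpy); with it the
  circulant eigenvalues are the DFT of the first row and
  uᵀC⁻¹u = (1/n)Σ|û|²/ĉ. Any convention passing the dense oracle is
  equivalent.
- Spectra are declared infeasible below 10⁻¹² of their maximum.
- Exponents above 700 nats in the conditional intensity raise an overflow
  error naming the bin (the simulator and likelihood never clip silently).
- Sequential simulation draws one uniform per bin and inverts the Poisson
  CDF, so results are reproducible from a numpy SeedSequence regardless of
  the compiled backend; the GP, the spike counts and the within-bin jitter
  use independent spawned streams.
- Half-open bins [b·Δt, (b+1)·Δt), 0-based, segment-relative times; the
  nominal-spike binning drops (with a warning) spikes whose nominal time
  falls before the segment start.
- Peak detection threshold defaults to mean + 5·MAD; minimum peak
  separation 2 ms; decimation keeps each output bin's left-edge sample and
  then overwrites the bin at each rounded peak time with the filtered value
  at the exact peak, pinning the post-spike dip to the following bin.

## Model comparison

Sixteen models arise from four binary factors: multi-OU covariance (G) vs
a single OU with free time constant, spike-related kernel (α), coupling
(β), adaptation (η); δ is a parameter only when α or β is present (12 of
16 models). Comparison is by K-fold cross-validated per-bin log-likelihood
on an exact partition into chunks (temporal order, treated as independent
segments), plus held-out test chunks scored with each model's
best-over-folds parameters; differences to the full model are reported
with their SEM over chunks. On data simulated from the full model the
reduced models validate significantly worse; on data from M0 the full
model's validation deficit is bounded by the classical k/(2n) optimism
penalty and vanishes as chunks grow.

## Known limitations

- The circulant likelihood assumes each segment is much longer than the
  slowest covariance time constant; segments of a few hundred bins with
  σ² weight on the 1 s component will show boundary bias.
- Individual σᵢ² and wᵢ are not separately identifiable on realistic data
  lengths (neighbouring basis elements are nearly collinear); k(t) and
  η(t) as functions are the meaningful estimands.
- The δ profile is shallow above the true δ (the model can almost mimic a
  larger offset by shifting the waveform and paying only the voltage–rate
  decorrelation over the mismatch), so δ recovery needs several hundred
  seconds of data at ~4 Hz firing.
- Multi-spike bins are handled exactly in the likelihood, but the simulator
  warns when r·Δt > 0.5 in more than 1% of bins — use the oversampled mode
  in that regime.
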