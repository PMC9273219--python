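# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind wormdyn, and what the synthetic generator does and does
not emulate.

## Input model and normalization

A trial is a matrix of raw fluorescence, neurons × frames, with a sampling
rate (2 Hz for 120-neuron population trials of 600 s; 4 Hz for
single-neuron trials). Fluorescence is normalized to ΔF/F₀ = (F − F₀)/F₀
per neuron. Two baseline dialects exist because they suit different signal
shapes: for population data, F₀ is the mean of the lowest ⌈1% × frames⌉
samples of that neuron (a robust floor estimate that tracks the quietest
state visited; ties resolved by sorting values, so short traces are
deterministic); for bistable single-neuron traces, F₀ is the trace mean.
ΔF/F₀ is invariant to rescaling the raw trace by any positive constant, and
`dff·f0 + f0` reconstructs the input to machine precision. A non-positive
F₀ aborts with an error rather than producing infinities.

One consequence of the lowest-1% baseline worth knowing: with per-frame
noise of standard deviation σ, the estimated floor sits ≈2.7σ below the
true quiet level, so the recomputed ΔF/F₀ of an idle neuron is biased up by
roughly 1.3σ–2.7σ (depending on the pedestal). This matters wherever a
threshold is compared against near-baseline values (see Quiescence).

## SNR

Two read-outs. The manual-amplitude method mirrors per-trace inspection:
the caller supplies a window containing the largest sustained transient and
a quiet window (≥20 s in practice); SNR = 20·log₁₀(peak |signal| / mean
absolute deviation of the noise window). We deliberately require explicit
windows instead of guessing what "sustained" means. The automated method
tiles the trace with non-overlapping windows of 10 s, takes the mean
squared value per window, and reports 10·log₁₀(max/min) — ≥0 dB by
construction, 0 dB exactly for a constant trace. Non-overlapping windows
were chosen as the simplest deterministic tiling. Both measures are
invariant to rescaling the trace.

## TV-regularized differentiation

The derivative u of a noisy series f minimizes

    E(u) = ½ ‖A u − (f − f₀)‖² + α Σⱼ √((u_{j+1} − u_j)² + ε)

with A the left-Riemann antiderivative. The penalty is a Huber-smoothed
total variation of u: for gradient magnitudes below √ε it acts like a
quadratic (smoothing), above it like TV (edge-preserving). The minimizer is
found by lagged-diffusivity fixed-point iteration: freeze the weights
w = 1/√((Δu)² + ε), solve the resulting linear system, repeat. Because the
left-Riemann discretization makes (AᵀA)⁻¹ exactly tridiagonal (the inverse
of the min-matrix), multiplying the normal equations by it converts each
inner step into a pentadiagonal banded solve — O(n) per iteration, no
conjugate gradients, no preconditioner. Derivatives live on staggered
intervals and are averaged back to the sample grid (second-order at
interior points).

Defaults: α = 0.3, ε = 1e−3, at most 100 iterations with early stop at
1e−6 relative change (typically ~15–50 iterations). These were chosen for
accuracy on smooth-derivative signals: with ε at machine-precision scale
the pure-TV staircase limits a noisy sinusoid's derivative RMSE to ≈0.03
regardless of α, while ε = 1e−3 reaches ≈0.013 (σ = 0.05 noise at 2 Hz)
and still recovers a ramp's slope to <1e−12 and a step's sharpness. The
scheme is exactly antisymmetric under trace negation. Non-convergence
within the iteration budget sets a flag on the result instead of raising.

## Transition kinetics

Bistable traces are modeled per transition as
F(t) = b + a/2·(1 + s·tanh((t − t₀)/τ)), s = +1 (ON) or −1 (OFF) — the
minimal four-parameter sigmoid for which the 5→95% transition time has the
closed form 2τ·atanh(0.9) ≈ 2.944τ. Reading the rise time off the fitted
curve rather than raw samples removes the noise dependence of
threshold-crossing estimates. Candidate transitions come from a hysteresis
detector on a moving-average-smoothed copy rescaled to its dynamic range
(up through 0.7 after having been below 0.3 → ON; mirrored for OFF;
flat traces below a minimum amplitude yield no candidates). Fits use
least squares with t₀ initialized at the window's extreme-derivative frame
and τ at a tenth of the window; a fit is flagged not-ok when τ leaves
(one frame, window span). The transition's first frame is the fitted
curve's 5% point (ON) or 95% point (OFF), both at t₀ − τ·atanh(0.9).

Bouts pair each ON onset with the next OFF onset; duty ratio = summed bout
duration / trace length (an unpaired trailing ON extends to the trace end
and is flagged); transient frequency counts bouts per minute. An OFF
preceding any ON is an ordering error — callers analyzing traces that start
in the active state should drop the leading OFF first.

Estimator efficiency: at σ = 0.1·amplitude, 4 Hz, τ = 1 s, the Cramér–Rao
bound for the four-parameter fit gives sd(τ) ≈ 0.156, i.e. a best
attainable median relative error in the 5–95% time of ≈10.5% (≈10.3% even
with baseline and amplitude known). The least-squares fit measures ≈11%
over 1000 replicates — essentially efficient; no unbiased estimator can do
materially better at those conditions. Relative error scales as
1/√(fs·τ), so slower transitions are recovered proportionally better.

## Spectra and the 40% edge

Per-neuron PSDs are one-sided full-length periodograms (boxcar window,
per-neuron mean removed, DC bin dropped), giving Δf = 1/600 Hz for 10-min
trials and exact Parseval agreement between total power and trace
variance. No Welch segmentation or tapering is applied by default — the
simplest deterministic estimator; variance reduction comes from averaging
across 120 neurons and across animals. Condition means average PSDs within
worm, then across worms, then rescale to unit total power so indicator
brightness differences between conditions cannot masquerade as dynamics
differences. The q-quantile spectral edge is the smallest grid frequency
whose cumulative power fraction reaches q (default 0.40); no interpolation,
so edges are resolved to one bin and are invariant to rescaling the
spectrum and monotone in q. PSDs can alternatively be computed on the TV
differentials via the same entry point; ΔF/F₀ input is the default.

## Correlation structure

Functional coupling is the zero-lag Pearson correlation between the TV
differentials of neuron pairs among the n_sel = 40 neurons with greatest
ΔF/F₀ standard deviation (ties to the lower index; n_sel may be set to all
neurons for robustness checks). Differentials emphasize co-active
*transitions* over shared slow trends. Zero-variance members make a pair
undefined (NaN): excluded from proportions, counted, never silently
dropped. The per-animal summaries are the fractions of defined pairs with
r < −0.2 (anti-correlated) and r > +0.2 (correlated) — strict inequalities,
so ±0.2 exactly falls in neither tail. Pooled histograms over [−1, 1] use
40 bins of width 0.05, so the tail bins tile the thresholds exactly.

## State-space trajectories

PCA treats neurons as variables and frames as observations; per-neuron
means are removed, no variance scaling, scores keep their natural scale.
Component signs are fixed by making each loading vector's
largest-magnitude entry positive, so results are bit-reproducible.
Explained-variance fractions are kept for all components (summing to 1);
the trajectory uses the first k = 3. Smoothness is measured per frame as
the absolute angle between the past and future displacement vectors over
±3 s (6 frames at 2 Hz) in the k = 3 score space — a discrete curvature
read-out. Zero-length displacements give NaN, counted and excluded from
histograms (18 bins of 10°) rather than binned at 0°, which would
otherwise inflate apparent smoothness during quiescence. Angles are
invariant to rigid rotation and uniform scaling of the score space. For
i.i.d. random-walk increments in 3-D the angle density is sin(θ)/2 with
mean 90° — the analytic null for a fully stochastic trajectory. Recurrence
maps are pairwise Euclidean distances between frame vectors over all
neurons, normalized by the trial's maximal distance (all-equal frames give
an all-zero map flagged degenerate).

## Global quiescence

The trial-level high-activity reference is the mean across neurons of the
⌈25% × frames⌉ highest frame-mean ΔF/F₀ values. A neuron is quiescent at a
frame when its ΔF/F₀ is strictly below 1/3 of that reference; a frame is
globally quiescent when strictly more than 70% of neurons are quiescent;
time-in-quiescence is the fraction of such frames. All thresholds are
relative, so the classification is scale-invariant. The frame ranking uses
the across-neuron mean (a per-neuron-reference variant is available via
`reference="neuron"`). Subset extraction is deterministic: the 700-frame
window maximizing quiescent frames (earliest among ties), or the earliest
window containing none.

Detection physics: the indicator decays with τ ≈ 4 s, so fluorescence
crosses the 1/3 cutoff only ≈ ln(3)·4 s ≈ 4.4 s after activity actually
stops. Planted-bout recall is therefore evaluated against
fluorescence-level truth (bout onset shifted by that lag); with that
convention recall exceeds 0.93 and the false-positive rate stays below
0.013 on long planted bouts.

## Synthetic generator

The generator is the package's test bed: it emulates the statistical
structure of immobilized whole-head recordings with full ground truth.
Components, per trial:

- **Latent states.** A semi-Markov sequence over 8 states: Gamma dwell
  times (shape 4) with mean `dwell_mean`, cyclic successor with
  probability 1 − `transition_stochasticity`, else uniform; consecutive
  visits are separated by low-drive interludes (mean 6 s) — transitions
  pass through a quiet intermediate rather than jumping group-to-group.
  State onsets/offsets ramp over a Gaussian `state_ramp_s` (collective
  transitions are slower than single-cell transients).
- **Loadings.** 40 of 120 neurons are state-coupled, assigned round-robin;
  each joins a given visit of its state with probability 0.7
  (participation variability). A 0.3 fraction per state group is
  inhibitory: suppressed below the shared tonic pedestal by up to
  `inhibitory_depth × tonic_level`, scaled by `inhibition_scale` — the
  knob whose removal emulates the loss of inhibitory signaling.
  Suppression is bounded by the pedestal because fluorescence cannot go
  negative, regardless of excitatory drive strength.
- **Private transients.** Every neuron also fires its own ON/OFF
  transient train (exponential dwells); state-coupled neurons at
  `private_amplitude`, the other 80 at `background_amplitude` (relative to
  `drive_amplitude`). These are what keep purely structural cross-group
  correlations moderate and the undriven neurons realistically active.
- **Calcium kernel.** Unit-area difference of exponentials, 1 s rise,
  4 s decay — slow-indicator kinetics; plateau levels are preserved.
- **Quiescence bouts.** Poisson arrivals (`quiescence_rate`/min), duration
  exponential with mean `quiescence_dwell` bounded by per-bout minimum and
  maximum and a per-trial total cap. Bouts suppress the *activity*
  component of the drive to 5% — the tonic pedestal persists, since sleep
  stops transients rather than dimming the indicator — through a per-neuron
  envelope with gradual entry/exit (Gaussian ramp, `bout_ramp_s`) and ±2 s
  timing jitter: animals enter quiescence near-concertedly but not
  frame-locked, and a frame-locked collapse would plant large spurious
  positive pair correlations that real data at ~9% quiescence does not
  show.
- **Noise and output.** Additive white Gaussian noise (`hf_noise_sd`),
  then raw fluorescence `baseline_f·(1 + ΔF/F₀)`, floored at zero. All
  draws flow from one seeded generator; identical configs are
  bit-identical.

Why 8 states and gaps: with few mutually exclusive states visited in a
cycle, the differential traces of neurons in temporally adjacent groups are
structurally anti-correlated near r ≈ −0.5 (one group's fall coincides
with the next group's rise), which would swamp the planted inhibitory
signature. Eight states make adjacency a small minority of pairs, and the
inter-state gap offsets fall and rise bumps in time; combined with
participation variability and private transients, cross-group pairs stay
within ±0.2 while planted opposite-sign pairs remain strongly negative —
so the measured anti-correlated proportion agrees with the planted
fraction to within ±0.05 in the noise-free limit.

**Presets.** `age_preset(1)` (young): strong, smooth, near-cyclic states
(drive 2.5, dwell 10 s, ramp 4 s, stochasticity 0.05), full inhibition,
slow sparse private transients, low noise (0.008), rare short quiescence
(≈0.5% of the trial). `age_preset(9)` (aged): weak, prolonged, erratic
states (drive 1.2, dwell 24 s, ramp 1 s, stochasticity 0.45), inhibition
at 0.15, fast strong private transients (2 s/3 s), higher noise (0.04),
frequent quiescence bouts (0.75/min, ~24 s) yielding ≈6–10% measured time
in quiescence. The constants are documented design choices that reproduce
the qualitative aged signature — higher 40% spectral edge, collapsed
negative-correlation proportion with stable positive proportion, flattened
angular-change histogram, more global quiescence — consistently across
seeds (20/20 seed pairs in our verification at these settings); they are
not fits to any measured dataset, and absolute magnitudes should not be
compared against real recordings.

What the generator does **not** emulate: motion and tracking artifacts,
photobleaching trends, neuron identity (no AVA/AVB labels or bilateral
pairs), non-stationary aging within a trial, behavior-locked structure, or
realistic spatial correlations in noise. Passing tests therefore validate
the *estimators* and the internal consistency of the pipeline, not any
claim about real animals.

Single-neuron mode plants tanh transitions (known t₀, τ per event) in a
bout train with seeded jitter, for kinetics-recovery tests.

## Statistics

Group comparisons are one-way ANOVA across condition groups of per-worm
metric values (never pooled-neuron values), followed by pairwise
equal-variance t-tests adjusted over the requested contrast set by the
Sidak formula p_adj = 1 − (1 − p)^m. Group summaries report SEM. Under a
simulated null the procedure's type-I rate at α = 0.05 sits within
[0.03, 0.07] over 1000 resamples.

## Problem sizes

Default analyses use the study geometry (120 × 1200 frames at 2 Hz). The
test suite and the acceptance script use 10 animals per condition, 50-200
Monte-Carlo replicates for analytic benchmarks, and 1000 resamples for the
type-I check — sizes chosen so every sampling-error tolerance asserted is
several times the corresponding Monte-Carlo standard error.

## Known limitations

- The spectral edge is bin-resolved (1/600 Hz for 10-min trials); edges of
  very low-frequency spectra quantize visibly.
- The tanh fit assumes a single clean transition per window; overlapping
  transitions (τ comparable to the inter-event interval) bias τ upward and
  are only flagged via the τ-range check.
- The hysteresis detector replaces manual annotation; traces whose dynamic
  range is dominated by drift rather than transitions can produce spurious
  candidates. Thresholds are configurable.
- Noisy kinetics recovery is information-limited: at σ = 0.1·amplitude and
  4 Hz the median relative error of the 5–95% time cannot go below ≈10%
  for τ ≤ 1 s (see Transition kinetics above).
- The quiescence classifier inherits the indicator's decay lag (~4.4 s per
  bout onset) and the lowest-1% baseline bias at high noise; both are
  documented above and bounded in the tests.
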