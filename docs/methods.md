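# Methods

This note documents the models, estimators and numerical choices behind
`lnkit`, and what the synthetic-data tests do and do not establish.

## The LN-cascade framework

Visual responses of retinal ganglion cells (RGCs) and lateral geniculate
nucleus (LGN) neurons to white-noise stimuli are summarized with a
linear–nonlinear–Poisson (LN) cascade: a linear temporal filter applied to
the stimulus history, followed by a static (memoryless) nonlinearity that
maps the filtered stimulus to an instantaneous firing rate. The filter
captures response *kinetics* (latency, frequency tuning); the nonlinearity
captures response *strength* (gain).

### Spike-triggered average

The linear filter is estimated by the spike-triggered average (STA) of a
full-field binary (±1) noise stimulus at the 60 FPS frame clock, over a
500 ms window (30 lag bins of Δt = 1/60 s). Conventions:

- **Lag convention.** Lag 0 is the frame containing the spike; lags count
  backwards in time. This is fixed here because it is otherwise easy to be
  off by one bin between the simulator (causal convolution) and estimator.
- **Binning.** Spikes are binned at the recorded frame times with half-open
  bins `[frame_i, frame_{i+1})`; a spike exactly on a boundary goes to the
  later bin. The recorded frame clock is authoritative (robust to dropped
  frames); the nominal rate is used only to close the final bin.
- **State conditioning.** A spike enters the STA only if its own frame and
  its full 30-frame history lie inside the behavioral-state mask. Spikes
  whose history crosses a mask boundary are dropped rather than zero-padded,
  so state-conditioned STAs never mix states — the point of conditioning.

Under the null of no stimulus coupling each STA bin is asymptotically
N(0, 1/C), with C the retained spike count (a mean of C iid ±1 values).
Per-bin two-sided p-values follow, and a unit counts as visually driven
when some bin within 200 ms of the spike reaches p < 10⁻¹⁰. With 13 bins
tested at that threshold, the family-wise false-positive rate is ~10⁻⁹, so
null units essentially never pass (verified by simulation, 100 null units).

### Static nonlinearity

The nonlinearity is the histogram-ratio estimator
`P(response | stimulus) = N(stimulus | response) / N(stimulus) / Δt`,
with both histograms over the stimulus projected onto the L2-normalized
STA, bin width 0.1. Each recording phase uses its own phase-specific STA as
the projection axis (a shared-axis variant would conflate filter and gain
changes; the phase-specific choice matches per-phase estimation).
Because spike and occupancy histograms share exactly the same frame set,
`Σ rate·occupancy·Δt = retained spike count` holds exactly and is asserted
in the tests.

**Gain change** between two phases is reduced to one number: the
occupancy-weighted least-squares scale `c` minimizing
`Σ w (after − c·before)²` over bins occupied ≥ 100 times in both phases
(weight `w` = the smaller of the two occupancies), reported as
`100·(c−1)` percent. A per-bin median ratio is available as an alternative.
The scalar fit is preferred because it weights the informative,
well-sampled part of the curve and is equivariant under rescaling.

### Spatial receptive fields

Spatial filters come from checkerboard noise (18×32 pixels, each frame an
independent arrangement with exactly half the pixels white, keeping frame
luminance constant). The per-pixel STA is evaluated at the lag of the
global-magnitude peak, and a 2-D Gaussian (amplitude, center, two SDs,
orientation, offset) is fitted by bounded nonlinear least squares. RF size
is twice the mean SD of the long and short axes, i.e. σ_long + σ_short.
RF estimation is conditioned on the eye-stability mask so that fixational
scatter does not blur the map.

## Scalar descriptors

- **Peak latency**: a difference-of-Gaussians curve is fitted to the
  temporal filter (bounds: means within the window, SDs in [Δt/2, window];
  three jittered restarts; raw-extremum fallback, flagged). The latency is
  the time of the global-magnitude extremum of the fitted curve. For
  noiseless unimodal inputs this lands within one bin of the raw extremum.
- **Peak frequency**: magnitude spectrum of the mean-subtracted filter,
  zero-padded to ≥1024 samples at the 60 Hz frame rate, peak searched in
  0.5–30 Hz (DC removed; 30 Hz is the stimulus Nyquist). The simulator
  sweep pads to 8192 because its frequency shifts are smaller than the
  1024-point resolution of 0.059 Hz.
- **Polarity**: (peak − valley)/(peak + valley) of the filter, peak/valley
  the magnitudes of its positive and negative extremes; +1 pure ON,
  −1 pure OFF.
- **Flash responses**: PSTH at 1 ms bins over OFF–ON–OFF trials (2 s epochs,
  1 s gray inter-trial), trial-averaged and smoothed with a Gaussian kernel
  whose *total support* is 6 SD (SD default 2 ms, configurable — the SD
  itself is a free choice here). The ON–OFF index uses mean rates in the ON
  and second-OFF epochs; the peak is the global maximum within (0, 250] ms
  after the preferred transition (first-local-max is a documented
  alternative; the global max is more robust at low trial counts).
- **SNR** (unit selection): variance over time of the trial-mean response
  divided by the time-average of the across-trial variance, on the ON–OFF
  segment at 1/60 s bins; units above 0.15 count as visually driven.
  Identical trials give +∞ (kept). A constant offset leaves SNR unchanged;
  time-varying offsets do not.
- **DS/OS indices**: `‖Σ_k r_k e^(−iαω_k)‖ / Σ_k r_k` over the eight
  grating directions, α = 1 (direction) and 2 (orientation). Closed forms
  used as test oracles: single direction → 1; uniform → 0 (roots of unity);
  1+cos tuning → 1/2. Units with DS index > 0.15 count as
  direction-selective.
- **Functional typing**: L2-normalized temporal filters are embedded with
  t-SNE (perplexity min(30, (n−1)/3), PCA init, fixed seed) and clustered
  with k-means++ into six groups, named by the cluster-mean polarity and
  its latency tercile within polarity (fast/–/slow × ON/OFF). The naming
  heuristic is ours; the embedding/clustering pipeline is standard.

## Behavioral-state segmentation

All masks are pure functions of the behavior trace, evaluated per stimulus
frame by nearest behavior sample (behavior is sampled at 30–60 Hz, faster
than the states change).

- **Locomotion**: running iff speed > 2 cm/s; summaries are the fraction of
  time running and the median speed over running samples.
- **Pupil size**: tertile cuts at the 33rd/66th percentiles of the phase's
  finite pupil samples (per-phase rather than per-session, so a baseline
  shift after treatment does not empty a state). Constant pupil is
  degenerate: all-neutral, flagged.
- **Pupil derivative**: centered finite differences on the behavior clock,
  smoothed with a 0.5 s boxcar (our choice; only the ±0.01 units/s
  threshold is prescribed), then thresholded into
  constricting/stable/dilating.
- **Eye stability**: a sample is centered when both coordinates lie within
  a band of total width one IQR around the median (|x − median| ≤ IQR/2).
  The phrase "within one IQR" is ambiguous; the [Q1, Q3] reading is
  available behind a flag. Only centered runs lasting ≥ 2 s are kept.

## The integrate-and-fire Poisson simulator

The model neuron separates *intrinsic* parameters from *apparent* (LN-
estimated) response properties. Its drive is
`V(i) = G·(Σ_j L(j)·S(i−j) + B)` with gain G, resting baseline B, and a
fixed kernel `L(i) = sin[2π(10^(t_i)−1)/(10^(s_t)−1)]`,
`t_i = i·s_t/(nT−1)`, nT = 25, s_t = 1.5 — a sine on a logarithmic time
axis with one positive and one negative lobe. The Gaussian white-noise
stimulus is normalized to maximum absolute value 1 (read as symmetric
division by max |S|). A spike fires in bin i when V_eff(i) exceeds a fresh
uniform threshold u_i ~ U(0,1) (strict inequality), approximating Poisson
spiking; each spike adds a refractory kernel −exp(−j/s_h), j = 0..5,
s_h = 1, onto subsequent bins, kernels from nearby spikes summing linearly.

**Refractory alignment.** The kernel is applied starting at the first bin
*after* the spike (offset 1): applying −1 at the spike bin itself would
retroactively cancel the spike that triggered it. The alignment is
genuinely ambiguous, so a flag allows offset-0 application for sensitivity
analysis.

**The sweep.** B ∈ {−0.45..+0.45, step 0.15} × G = 1.2^g, g ∈ {−3..+3}:
49 cells, all sharing one million-frame stimulus realization (single-
stimulus design); the uniform thresholds use per-cell seeds
(base + 1 + cell index) — whether the original threshold stream was shared
across cells is unknowable, and sharing it would correlate the cells'
sampling noise. Each cell's spikes are re-analyzed with the same STA /
DoG-latency / spectral-peak / nonlinearity estimators used for data; cells
under 100 spikes have their estimates flagged undefined rather than
raising. Latencies and frequencies are reported in bins and, under a
60 bins/s convention, in ms and Hz.

The sweep reproduces the model signature: spike counts increase with G at
every B; the apparent latency at B = 0 shortens (monotonically, by a
fraction of a bin) as G rises; the apparent peak frequency depends more on
B than on G (range comparison at the grid medians); and the half-wave
slope of the estimated nonlinearity grows with G. The half-wave slope fit
(`rate = m·max(0, x − x0)`, m ≥ 0) profiles out m in closed form and scans
x0 on a dense grid with local refinement, which is robust for the noisy,
few-bin curves the sweep produces.

## The synthetic-data generator

The generator produces exactly the stimulus ensembles the estimators
assume — binary full-field noise at 60 FPS, luminance-balanced 32×18
checkerboards, OFF-ON-OFF flash protocols, eight-direction gratings — and
LN-Poisson ground-truth neurons (unit-norm filter, rectified-linear
nonlinearity `rate = state_gain·max(0, m·(proj − x0)) + baseline`). Spikes
are drawn per frame as Poisson(rate·Δt), matching the frame-clocked
analyses, and placed uniformly within the frame. The behavioral
`state_gain` multiplies the rectified drive, not the baseline, so gain and
baseline effects can be toggled independently when testing the simulator
logic.

Behavior is emulated with: an Ornstein–Uhlenbeck pupil (mean 1, SD 0.15,
autocorrelation time 20 s — slow against the frame clock, so tertile and
derivative states are non-degenerate); locomotion bouts with exponential
dwell times rescaled so the session's running duty equals the configured
fraction exactly (a finite draw of exponential bouts would otherwise
scatter by several points); and jittered fixations with Poisson saccades.
Defaults (20% running duty, 8 cm/s bouts) reflect a calm head-fixed mouse.

**What the synthetic tests do not show.** The generator matches the
estimators' assumptions by construction: real recordings add spike-sorting
contamination, nonstationary gain, non-Poisson firing, stimulus
correlations through eye movements, and adaptation. Passing the recovery
tests establishes the *estimators* are correct and well-calibrated, not
that the LN model is an adequate description of any particular neuron.

## Group statistics

Modulation of a nonnegative feature is summarized as
MI = (after − before)/(after + before) ∈ [−1, 1], antisymmetric and
scale-invariant. Paired before/after comparisons use the Wilcoxon
signed-rank test with Bonferroni correction across features. Treatment
groups are compared to the saline control with a Kruskal–Wallis omnibus
test and a Dunn-style post-hoc z-test on average group ranks (tie-corrected,
Holm-adjusted); the exact post-hoc procedure is configurable since only
"average group ranks" is prescribed by convention. The gain-vs-kinetics
analysis pools per-unit (gain MI, latency MI) and (gain MI, frequency MI)
pairs across conditions and reports Pearson correlations with pairwise
deletion of missing values.

## Problem sizes and determinism

Analyses and tests run on: 5–15 min noise recordings (18 000–54 000
frames) for single-unit round trips; one million frames for the simulator
sweep; 20 seeds for the gain-change recovery; 100 null units and 1000
Kruskal–Wallis replicates for calibration; 30-unit cohorts for the
correlation analyses. Every random quantity flows from an explicit
`numpy.random.default_rng` seed; the simulator's threshold loop is
compiled (numba) with a pure-Python fallback that is bitwise identical.

## Known limitations

- The LN estimators assume white stimuli; no whitening/regularization is
  provided, so they are not suitable for correlated (natural) stimuli.
- The DoG latency fit can fall back to the raw extremum on pathological
  filters; the fallback is flagged but still returns a number.
- t-SNE embeddings are only seed-deterministic, not stable under input
  perturbations; cluster *names* are a heuristic, not a physiological
  taxonomy.
- The simulator's latency and frequency shifts are fractions of a bin at
  these parameter ranges; resolving them requires the documented fine FFT
  padding and sub-bin DoG latency interpolation.
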