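# Methods

This note documents the models, parameter choices and numerical decisions
behind `fatigueforest`, and what the synthetic-data experiments do and do
not demonstrate.

## Signal model and preprocessing

Recordings are dual-channel segments — EEG in µV, ECG in mV — sampled at
`fs = 250` Hz, each with one Karolinska Sleepiness Scale (KSS) self-report.
KSS ≥ 6 defines the fatigued class `Y`; the first and last 30 s of every
acquisition are discarded as unstable, so a 5 min acquisition contributes
its central 4 min.

**ECG chain.** Four stages, in order:

1. *Scalar Kalman filter.* The recursion needs a state model the raw
   recursion equations do not supply; we use a random walk
   (`A = 1, B = 0, h = 1`) with data-driven noise levels
   `Q = 1e-4·var(x)`, `R = var(diff(x))/2`, `x0 = x[0]`, `P0 = var(x)`.
   The covariance/gain recursion is data-independent for a scalar model,
   so gains are precomputed to convergence and the stationary tail of the
   recursion runs through `scipy.signal.lfilter`; output is identical to
   the naive loop but ~100× faster on long records. The filter is causal
   and therefore introduces a small constant group delay (~4 samples at
   the default gain); this cancels in all R–R interval statistics.
2. *Approximation-only DWT reconstruction* (db4, J = 5, symmetric
   padding): all detail coefficients zeroed, removing content above
   ≈ fs/2^(J+1) ≈ 3.9 Hz.
3. *Zero-phase Butterworth high-pass*, fc = 0.5 Hz, order 5, against
   respiratory/motion baseline drift.
4. *Zero-phase Butterworth band-stop* 49–51 Hz, order 4, against mains hum.

All filters are applied forward–backward (`sosfiltfilt`) so fiducial
timing is not shifted; the transfer functions given for the design do not
prescribe phase handling, and zero phase is the right choice when R-peak
positions matter downstream.

*Where R-peak detection runs.* At 250 Hz with J = 5, stage 2 keeps only
0–3.9 Hz and therefore destroys the 5–15 Hz QRS energy every standard QRS
detector relies on. R peaks are consequently detected on the output of
stages 1+3+4 (Kalman, high-pass, notch), while the full four-stage chain
defines the denoised waveform used for quality reporting. This is a
deliberate design choice: detection needs the QRS band, waveform
denoising does not.

**EEG chain.** Wavelet soft-threshold denoising (db4, J = 5):
λ = std(finest-level detail coefficients)/2, applied as
`sign(c)·max(|c|−λ, 0)` to *all* detail levels; approximation
coefficients are never shrunk, because they carry the slow (δ) EEG
content. The same 49–51 Hz notch follows. Whether the original
formulation also thresholds approximation coefficients is ambiguous;
details-only is the standard reading and the one implemented. Rhythm-band
series are obtained by zero-phase 4th-order Butterworth band-passes at
the canonical edges δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz (a
level-to-band mapping of raw wavelet details is not frequency-consistent
at 250 Hz, so band-pass extraction is used instead).

The decomposition depth is stated both as 4 and as 5 in the source
description of this pipeline; J = 5 is adopted (it is the repeated value)
and configurable.

**Quality metrics.** SNR = 10·log₁₀(Σref²/Σ(ref−proc)²), RMSE, Pearson
CC. Identical inputs report a capped SNR of 300 dB so JSON reports remain
finite.

## Features (25 per window)

EEG, per band δ→γ (feature numbers 1–20): integrated Welch band power,
differential entropy ½·log₂(2πe·var), kurtosis (non-excess: Gaussian → 3)
and skewness, each computed on the band-filtered time series within the
window. Welch settings (unstated in the source): 2 s Hamming segments,
50% overlap — ≥ 14 averaged segments per 30 s window at 0.5 Hz
resolution. Band power integrates the PSD over the band's edges
(half-open `[lo, hi)` masks), reducing the density to one scalar per band.

ECG (features 21–25): HR = mean(60/RRᵢ) in bpm; RMSSD = √(mean of squared
successive R–R differences) in ms (the divisor is the number of
successive differences; a published variant normalising by "HR − 1" is a
notation slip); LFnorm = LF/(TP−VLF), HFnorm = HF/(TP−VLF), and
LF/HF = LFnorm/HFnorm (algebraically identical to raw LF/HF). The
unevenly sampled tachogram is cubic-interpolated to 4 Hz, linearly
detrended and Welch-estimated with 64-sample Hamming segments. Spectral
HRV requires the R–R series to span ≥ 20 s — the 30 s analysis window
itself bounds the span of detected beats strictly below 30 s, so a 30 s
guard would reject every window.

R-peak detection is Pan–Tompkins-style: 5–15 Hz band-pass, derivative,
squaring, 150 ms moving-window integration, an adaptive threshold at 20%
of the 90th-percentile peak energy, refinement to the local ECG maximum
(±100 ms) and a 250 ms refractory period. Candidates within 0.25 s of the
record edges are discarded (filter transients).

## Selection, fusion, classification, tuning

**mRMR.** Mutual information uses a plug-in estimate on equal-frequency
bins, `bins = min(10, ⌊√n⌋)`; discrete inputs (labels) are used as-is.
The greedy criterion at each step maximises Φ = D − R over the candidate
set, D the mean feature–label MI and R the mean pairwise MI over
unordered pairs of the set; ties break toward the lower feature index.
The fused feature count defaults to the top 14 of the ranking and can be
recomputed per dataset by the accuracy-vs-k subset search (smallest k on
ties).

**Fusion.** Half-open sample-aligned windows `[tᵢ, tᵢ+W)`, tᵢ = t₀+i·S
(W = 30 s, S = 1 s by default; a 30 s window is exactly 7500 samples).
Every row inherits its segment's label — the only labelling granularity
the acquisition protocol provides. Denoising and peak detection run once
per segment; windows slice the precomputed band series and beat series.
A failed window is dropped with a warning; more than 10% dropped is an
error.

**Cascade forest.** Each level holds `n_cascadeRF` random forests plus
`n_cascadeRF` completely-random forests (extra-trees with
single-feature splits), each with `n_cascadeRFtree` trees. Class vectors
for training rows are produced out-of-fold (3 internal stratified folds)
so no level sees its own training predictions; the deployed forests are
refit on all rows. Early stopping monitors the level's out-of-fold
accuracy with patience 1, up to 10 levels, and the model truncates to the
best level. Prediction averages the last retained level's forest
probability vectors; argmax ties resolve to the lexicographically first
class (`N`). A formulation that sums augmented vectors across all levels
appears in one place in the source description but contradicts the
level-wise recursion; the standard last-level average is implemented.
Multi-grained scanning is omitted: the input is an unordered 14-feature
vector, so the scanning stage of canonical deep forests is inapplicable.

**Bayesian optimization.** The objective is mean 5-fold stratified CV
accuracy. The GP uses a Matérn-5/2 kernel on inputs normalised to [0,1]²
with observation jitter 1e-6 and `normalize_y`. Length scales are bounded
to [0.05, 2]: with open-ended bounds the marginal-likelihood fit can pin
the length scale at a huge value, collapsing the posterior to a flat
function with zero predictive spread, which silently disables the
expected-improvement acquisition. EI is maximised over the 10 × 30
integer candidate lattice (tree axis stepped by 10); 5 random initial
points; exploration offset ξ = 1e-3 (ξ = 0.01 is of the order of the
objective's total range on this small lattice and stalls the search
before it localises the optimum — measurably worse than random search);
early termination when the best attainable EI < 1e-6. Evaluations that
raise are recorded as failures and skipped; more than 20% of the planned
budget failing aborts. Grid search walks the same lattice; random search
draws uniform integers from the full space.

## Synthetic cohort

The generator emulates a 20-subject campaign with 13 segments per subject
(7 non-fatigued, 6 fatigued; 260 segments), 5 min each at 250 Hz, one KSS
per segment drawn consistently with the state (N: 1–5, Y: 6–9).

*EEG*: a sum of band-passed Gaussian processes scaled so the relative
band powers match per-state shares. Non-fatigued shares
δ/θ/α/β/γ = 0.25/0.15/0.25/0.25/0.10; fatigue adds
(0, +0.10, +0.10, −0.15, −0.05) — θ/α up, β/γ down, the standard
drowsiness signature. Total band-mixture RMS 30 µV, plus 5 µV white
noise, 10 µV drift at 0.2 Hz, 2 µV 50 Hz hum.

*ECG*: a PQRST template (five Gaussian bumps, 1 mV R peak) placed at
cumulative R–R times. The R–R process is
`mean + a_L·sin(2π·0.1t) + a_H·sin(2π·0.3t) + jitter`, with amplitudes
solved in closed form so the realised RMSSD and LF/HF hit per-state
targets (N: RR 0.8 s, RMSSD 40 ms, LF/HF 1.5; Y: RR 0.9 s, RMSSD 20 ms,
LF/HF 3.0 — slower, steadier, sympathetically shifted rhythm). White
noise 0.03 mV, drift 0.15 mV at 0.2 Hz, hum 0.03 mV, beat jitter 2 ms,
between-subject RR offset σ = 0.02 s.

What passing tests show: every pipeline stage recovers the generator's
ground truth (band shares within ±0.05, HR within ±2 bpm, RMSSD within
±25%) and the end-to-end classifier separates the states. What they do
not show: performance on real EEG/ECG, where artifacts (blinks,
electrode pops, ectopic beats), non-stationarity and far smaller,
subject-dependent effect sizes dominate. The generator's effect sizes are
configuration, not empirical claims; zeroing them drives end-to-end
accuracy to chance, which the test suite checks.

## Problem sizes used in tests and the acceptance script

Simulations are scaled so the whole suite runs comfortably on one CPU:
cohorts use 110 s acquisitions (50 s central part after the 30 s edge
trims) with 10 s window steps — 3 windows per segment, 780 fused rows for
the 260-segment cohort — and the GP tuning demonstration uses a handful
of initial points and proposals over a 150-row stratified subsample with
single-level cascades in the cross-validated objective. The structural
checks still exercise the full-length geometry (a 300 s acquisition → 240 s
segment → 211 windows at S = 1). All stages accept the full-scale
parameters unchanged.

## Known limitations

- Binary fatigue only; no multi-level grading.
- Single EEG channel; no ICA/EOG artifact handling.
- The MI estimator is plug-in/equal-frequency; rankings are deterministic
  but biased for small n (no KSG estimator).
- The Kalman filter's causal group delay shifts absolute R-peak times by
  a few samples (intervals are unaffected).
- The cascade forest stores all level forests in memory; no out-of-core
  mode.
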