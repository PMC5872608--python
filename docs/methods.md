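# Methods

This note documents the models, conventions and numerical choices behind
`semgkit`: an offline analysis chain for multichannel surface EMG (sEMG)
aimed at myoelectric movement classification and at recovering volitional
muscle activity recorded during functional electrical stimulation (FES).

## Signal model and the synthetic generator

No public recordings exist for the acquisition protocol this package
targets, so a synthetic generator (`semgkit.simulate`) produces records
with the statistical structure the analysis assumes, together with a
ground-truth decomposition of every additive component. The generator is
first-class, tested code: every downstream stage is validated against
what was actually injected.

**Volitional sEMG.** Each channel's active-phase signal is
amplitude-modulated band-limited Gaussian noise: white noise band-passed
to 20–95 Hz (order-4 Butterworth, forward–backward), normalized to unit
RMS, then multiplied by a per-channel gain (mV RMS) and an on/off
activation envelope with 100 ms raised-cosine edges. This is the standard
surrogate for interference-pattern sEMG when motor-unit-level simulation
is not needed; the 95 Hz upper edge respects the 125 Hz Nyquist limit of
the 250 Hz sampling rate. What it deliberately does *not* reproduce:
motor-unit firing statistics, amplitude non-stationarity within a
contraction, fatigue, electrode-skin impedance drift, or cross-channel
crosstalk. Passing tests therefore demonstrate correct recovery under the
assumed model, not performance on real muscle.

**Session protocol.** A session starts with 10 s rest, then alternates
10 s isometric contraction with 10 s rest for `n_reps` repetitions
(default 10 → 210 s, 52 500 samples at 250 Hz). The ground-truth activity
mask is true exactly on the contraction plateaus.

**Contaminants.** Baseline wander is a sum of four sinusoids at
0.05–0.33 Hz (default total amplitude 0.5 mV, random phases per channel);
line interference is a 60 Hz sinusoid (default 0.05 mV); sensor noise is
white Gaussian (default 0.01 mV RMS). The record equals
`volitional + artifact + evoked + drift + line + noise` exactly, and all
six components are stored.

**Movement profiles.** Default hand-open and power-grasp profiles use
per-channel gains of 0.2–0.8 mV with the discriminative differences
concentrated on channels 1–3 and 7; the remaining channels respond
identically for both movements, so any classifier has to exploit the
informative channels. Amplitudes of ~0.1–1 mV are typical of forearm
sEMG; the scale is configurable.

**FES trials.** A trial is three consecutive blocks of five repetitions
(1 s on / 3 s off by default, 1.8 s / 2.2 s for pronation/supination
parameter sets): volitional only, FES only, and volitional during FES.
The stimulus artifact is modelled as the band-limited Fourier synthesis
of a strictly periodic biphasic pulse train: a constant-frequency
stimulator is periodic in continuous time, so the sampled artifact
carries all its energy exactly at the stimulation frequency and its
in-band harmonics (30 Hz → 30/60/90/120 Hz at 250 Hz). Peak amplitude
defaults to 2 mV. Each pulse triggers an M-wave surrogate — a damped
sinusoid (90 Hz carrier, 5 ms decay, 20 ms support, 5 ms latency, 0.5 mV
peak) evaluated at exact continuous pulse times so the evoked train is
periodic too. Real M-waves vary with recruitment and fatigue; this
surrogate is stationary by design.

## Preprocessing

* **Line notch** — order-2 Butterworth band-stop, 59–61 Hz, applied
  forward–backward (zero phase). All IIR stages in the package are
  zero-phase: the analysis is offline and a phase shift would move burst
  onsets relative to the ground truth.
* **Baseline removal** — 8-level discrete wavelet decomposition with
  Daubechies-4; the level-8 approximation is reconstructed and subtracted.
  At 250 Hz the level-8 approximation band is analytically
  [0, 250/2⁹ ≈ 0.49] Hz, which comfortably covers the injected sub-0.4 Hz
  drift. Wavelet boundaries use symmetric padding; reconstructions are
  truncated to the input length.
* **Envelope** — each channel is rectified and its 8-level Haar
  approximation reconstructed; the across-channel mean is the combined
  envelope. Rectification before the transform is required: the deep
  approximation of a zero-mean process is ≈ 0. Small negative
  reconstruction excursions are clipped at zero. The Haar approximation is
  piecewise-constant over ~1 s blocks, which smears burst edges by up to
  half a block; this bounds the achievable onset precision (see below).
* **Activity detection** — hysteresis thresholding against rest
  statistics taken from a known-rest interval (the protocol starts with
  rest): activate above μ_rest + 3σ_rest, deactivate below
  μ_rest + 1σ_rest. Morphology then merges gaps shorter than 200 ms and
  drops segments shorter than 200 ms (in that order; the order only
  matters for pathological envelopes). All four constants are exposed in
  `detect_activity`. With the default generator the detected mask overlaps
  the true plateaus at Jaccard ≈ 0.92; the ~0.08 deficit is almost
  entirely the ±0.5 s envelope smear at burst edges, not misdetection.

## Features and windowing

Within each active segment, windows of length `n = round(w·fs)` samples
start at multiples of `step = round((1−overlap)·n)` (minimum 1); only
fully contained windows are emitted. The seven features are computed per
channel and concatenated channel-major (CH1:MAV … CH8:SSC; 7 × 8 = 56
values per trial). Conventions where the usual definitions are ambiguous:

* **WL** sums |x_i − x_{i−1}| over the n−1 adjacent pairs.
* **ZC** counts strict sign oppositions with no amplitude dead-band; a
  zero-valued sample never contributes.
* **SSC** counts strict interior local extrema,
  (x_i − x_{i−1})(x_i − x_{i+1}) > 0 — the standard slope-sign-change
  count.
* **SD** and **V** use the n−1 normalization, so V = SD² exactly.

## Classification

Two-class LDA with class means and pooled within-class covariance
S = [(n₁−1)S₁ + (n₂−1)S₂]/(n−2), regularized by trace-scaled shrinkage
S ← (1−γ)S + γ·tr(S)/p·I with γ = 10⁻³. The shrinkage guards against
singular covariances at small trial counts (short windows can yield few
trials per class) while perturbing well-conditioned problems negligibly.
The decision rule sign(wᵀx + b) with w = S⁻¹(μ₂−μ₁) is algebraically
identical to comparing the two Gaussian discriminant functions, and is
computed from the same solve so the identity holds in floating point.

Evaluation repeats a stratified 70/30 split → train → test cycle ten
times, with repetition *i* seeded by `master_seed + i`; the same ten
splits are reused for every candidate subset so candidates are compared
on identical resamples. Subset selection is exhaustive over feature
subsets crossed with greedy-forward channel growth (stop when the mean
accuracy no longer improves); every greedy step's chosen subset is scored,
and candidates above the 90% threshold are retained, sorted by mean
accuracy with ties broken toward fewer channels, fewer features, shorter
windows. An exhaustive search over all 2⁵⁶ column subsets is infeasible;
greedy channel growth is the conventional compromise. The cross-session
figure trains one model on all session-1 trials of a configuration and
evaluates on all session-2 trials with no shuffling across sessions.

## FES artifact removal

The "comb" filter is a cascade of order-2 Butterworth band-stops of ±1 Hz
about the stimulation frequency and (by default) every harmonic below
Nyquist, each zero-phase. Harmonic notching is switchable
(`harmonics=False` keeps only the fundamental's 29–31 / 49–51 Hz band).
Overlap of the 30 Hz train's second harmonic with the 60 Hz line notch is
harmless — cascaded stop bands compose. Because the filter only removes
narrow bands, the output conserves every sample (no blanking) and
sub-25 Hz content passes essentially unchanged. Limitations: energy the
artifact leaks between harmonics (from the 1 s on/off gating of the pulse
train) and any evoked energy aliased off the harmonic grid survive the
comb; with the default generator the recovered signal correlates ≈ 0.88
with the injected volitional component over active samples.

## Problem sizes and determinism

Tests and the acceptance script regenerate all data at run time from
small integer seeds; every stochastic routine takes an explicit seed and
is bit-reproducible. The shipped analyses use 10-repetition sessions
(210 s per record, two movements × two sessions) for the cross-session
figure, 20 seeded sessions for activity-detection recovery, and 10 seeded
60 s FES trials for extraction recovery — sizes at which every recovery
statistic is stable to well within its acceptance margin while the whole
suite runs in well under a minute of compute per stage.

## Known limitations

* The sEMG surrogate is stationary Gaussian; real sEMG is neither, and
  reported accuracies on synthetic sessions are upper bounds on what the
  same pipeline achieves on real recordings.
* The envelope's ~1 s Haar-block resolution makes sub-second bursts
  detectable but their boundaries imprecise; for protocols with bursts
  ≪ 1 s a shallower decomposition would be needed.
* The LDA is strictly pairwise; multiclass problems require a wrapper
  (one-vs-one voting) that is out of scope here.
* Only 30 and 50 Hz stimulation frequencies are supported by the comb
  filter; other rates would need their own harmonic grids.
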