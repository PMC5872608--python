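# semgkit

Offline analysis of multichannel surface electromyography (sEMG) for
myoelectric control research: movement classification from forearm
recordings, and recovery of volitional muscle activity from recordings
contaminated by functional electrical stimulation (FES).

It is written for biomedical-signal researchers and neurorehabilitation
engineers who work with 8-channel forearm sEMG sampled at 250 Hz
(OpenBCI-class hardware exporting CSV) and need a tested, reproducible
version of the classic processing chain:

1. **Preprocessing** — 60 Hz line notch (order-2 Butterworth band-stop,
   59–61 Hz, zero phase); baseline-drift removal by subtracting the
   level-8 Daubechies-4 wavelet approximation; an amplitude envelope from
   the rectified signal's level-8 Haar approximation; and conversion of
   the envelope to a logic signal (active / rest) by hysteresis
   thresholding against rest statistics.
2. **Features** — overlapping windows (20 ms–3 s, 25% overlap) cut from
   active segments, with the classic time-domain features per channel:

   MAV = (1/n)Σ|xᵢ|, WL = Σ|xᵢ−xᵢ₋₁|, ZC (strict sign oppositions),
   SD and V (n−1 normalized, V = SD²), IAV = Σ|xᵢ| = n·MAV,
   SSC (interior local extrema), RMS = √((1/n)Σxᵢ²).

   Seven features × eight channels = one 56-value trial per window.
3. **Classification** — two-class LDA (pooled covariance with light
   shrinkage, w = Σ⁻¹(μ₂−μ₁)); stratified 70/30 splits repeated 10×;
   channel/feature/window-length subset selection keeping combinations
   above 90% mean accuracy; and a cross-session evaluation that trains on
   session 1 and tests on session 2.
4. **FES artifact removal** — a comb of narrow Butterworth band-stops
   (±1 Hz at the 30 or 50 Hz stimulation frequency and its in-band
   harmonics) that removes the stimulus pulse train without blanking a
   single sample, plus RMS/MAV comparison of evoked-only vs
   volitional+evoked conditions.

Because no public dataset exists for this acquisition protocol, the
package includes a first-class synthetic generator
(`semgkit.simulate`) producing 8-channel sessions and FES trials with
ground truth for every additive component (volitional, artifact, evoked,
drift, line, noise); all recovery claims are tested against it. See
`docs/methods.md` for the signal model and its limitations.

## Worked example

Train on one synthetic session per movement, test on a second:

```python
from semgkit import RunConfig
from semgkit.pipeline import synthetic_two_session_experiment, cross_session_accuracy

cfg = RunConfig(window_lengths_s=[0.5], feature_set=["MAV", "WL", "SD"],
                channel_subset=[0, 1, 2, 6], seed=1)   # CH1-3, CH7
s1, s2 = synthetic_two_session_experiment(cfg, seed=1)
acc = cross_session_accuracy(s1, s2, cfg, window_length_s=0.5)
print(f"cross-session accuracy: {100 * acc:.2f}%")
```

```
cross-session accuracy: 99.27%
```

That is: hand-open vs power-grasp trials from 0.5 s windows (MAV, WL, SD
on channels 1, 2, 3, 7), LDA trained on all 550 session-1 trials and
evaluated on the 550 untouched session-2 trials — on the default
synthetic profiles the two movements are nearly perfectly separable
across sessions.

Separating volitional sEMG from FES contamination:

```python
import semgkit as sk
from semgkit.records import ActivityMask

prof = sk.default_profiles()["power_grasp"]
rec, truth = sk.generate_fes_trial(prof, sk.StimulusSpec(), seed=1)
out = sk.extract_volitional(rec, stim_freq=30.0)     # baseline + comb filter
e0, e1 = rec.meta["blocks"]["fes"]                   # evoked-only block
c0, c1 = rec.meta["blocks"]["combined"]              # volitional + evoked
mask = ActivityMask(active=truth.activity_mask[e0:e1], fs=rec.fs)
table = sk.compare_conditions(out.slice_samples(e0, e1),
                              out.slice_samples(c0, c1), mask)
print(table.head(4).to_string(index=False, float_format=lambda v: f"{v:.4f}"))
```

```
channel  rms_evoked_mv  mav_evoked_mv  rms_combined_mv  mav_combined_mv
    CH1         0.1891         0.1180           0.2869           0.2246
    CH2         0.1894         0.1185           0.6691           0.5276
    CH3         0.1890         0.1184           0.2626           0.2001
    CH4         0.1896         0.1184           0.3653           0.2908
```

Adding volitional drive on top of stimulation raises the active-phase
RMS/MAV in every channel, most strongly in the channels the power-grasp
profile activates — the comb filter has removed the 2 mV stimulus
artifact while conserving every sample.

The same flows are available from a shell via the `semgkit` CLI
(`simulate`, `preprocess`, `features`, `classify`, `select`,
`extract-volitional`), e.g.:

```bash
semgkit simulate --movement hand_open --kind session --seed 1 --out out/
semgkit preprocess --input out/hand_open_session.csv --out out/
```

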