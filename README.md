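# vr2p

Analysis pipeline for head-mounted VR visual-learning experiments in mice
combined with 3D acousto-optical two-photon calcium imaging.

## The problem

In a fast visual discrimination task, a head-fixed mouse runs through an
infinite virtual corridor and is teleported into zones marked by grating
orientations. One orientation (0°) is aversive: the mouse has a 3.5-s grace
period to escape before airpuffs start (0.4-s pulses every 0.8 s); 45°/135°
zones are neutral controls. Learning shows up within tens of minutes as
(a) a behavioral speed-up at the end of the aversive zone and (b) a
ramp-like rise of V1 calcium activity over the final seconds of a zone.
Activity is recorded with 3D chessboard scanning: one small subfield per
soma at an arbitrary 3D position, at ~14 Hz, with neuropil decontamination.

This package implements the full analysis chain for such experiments, plus
a synthetic-data generator with complete ground truth standing in for
in vivo recordings:

- `vr2p.synthetic_data` — trial-structured sessions, 3-ms treadmill
  velocity, population transients built from known latent components
  (visual ON, zone-end ramp, two-component reinforcement, locomotion
  coupling) and rendered chessboard movies.
- `vr2p.imaging_pipeline` — per-subfield rigid motion correction
  (cross-correlation with subpixel refinement), mask cleaning for
  chessboard geometry (fill-value pixel screening; neuropil restricted to
  the home subfield and soma-free pixels), neuropil subtraction
  `F − 0.6·F_np`, and `ΔF/F = (F − F0)/F0` with F0 the 8th percentile of
  the day trace.
- `vr2p.behavior` — the abyss (virtual cliff) velocity ratio with failure
  rules, a label-shuffle bootstrap of zone velocity differences using
  dynamic time warping (DTW) in the 1.5 s before the scheduled first
  airpuff, anticipatory licking rates, and a Gaussian fit of the velocity
  frequency distribution.
- `vr2p.learning_metrics` — zone-end alignment, ramp amplitudes (window
  mean over (−1, −0.4) s or (−1, −0.3) s), activation ratios (2×s.e.m.
  threshold or paired tests), zone-preference classification, and the
  exponential + velocity decomposition of reinforcement responses whose
  residual ("second component") predicts later learning.
- `vr2p.assemblies` — hub-cell detection from the jump in the sorted
  ramp-amplitude distribution, hub spatial clustering against a
  permutation null, spontaneous cross-correlation outside the aversive
  zone, a 3–7-cell trial decoder (window mean over (−4, −2.5) s), 2-means
  high/low-ramp trial clustering, and V1↔running lead–lag.
- `vr2p.tca` — non-negative CP tensor decomposition of
  neurons × time × trials tensors via alternating non-negativity-
  constrained least squares with **block principal pivoting**, plus
  component interpretation (motion correlation, zone preference, kinetic
  tags).
- `vr2p.distortion` — the Brown–Conrady radial model of headset optics:
  `x_d = x_u(1 + K1 r² + K2 r⁴ + K3 r⁶)`, numerical inverse, coefficient
  estimation from calibration grids (Levenberg–Marquardt), and
  barrel/pincushion/mustache classification from the coefficient signs.

## Worked example

```python
import numpy as np
from vr2p.synthetic_data import (SimConfig, generate_session,
                                 sample_ground_truth, generate_transients)
from vr2p.learning_metrics import align_to_zone_end, ramp_amplitude
from vr2p.behavior import bootstrap_learning

cfg = SimConfig(seed=42, n_neurons=40, grid_shape=(5, 8),
                n_trials_per_zone=10, mean_interteleport=5.0,
                p_immobility=0.0)
session = generate_session(cfg, learning_curve=lambda t: min(t / 300, 1.0))
truth = sample_ground_truth(cfg)
traces = generate_transients(session, truth, cfg)

curves, labels = session.pre_airpuff_curves(pre_window=1.5)
res = bootstrap_learning(curves, labels, n_shuffles=1000, seed=0)
print(f"bootstrap learning score: {res.score:.3f}")

aligned = align_to_zone_end(traces.total, session, pre_window=5.0,
                            frame_rate=cfg.imaging_rate)
amp = ramp_amplitude(aligned, baseline_window=(-4.9, -4.0)).per_neuron
r = np.corrcoef(amp["AVER"], truth.ramp_amp_aver)[0, 1]
print(f"planted-vs-estimated ramp correlation: r = {r:.3f}")
```

Output:

```
bootstrap learning score: 0.954
planted-vs-estimated ramp correlation: r = 0.980
```

The bootstrap score is the proportion of 1,000 label shuffles whose DTW
group-mean velocity difference falls below the observed aversive-vs-control
difference; 0.5 is chance, values near 1 indicate the simulated mouse
discriminates the zones. The correlation shows the alignment + windowed-
mean estimator recovering the per-neuron ramp amplitudes planted by the
generator.

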