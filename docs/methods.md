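# Methods

This note documents the models, estimators and numerical choices behind
`vr2p`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where several operationalizations were
defensible.

## The synthetic experiment

The generator emulates a single-session visual discrimination experiment.
A simulated mouse runs on a treadmill whose velocity is an
Ornstein–Uhlenbeck (OU) process: mean `baseline_speed` = 12 cm/s,
stationary s.d. `speed_sd` = 2 cm/s, relaxation 1 s⁻¹, sampled every 3 ms
(negative excursions allowed, as on a real rotary encoder). At intervals
drawn from an exponential with mean `mean_interteleport` = 20 s (truncated
to 4–60 s) the mouse is teleported into a grating zone: `AVER_0` or
`CTRL_45` (optionally `CTRL_135`), with exact per-zone trial counts and a
shuffled visit order. In the aversive zone a grace period of
`zone_grace` = 3.5 s precedes airpuff pulses every `puff_period` = 0.8 s
until exit. With probability `learning_curve(t)` the mouse "escapes": it
exits before the first scheduled pulse, with a cosine-ramped speed-up of
`escape_speedup_sd` = 3 velocity standard deviations over the final 1.5 s
— the effect size the bootstrap power analysis assumes. Non-escape visits
last grace + 1.5 s + Exp(1.5 s) (capped at 6.5 s extra), so completed
trials always cover the 5-s alignment window used downstream. Airpuffs add
a transient `puff_reaction` = 5 cm/s speed-up (set to 0 in null
calibrations, whose defining property is one shared velocity process in
both zones). A fraction `p_immobility` = 0.05 of neutral periods contains
an immobility episode: velocity is exactly zero for 8 s, after which the
scheduled teleport fires at immobility onset + 8.000 s, implementing the
anti-passivity rule.

Per-neuron calcium traces are sums of separately returned components:

- **visual ON**: an alpha kernel `(t/τ)·exp(1 − t/τ)`, τ = 0.3 s, at every
  zone entry, scaled by `on_amp`;
- **ramp**: a linear rise over the final `ramp_onset` = 3 s of each zone,
  peaking at the zone end, scaled by `ramp_amp_aver` / `ramp_amp_ctrl` and
  by a per-trial high/low class (low trials scaled by 0.3) in the aversive
  zone. The 3-s onset is a free parameter: real ramps start "a few
  seconds" before the zone end and no exact figure is established;
- **reinforcement**: at the first airpuff of non-escaped aversive visits, a
  fast exponential `exp(−t/τ)` with per-neuron τ ∈ [0.4, 0.8] s scaled by
  `reinf_first_amp`, plus a slower bump (Gaussian at +1.5 s, σ = 0.5 s,
  unit integral) whose integral is `reinf_second_amp`. The second
  amplitude is generated as `0.5 · ramp_amp_aver` with 20% proportional
  noise, planting the early-reinforcement → late-learning correlation at
  single-cell level;
- **locomotion**: `locomotion_gain` times the velocity envelope (smoothed
  0.2 s, normalized to peak 1). A nonzero `planted_lead` samples the
  envelope `lead` seconds later, so neural activity leads running — the
  structure the lead–lag estimator must recover;
- **noise**: i.i.d. Gaussian with s.d. `noise_sd` = 0.05 ΔF/F. A Poisson
  (shot-noise) option was considered and deferred; additive Gaussian is
  sufficient for the recovery tests the generator serves.

Hub cells (fraction 0.1) receive aversive ramp amplitudes ~N(1.0, 0.05)
versus ~N(0.1, 0.02) for the rest — a bimodal distribution with an
unambiguous jump. Zone preference splits the population 44% / 14% / 42%
into aversive-dominant (control amplitude × 0.3), control-dominant
(÷ 0.3) and neutral cells. Somata are uniform in a 650-µm cube; a
`hub_cluster_radius` places hubs in a uniform ball instead.

Chessboard movies render one soma disk (radius 3 px) plus an annular
neuropil (radii 4.5–7 px) per 16×16-px subfield: soma pixels carry
`base + gain·(trace + 0.6·b(t))`, neuropil pixels `base + gain·b(t)`,
where `b(t)` is a shared smooth background — so the planted neuropil
contamination is exactly the 60% the correction assumes. Per-frame rigid
shifts move the scene; uncovered pixels take the fill value (0 by default,
NaN selectable). One soma per subfield is a deliberate simplification
(real segmentations occasionally find several).

What the generator does **not** emulate: optics and rendering of the VR
scene, eye movements, slow drift in baseline fluorescence, spatially
correlated noise, spike-to-fluorescence nonlinearity, or z-motion. Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated statistical structure, not robustness to every artifact of real
recordings.

## Imaging pipeline

**Motion correction.** Every subfield is registered separately against the
maximum-intensity projection of the first measurement unit. The integer
stage is a bounded exhaustive search (|shift| ≤ subfield/4, the same bound
the renderer enforces) maximizing the Pearson correlation over valid
(non-fill) pixels of the overlap; generic FFT phase correlation proved
unreliable on the small, radially symmetric subfields (spurious
ring-symmetry peaks). A subpixel residual is then estimated by upsampled
DFT cross-correlation (default upsampling 10, i.e. 0.1-px precision) on a
central crop that excludes fill pixels. Flat subfields get shift (0, 0)
with a warning rather than an exception. Integer shifts are recovered
exactly and 0.5-px shifts within 0.1 px on planted-motion movies.

**Mask cleaning.** Soma pixels whose trace contains a single fill value
(zero or NaN — both conventions occur in motion-corrected exports) are
dropped and the remaining weights renormalized to sum 1; an ROI losing all
pixels is flagged invalid, not raised. Neuropil pixels outside the home
subfield rectangle or overlapping *any* ROI's soma pixels (including the
ROI's own) are removed, and survivors are averaged with equal weight. Both
cleaning passes are idempotent.

**Correction and normalization.** `corrected = F_roi − 0.6·F_np` (the mix
is a parameter in [0, 1]; an empty neuropil falls back to a zero trace,
making the correction the identity). `ΔF/F = (F − F0)/F0` with F0 the 8th
percentile of the full day trace. The percentile convention is linear
interpolation between order statistics (the dominant array-library
convention), switchable to nearest rank; the choice moves F0 marginally.
A nonpositive F0 raises an error naming the ROI. Whether the 60%
subtraction precedes or follows pixel-weight renormalization is
mathematically irrelevant for fixed weights; it is applied after trace
formation.

## Behavioral statistics

**Abyss test.** The edge time is the first position-crossing of the edge
coordinate, else the onset of the first ≥2-s stop (velocity ≤ 0) at a
position from which the edge is visible; runs failing both within 20 s are
classified failed and excluded from ratio statistics. The velocity ratio
is mean velocity over (edge, edge+2 s] divided by mean over
[edge−2 s, edge): oriented so slowing gives < 1 and recoil < 0, matching
the stopped/recoiled narrative; the orientation is switchable.

**DTW.** Classical dynamic programming with absolute-difference local
cost, symmetric steps (insert, delete, diagonal), no window constraint,
unnormalized accumulated cost. The recursion is JIT-compiled (numba); the
test oracle enumerates all warping paths on tiny inputs. Note that under
this step pattern a series and a copy with repeated samples have distance
zero — distance zero means "identical up to warping", not sample-wise
equality.

**Shuffle bootstrap.** Per session: the statistic is the DTW distance
between the label-group mean velocity curves in the 1.5-s window ending at
the scheduled first-airpuff time (entry + 3.5 s; the same schedule defines
the window in control trials, where no airpuff occurs). The label vector
(control = 1, aversive = 2) is shuffled 1,000 times; the score is the
proportion of shuffled distances below the original, with ties counted
half — the tie rule keeps degenerate nulls at the 0.5 chance level. A
simpler mean-difference statistic is available behind `statistic=
"mean_diff"`; DTW between group means is the default reading. A quartering
helper splits a day into four equal parts for within-day trends. Null
calibration: across simulated exchangeable sessions the score is uniform
on (0, 1) (KS-tested) with mean 0.5.

**Velocity Gaussian.** The frequency count of velocity samples is fitted
with `y = y0 + A/(w·(π/(4 ln 2))^−0.5) · exp(−4 ln2 (x−xc)²/w²)` — the
FWHM parameterization implemented verbatim; note the −0.5 exponent in the
amplitude term differs from the more common `A/(w·sqrt(π/(4 ln2)))`
normalization and only rescales the fitted A. Moment-based initialization
with random restarts; per-parameter p-values from the asymptotic
covariance (t-test against zero, n − 4 d.o.f.).

## Learning metrics

**Alignment.** Trials are cut to `pre_window` seconds ending at the zone
exit (right-closed: the frame at the exact exit time is the last sample),
or at the scheduled first airpuff for aversive trials when quantifying
learning. Velocity is resampled to the imaging rate on the same axis.
Trials shorter than `min_trial_duration` (default: the window) are dropped
and counted; passing 0 keeps short trials whose window reaches into the
preceding neutral corridor — legitimate for 5-s tensors over ~4–5-s zone
visits.

**Ramp amplitude** is the window mean of ΔF/F (integral ÷ length) over
(−1, −0.4) s by default, making the alternative (−1, −0.3) s window
directly comparable; a raw-integral mode is retained. An optional
`baseline_window` subtracts the mean of an early reference window of the
same segment: this isolates the ramp from tonic and locomotion-coupled
offsets and is used in the recovery analyses (raw window means correlate
r ≈ 0.92 with planted amplitudes under locomotion coupling,
baseline-referenced means r ≈ 0.98). The estimator is linear in the input
either way.

**Activation ratio.** `threshold_2sem`: active if the trial-mean response
exceeds the baseline mean by 2 × s.e.m. of the baseline across trials.
`paired_test`: one-tailed paired t (or Wilcoxon signed-rank) across trials
at α = 0.05, reported raw (for fidelity with the original analyses, which
apply no correction) and Benjamini–Hochberg-adjusted. Type-I calibration
on pure noise lands at ~5%. The baseline window is a parameter; the last
second of the preceding neutral period is the recommended choice.

**Zone preference.** Per-neuron difference of mean aversive vs control
ramp amplitude, labeled by sign where a two-tailed Welch two-sample t-test
across trials rejects at α = 0.05. (Aversive and control trials are
disjoint sets, so a paired test is undefined.)

**Reinforcement decomposition.** Post-airpuff responses are modeled as
`a·exp(−t/τ) + g·v(t)` with `v` the normalized aligned velocity and
a, g ≥ 0 (NNLS); τ is scanned over a geometric grid (0.1–3 s, 25 points)
with bounded scalar refinement. The fit is made robust to the quantity it
is meant to expose: samples whose residual exceeds 0.5 × RMS are excluded
and the model refitted (≤6 iterations), so a delayed second component is
not absorbed into a stretched exponential. The second component is the
time-integral of the positive residual; per-component velocity
correlations are reported. This operationalization is one of several
defensible readings of "an additional second component after
reinforcement" and is isolated behind a single function so it can be
swapped.

## Assemblies

**Hub threshold.** Amplitudes are sorted ascending; the threshold sits at
the largest first-difference whose upper rank lies in the top quartile,
accepted only if it exceeds 2 × the median gap (otherwise: no-jump flag,
empty hub set). The rule is invariant under affine maps `a·x + b`, a > 0,
and is deliberately isolated: the original analyses display a derivative
trace and a marked jump without an explicit formula.

**Spatial clustering.** Mean pairwise Euclidean distance among hub somata
versus `n_draws` equal-size random subsets of the coding population;
normalized ratio (hub/null) and a one-sided permutation p-value with the
add-one correction `p = (1 + #{null ≤ obs})/(n + 1)`, which keeps the null
distribution of p uniform.

**Spontaneous cross-correlation.** Zero-lag Pearson correlations over all
samples outside aversive-zone intervals (control-zone exclusion optional),
with group means for hubs, the lowest-ramp decile, and the rest;
normalization of group means to the largest group is optional output,
since the corresponding published group values appear to be normalized to
the best-learner group without an explicit statement.

**Decoder.** Members are the top-k neurons (k ∈ 3..7) by
aversive-minus-control ramp difference on training trials; the decoder
function is their mean ΔF/F, the decision statistic its window mean over
(−4, −2.5) s, and the threshold the midpoint of the training-class means
(ROC-optimal thresholds would be a drop-in alternative). `k = None` picks
the smallest k with perfect training accuracy, else 7. Reliability is the
held-out fraction correct; on exchangeable labels it sits at 0.5.

**Trial clustering and lead–lag.** 2-means on per-trial ramp scores
(seeded, 10 restarts; scores are max-normalized first so labels are
scale-invariant), with the larger-center cluster labeled high-ramp, plus
the Pearson correlation between per-trial velocity and ramp score. The
lead–lag estimator maximizes the normalized cross-correlation over
integer-sample lags within ±max_lag; positive lags mean neural activity
leads running. Onset times (for hub-vs-population timing) are first
crossings of 20% of peak-above-baseline on 0.2-s-smoothed traces.

## Tensor component analysis

Aligned responses are Gaussian-filtered along time (σ = 0.15 s default,
truncated kernel, reflect padding), cropped to the 5 s before the zone
end, and clipped at zero (negative ΔF/F has no representation in a
non-negative model; a shift-to-minimum alternative is available). The
per-trial motion integral (velocity integrated over the cropped window)
and zone labels ride along for interpretation.

The CP model is fitted by alternating non-negativity-constrained least
squares, each mode solved *exactly* by block principal pivoting: passive
and active index sets are exchanged wholesale while the number of KKT
violations decreases, with a fall-back to single-variable (largest-index)
exchanges that guarantees termination; an ill-conditioned Gram matrix
triggers ridge regularization with a warning. Because each mode update is
an exact minimizer, the Frobenius objective is monotone nonincreasing —
asserted at every iteration. Convergence: relative error change < 1e-6 or
500 iterations; the best of `n_restarts` seeded random initializations is
kept, and identical seeds give identical factors. Scale indeterminacy is
fixed by unit-L2-normalizing neuron and time columns and absorbing all
scale into the trial factors. Rank selection follows a no-overfit
criterion — reconstruction error at the planted rank must beat rank − 1 —
rather than full-reconstruction fidelity; component recovery is verified
by congruence (product over modes of column cosine similarities, matched
by Hungarian assignment) > 0.9 on planted rank-3 tensors at 5% noise.

Interpretation per component: Pearson r between trial factor and motion
integral; aversive-vs-control comparison of trial weights by both
two-sample t-test and Mann–Whitney U; kinetic tags from the temporal
profile (peak in the last 20% of samples with Spearman ρ(t, factor) > 0.7
→ ramp; peak in the first 30% → on).

## Distortion model

Purely radial Brown–Conrady: `x_d = x_u·(1 + K1 r² + K2 r⁴ + K3 r⁶)`,
with r the distance from the center in units of `norm_radius` (half the
image diagonal by convention — rescaling it rescales the coefficients;
tangential/decentering terms are out of scope). The forward map refuses
domains where the radial polynomial is nonmonotone (the inverse would be
ill-defined). Inversion works on the radius: fixed point
`r_u ← r_d/g(r_u)` with a Newton fallback, to `‖apply(invert(p)) − p‖ ≤
1e-9` in ≤100 iterations (no closed form exists). Coefficients are
estimated from point correspondences by Levenberg–Marquardt on the
reprojection residuals; at least 6 pairs spanning ≥3 distinct radii are
required (a single radius is rank-deficient and rejected). Classification
follows the sign rule: all-negative coefficients → barrel, all-positive →
pincushion, mixed → mustache, all ≈ 0 → none.

## Problem sizes and determinism

Simulated analyses use sizes chosen to make their statistics meaningful at
interactive runtimes: bootstrap calibration uses 300 null sessions of
16 + 16 trials with 1,000 shuffles (session scores are ~uniform, so the
mean has SE ≈ 0.29/√n ≈ 0.017 at n = 300); recovery analyses use
54–100-neuron populations; tensor recovery uses 80 × 72 × 40. Every
stochastic component consumes an explicit seed (NumPy `default_rng`;
derived streams via `SeedSequence`), and same-seed runs are bit-identical.

## Known limitations

- The chessboard renderer shares one motion series across subfields;
  per-subfield motion is supported by the registration but not planted.
- The reinforcement second-component extraction is heuristic (robust
  residual integral); alternative definitions would shift absolute values
  while preserving the across-neuron ordering the learning correlation
  relies on.
- The generator's licking model is a homogeneous Poisson process; it does
  not emulate bout structure or reward anticipation, so the anticipatory
  licking-rate estimator is exercised on constructed event times.
- The DTW bootstrap treats trials as exchangeable; slow within-session
  drift in running speed would violate the null in real data and should be
  handled by the day-quartering helper.
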