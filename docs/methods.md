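# Methods

This note documents the models, parameter choices and known limitations
of the `flightlfp` pipeline, in the order data flows through it.

## Synthetic multimodal recordings

The generator (`flightlfp.synthio`) produces the three synchronized
streams of a wearable avian telemetry system — 8-channel LFP at 1000 Hz,
six-axis IMU at 200 Hz, GPS at 10 Hz — for a ~2 km homing flight,
together with the ground truth needed for recovery tests. All randomness
derives from one seed through independent `SeedSequence` children
(trajectory / sensors / LFP), so runs are bit-reproducible and the clean
LFP is provably independent of the trajectory when the planted effects
are zeroed.

**Trajectory.** Tangential acceleration is a sum of Gaussian episodes
(width 0.5–1.2 s, peak 0.8–6 m/s², one every 3–7 s) plus a band-limited
(< 0.4 Hz) jitter of 0.25 m/s² RMS emulating airflow buffeting, clipped
to ±6 m/s². Episode signs are steered so speed stays within
8–22 m/s around a 15 m/s cruise; this bounds the time-mean acceleration
near zero (|Δv|/T) and keeps speed far above the 2 m/s flight
threshold. Heading follows a slow sinusoidal meander (±0.35 rad, 45 s
period). The meander replaces a strictly constant heading for two
reasons: real homing tracks are not straight lines, and heading
variation is what renders body-fixed accelerometer biases separable
from attitude error in the fusion filter. Attitude is level with yaw
along track and a small pitch oscillation (0.06 rad) at the wingbeat
frequency.

**IMU and GPS.** The accelerometer measures specific force in the body
frame, `f_b = Rᵀ(a − g) + v_wb + b_a + n`, where the wingbeat vibration
`v_wb` acts on the z axis as a fundamental (8 Hz, 3 m/s²) plus 2nd and
3rd harmonics at relative amplitudes 0.5 and 0.25. Gyroscope output is
the exact body rate (quaternion log-difference of the attitude series)
plus bias and noise. Noise magnitudes are MEMS-grade (accelerometer
0.04 m/s², gyroscope 0.001 rad/s per sample; constant biases of order
0.2 m/s² and 0.005 rad/s). GPS is the true ENU position plus isotropic
noise of 2.12 m per axis, the per-axis sigma equivalent of a 2.5 m
circular error probable.

**LFP.** Each channel is a 1/f background (40 µV RMS, flat below 1 Hz)
plus a gamma (30–80 Hz) component of 20 µV baseline RMS. Two planted
effects make the analysis recoverable by construction:

* gamma power follows `1 + gamma_slope · a(t)` with
  `gamma_slope = −0.08` per m/s² (clipped at a 5% floor), producing the
  decreasing gamma-proportion trend;
* channels form two groups of four (the 2×4 electrode geometry); each
  group shares a gamma source with mixing fraction
  `ρ(t) = 0.15 + 0.025·a(t)²` (capped at 0.85) plus a weak source
  (0.05) common to all channels. Measured magnitude-squared coherence
  between within-group channels is ≈ ρ², giving the U-shaped
  coherence/clustering trend with realistic peak coherence ≈ 0.5.

The planted magnitudes are free parameters of the emulation (no
published effect sizes exist for this preparation); they were chosen so
the effects sit clearly above the estimation noise of one ~2-minute
trial — the weakest signal regime the sign-recovery tests must resolve —
while keeping band proportions and coherence in physiologically
plausible ranges. A wingbeat artifact equal to `artifact_gain` (40 µV
per m/s²) times the z-axis vibration waveform contaminates the recorded
but not the clean LFP, together with a slow baseline drift. What the
generator does *not* emulate: wingbeat frequency drift, non-stationary
artifact coupling, inter-subject variability, electrode impedance
differences, and any real neural dynamics beyond band-limited Gaussian
processes. Tests passing on these data therefore demonstrate the
*machinery* (recovery of planted structure under realistic noise), not
biological claims.

## Sensor fusion

The error-state Kalman filter integrates a nominal state (attitude
quaternion, velocity, position, biases) with bias-corrected IMU samples
and estimates the 15-dimensional error state about it. Attitude error
uses the multiplicative small-angle convention on the body side;
`Φ = I + F·dt` is the first-order discretization of the continuous
error dynamics at the IMU period (5 ms). GPS position fixes enter
through `H = [I₃ 0]`; the covariance update uses the Joseph form, which
preserves symmetry and positive semidefiniteness, and the estimated
error is folded into the nominal state and reset after every update.

Noise defaults follow the configured sensor noise and the 2.5 m CEP
(`Q` from per-sample accelerometer/gyroscope noise and small bias random
walks of 10⁻³ m/s²·√s and 10⁻⁵ rad/s·√s; `R = (2.12 m)²·I₃`).
Initialization fits a least-squares line through the first 2 s of GPS
fixes for position/velocity (a two-fix difference would inherit
~30 m/s of noise), takes yaw from that track direction, and starts
level with zero biases; initial sigmas are 3 m, 3 m/s, 0.2 rad,
0.01 rad/s, 0.3 m/s².

The scalar "flight acceleration" used by all downstream stages is the
tangential component `a·v̂` of the gravity-free acceleration, low-pass
filtered at 5 Hz (zero phase). The cutoff sits below the 6–10 Hz
wingbeat band and above the ≲1 Hz timescale of behavioural
acceleration episodes, so the wingbeat vibration that necessarily leaks
into the specific force does not contaminate the behavioural variable.
The full acceleration vector is also reported for users who prefer the
magnitude. On default synthetic conditions the filter reaches
~0.13 m/s² acceleration RMSE (raw GPS double-differencing: ~130 m/s²)
and recovers planted accelerometer biases within a few percent over
120 s.

## Segmentation and QC

States follow fixed thresholds — speed > 2 m/s and acceleration
> +0.5 m/s² (acceleration), within ±0.5 m/s² closed (steady), or
< −0.5 m/s² (deceleration); slower windows are excluded. Windows are
1 s long. For *export and visual inspection* the default step is 0.5 s;
*all statistical analyses and decoding use non-overlapping windows*
(step = 1 s). This is deliberate: overlapping windows share half their
samples, which (a) makes binned-regression confidence intervals
anti-conservative (measured null-slope coverage dropped to 8/10) and
(b) leaks realization content between cross-validation train and test
folds, inflating decoding accuracy in every band. Trial QC fails a
recording when any stream has > 5% missing samples, speed stays below
2 m/s for > 5 s, or the maximum cross-track deviation exceeds twice the
start-to-end chord; thresholds are configuration values, since the
underlying criteria are qualitative.

## Wingbeat-artifact suppression

The LFP is band-passed 0.5–200 Hz (zero-phase Butterworth), then each
channel is decomposed into K = 10 modes by VMD (ADMM formulation;
bandwidth penalty α = 2000, tolerance 10⁻⁷, 300-iteration cap, centre
frequencies initialized uniformly over the half-band — zero
initialization collapses modes at DC on multi-tone signals). Each mode
is compared with the z-axis accelerometer stream (linearly upsampled to
1000 Hz) by DTW on z-normalized non-overlapping 2 s chunks with a
Sakoe–Chiba band of 10% of the chunk, distances averaged per mode; the
DTW dynamic program is numba-compiled and verified against an
exhaustive pure-Python table.

A mode is attenuated to weight 0.1 when it is a robust low outlier in
DTW distance (below median − 1·MAD) **and** synchronous with the
reference (|Pearson r| > 0.1). The synchrony gate is essential: a 200 ms
warp window spans more than one flap cycle, so any narrowband mode near
the flap frequency can be warped onto the reference regardless of phase
— DTW distance alone cannot distinguish a phase-locked artifact from
independent neural activity in the same band, while time-locked
correlation separates the two by more than an order of magnitude
(|r| ≈ 0.85/0.42/0.20 for artifact fundamental/harmonic modes versus
< 0.02 for clean modes on the generator).

The output is `x − (1 − w)·Σ(flagged modes)`, i.e. the attenuated
portion of flagged modes is subtracted from the input rather than the
signal being rebuilt as a weighted mode sum. This keeps the VMD
residual untouched, so a recording without artifacts passes through
exactly. The subtracted estimate is additionally low-passed at 30 Hz:
the artifact model (fundamental + harmonics, ≤ 24 Hz at an 8 Hz flap
rate) has no energy above that edge, whereas the spectral tails of
flagged modes are coherent with retained gamma activity and would
otherwise shift gamma band power by ~10% through the cross-term. On
default synthetic recordings this achieves ≥ 20 dB suppression at the
flap fundamental with < 3% gamma-band change.

## Spectra, networks, statistics

Band proportions are Welch-PSD power integrals over δ 0.5–4, θ 4–8,
α 8–13, β 13–30, γ 30–80 Hz, normalized by the power over the union of
bands; only the gamma edges are dictated by the scientific question,
the others are conventional. Welch uses 0.5 s Hann windows with 50%
overlap inside each 1 s analysis window, and proportions are averaged
across the 8 channels (per-channel output is available). The CWT uses
the analytic Morlet (`cmor1.5-1.0`) with the standard scale-to-frequency
mapping.

Coherence networks extend each 1 s window symmetrically to 2 s so
that 7 Welch segments (0.5 s, 50% overlap) are averaged — magnitude-
squared coherence from a single segment is identically 1, so averaging
is mathematically required. The band-averaged gamma coherence matrix is
binarized by keeping the strongest 30% of pairs (ties at the cutoff are
kept; zero entries never form edges), and the clustering coefficient is
computed per node with `CC_i = 0` for degree < 2, the network mean taken
over all nodes. Proportional (rather than absolute) thresholding keeps
graph density comparable across windows; an absolute-threshold mode is
provided. Because a *uniformly* elevated coherence is invisible to
density thresholding, the recoverability of the network trend rests on
the grouped (within- vs cross-group) structure of the planted coherence,
which matches the electrode-array geometry.

Group comparisons use one-way ANOVA when every group passes Shapiro–Wilk
at α = 0.05 and Kruskal–Wallis otherwise; zero-variance groups force the
non-parametric branch. The empirical type-I error of this two-branch
protocol is within [0.03, 0.07] under Gaussian nulls (1000 replicates).
Trend regression bins a per-window metric by acceleration (0.5 m/s²
half-open bins over [−6, 6), bins with < 5 windows dropped), fits an
ordinary least-squares polynomial to the bin means (order 1 for the
gamma proportion, order 2 for clustering), and reports t-based 95%
pointwise and coefficient intervals. No multiple-testing correction is
applied across bands.

## Decoding

Datasets are balanced by random undersampling, so the three-class chance
level is exactly 33.3%. Epochs are 1 s, band-filtered, per-channel
demeaned. The margin classifier and the shallow network operate on 36
moment features (8 log band-powers + 28 channel correlations); the
convolutional model applies 48 seeded random kernels (length 32) with
ReLU max/positive-proportion pooling and a logistic readout — a
random-kernel convolutional classifier standing in for a trained CNN,
since the published architectures for this task are not specified beyond
figure panels. Feature scaling lives inside each model pipeline and is
fitted on training folds only; this is verified against a hand-rolled
train-only-scaling cross-validation in the tests. Absolute accuracies
on synthetic data are not comparable to any published animal-data
values; the meaningful readouts are the band ordering (gamma highest)
and the calibration of the chance level.

The empirical chance level is estimated by averaging repeated-CV mean
accuracy over 20 label permutations × several balanced-undersample
draws. A single permuted draw at ~90 windows carries ±5–6 percentage
points of realization luck — the classifier finds, then
anti-generalizes, spurious structure of that particular draw — so a
single-permutation estimate cannot resolve a ±3-point band around
33.3%; the permutation average is the standard permutation-null
estimator and converges to 32–34% on default conditions.

## Problem sizes and numerical notes

Default trials are 120 s (the scale of a real 2 km homing flight);
artifact-suppression analyses and their tests run on 40 s recordings
and the end-to-end reproducibility check on 15 s, sizes at which every
result above is stable. VMD may hit its iteration cap on broadband
signals; it then returns the current (deterministic) iterate with a
warning flag, and with τ = 0 its mode sum reconstructs tones exactly
but splits broadband noise between modes and residual — another reason
the denoiser subtracts flagged modes instead of re-summing. Degenerate
inputs are defined explicitly: constant series are maximally dissimilar
in DTW (infinite distance, never flagged), silent channels make their
coherence rows undefined (NaN, never edges), identical groups compare
at p = 1, and an all-flagged mode set refuses to denoise rather than
annihilate the signal.

## Known limitations

* The generator's stationary Gaussian construction cannot probe
  robustness to non-stationary artifacts, frequency-drifting wingbeats,
  or cross-frequency coupling; the denoiser's synchrony gate in
  particular assumes a stable artifact phase over each trial.
* The ESKF assumes a loosely-coupled GPS position observation; velocity
  or raw-measurement coupling, RTS smoothing and magnetometer fusion are
  out of scope.
* Binned-trend inference treats bin means as independent; this holds
  for non-overlapping windows of band-limited power but would break for
  metrics with memory longer than a window.
* Decoding magnitudes depend strongly on window counts; with ~30
  windows per class, ±2 percentage points of run-to-run variation in
  mean CV accuracy is expected even at fixed seeds when any protocol
  detail changes.
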