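# Methods

This note documents the models, numerical choices and known limitations of
`motorstates`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external data.

## Behavioral metrics

Cursor and target positions are 2-D time series in degrees of visual angle,
sampled at 100 Hz with trial spans of 10–30 s. Metrics are computed per
trial and averaged into non-overlapping epochs tiled within each trial
(final partial window dropped); the default epoch is 7 s for decoding and
100 ms for timescale analysis. The epoch statistic is the arithmetic mean of
per-sample values.

- **Tremor.** The cursor trace is bandpass filtered 3–10 Hz (4th-order
  Butterworth, zero-phase forward–backward so the envelope is not phase
  distorted), projected onto its first principal axis per trial (the
  dominant tremor axis; this makes the metric rotation invariant to < 1%),
  and the amplitude of the analytic signal (Hilbert) is the instantaneous
  tremor amplitude in degrees. Trials shorter than three filter time
  constants (3 / f_low = 1 s at the default band) are skipped.
- **Speed.** Euclidean norm of the central-difference derivative of the
  3 Hz-lowpassed cursor, in deg/s. The lowpass removes the tremor
  contribution (a 1 deg, 5 Hz oscillation perturbs a 4 deg/s drift estimate
  by under 2%). Mean instantaneous speed is used rather than net
  displacement over the epoch.
- **Slowness.** Within-session min–max normalization of epoch speed,
  `(max − v) / (max − min)`, so 0 is the session's fastest epoch and 1 its
  slowest. A session with constant speed is rejected as degenerate.
- **Effective motor control.** `emc = ((1 − tremor_norm) + (1 − slowness)) / 2`
  with tremor_norm the per-session min–max of epoch tremor. The min–max
  choice for tremor is a design decision: the composite requires both inputs
  on [0, 1] while raw tremor is in degrees, and a per-session normalization
  keeps the metric comparable across subjects with very different tremor
  amplitudes. Its consequence is that emc is only meaningful relative to the
  session's own range.

## State dynamics

Metrics binned at 100 ms are characterized by the biased autocorrelation of
the mean-subtracted series, normalized to 1 at lag 0. The full width at
half maximum (FWHM) is twice the positive-lag 0.5-crossing, linearly
interpolated between bins; it serves as the minimum duration for a
*sustained* symptomatic episode. Episodes are maximal runs of strictly
supra-threshold bins (ties at the threshold are sub-threshold) lasting at
least the FWHM; thresholds are supplied by the caller (95th percentile of
pooled control data for tremor/slowness, session median for emc). Episode
durations are summarized by a gamma maximum-likelihood fit with the
location fixed at the minimum duration, plus the empirical median; MLE was
chosen because its parameter recovery is directly testable (shape 2.0
recovered within [1.8, 2.2] at n = 2000).

## Spectral features

Neural signals are conditioned to a 1 kHz reference: optional common-median
re-referencing across an ECoG strip, 2–600 Hz bandpass, notches at 60 Hz
and harmonics up to 540 Hz (Q = 30, applied zero-phase), and polyphase
anti-aliased resampling.

Instantaneous power comes from a complex Morlet convolution, wave number
w = 7, at 1 Hz steps covering 3–400 Hz (398 rows). The implementation works
in the frequency domain: a Morlet wavelet of centre frequency f has a
Gaussian transfer function with spectral s.d. f/w, so each row is one
spectral multiply plus an inverse FFT, with the bank normalized so a pure
sinusoid of amplitude A yields envelope A at its own row (verified to 2% in
tests; off-row leakage at ±1 octave is < 0.1%). For epoch-mean power the
package uses an exact decimation: each row's analytic signal is band-limited
to its Gaussian window, so inverse-transforming only that window at a
power-of-two length P reproduces the signal subsampled with stride nfft/P;
epoch means over the decimated grid match full-resolution means to ~0.1%
and cut the cost roughly four-fold.

Rows are grouped into six canonical bands — θ/α 3–12, β 12–30, γ_low 30–60,
γ_mid 60–100, γ_high 100–200, hfo 200–400 Hz — each split into 7 sub-bands
with log-spaced edges (matching roughly log-spaced spectral axes), for 42
features per epoch. Feature values are log10 mean power by default
(config-switchable to linear). The hfo band is treated as broadband power
(a multiunit-activity proxy), not discrete ripples. Coherence features use
Welch magnitude-squared coherence (Hann windows, 1024-sample segments,
512-sample hop) averaged into the same 42 bins; a sub-band narrower than
the Welch grid (only the lowest θ/α sub-band at 1 kHz) takes its nearest
frequency bin. Epochs shorter than two Welch segments are dropped.

## Decoding

A linear ε-insensitive support-vector regression maps the 42 features to a
behavioral metric. Hyperparameters are C = 1.0 and ε = 0.1 on standardized
data (features and target z-scored per training set; predictions
de-standardized) — library defaults, exposed in the API. Monte-Carlo
cross-validation draws 100 random 2:1 train/test splits of epochs by
default (a contiguous-block split is available for leakage sensitivity
checks); out-of-fold predictions are pooled per epoch by averaging across
the folds holding that epoch out, and performance is the squared Pearson
correlation between pooled predictions and the observed metric. Model
weights are the per-fold mean on the standardized scale, which makes them
invariant to rescaling any raw feature column. Chance level is the r²
distribution of models refit with the training-set metric permuted within
each fold.

Cross-metric transfer applies a frozen model to a different metric and
reports sign(r)·r², so anti-correlated transfer is negative (a plain r²
cannot be negative, which would make "inverted fingerprint" and "unrelated
fingerprint" indistinguishable). Whole-trajectory models split each depth's
epochs 2:1, train one SVR on the pooled training portions, score on the
pooled test portions, and report per-depth r² of the shared model's
predictions within each depth; depths with fewer than three epochs are
excluded.

## Weight inference

Per recording, the 42-feature weight vector is smoothed with a centred
3-feature moving average (edges truncate to the available neighbors);
smoothing and the contiguity rule both run over the full ordered feature
axis, crossing band boundaries. The empirical statistic is the paired
t-value across recordings of (condition A − condition B) per feature, where
the conditions are empirical vs. metric-shuffled models, or two metrics'
models. The null swaps each recording's condition pair with probability 1/2
per iteration — equivalently sign-flips its difference row — which is
vectorized by noting the per-feature sum of squares is flip-invariant.
Two-sided empirical p-values use the add-one rule, Benjamini–Hochberg
correction is applied at q = 0.05, and runs of ≥ 3 contiguous surviving
features are reported with the sign of the mean difference. The test
refuses fewer than 5 recordings (the sign-flip null has at most 2^n
distinct values) and fewer than 1000 iterations. Calibration: under
exchangeable inputs the uncorrected per-feature significance rate is
0.05 ± 0.02 and empirical p-values are super-uniform (KS-tested).

## Spatial mapping

Per-recording decoding r² values are assigned to 1 mm³ voxels by site
coordinate (voxel value = mean of contained sites). The A-vs-B contrast
uses a recording-level sign-flip null: per permutation each recording's
(A, B) assignment is swapped, all its site differences change sign, and
voxel means are recomputed; Z = (observed − null mean) / null s.d. per
voxel. This is a deliberately simplified permutation scheme — no
cluster-size inference and no atlas masking; coordinates are abstract
millimetres, and surface-vertex analyses reuse the machinery with vertices
as voxels. With one recording per voxel the per-voxel Z saturates near ±1
(the null is ±d), so Z carries the sign of the contrast but not its
magnitude; the reported signed peaks are therefore located on the paired
difference map itself and annotated with their Z.

## Mixed models

Population contrasts are random-intercepts linear mixed models,
y = Xβ + Zu + ε, one intercept per subject, fit by REML (statsmodels
MixedLM); inference is Wald, Z = β/se against the normal distribution.
Categorical predictors are dummy-coded against the first level; singular
designs are rejected with the collinear columns named. The default
optimizer occasionally converges to a degenerate boundary (zero
random-effects variance), so the fit falls back through optimizers and is
calibrated in tests (slope recovery and a 5% ± 3% type-I rate).
Benjamini–Hochberg correction is a thin wrapper with monotonicity tested.

## Synthetic generator

The generator defines the study conditions; its defaults are fixed, not
tuned per experiment.

- **Latent dynamics**: a three-state Markov chain {tremor, slow, effective}
  at 100 ms resolution. Default transition matrix gives mean dwell times of
  ~2 s (tremor), ~0.67 s (slow) and ~3 s (effective) with stationary
  occupancy ≈ 0.25/0.12/0.63 — tremor episodes of seconds, slow episodes
  sub-second, echoing the distinct-timescale structure of the two cardinal
  signs. State indicators are smoothed with a 200 ms raised-cosine ramp to
  avoid filter ringing at state edges.
- **Behavior** (100 Hz): the target follows a random smooth path at
  constant baseline speed (4 deg/s) — heading is an integrated
  Ornstein–Uhlenbeck process with a soft restoring pull toward the
  workspace centre. The cursor tracks it first-order (rate 4 s⁻¹, catch-up
  speed capped at 1.3× target speed); the slow state scales the tracking
  rate down by 70–90%, so the cursor trails the curvy target and cuts
  corners, persistently lowering mean cursor speed. A curvy path matters:
  on a low-curvature path a lagging cursor catches up along nearly the same
  arc and epoch-mean speed barely drops. The tremor state adds a sinusoid
  (default 5 Hz) of amplitude `tremor_gain` along a fixed random axis, plus
  0.01 deg white measurement noise. Injected 3–10 Hz cursor band power
  scales as tremor_gain² (tested to 10%).
- **Neural** (1 kHz, the post-downsample rate; the 22–44 kHz acquisition
  stage is skipped as it adds nothing testable): each channel is
  spectrally-shaped 1/f white noise plus band-limited components (4th-order
  Butterworth-filtered independent noise) whose envelope is
  1 + slope × metric, with the latent metric normalized to [0, 1] and
  upsampled to the neural clock. `slope` therefore plays the role of an
  envelope SNR. Optional shared band-limited components in two channels
  create metric-gated coherence. Site maps place recordings on a 1 mm grid
  along a spatial axis with coupling slopes varying linearly (clipped at
  zero) along it.

What the generator does **not** emulate: 1/f knees and spectral peaks
unrelated to behavior, non-sinusoidal or amplitude-varying tremor,
movement artifacts, electrode drift, volume conduction between sites, and
any calibrated match to real patient effect-size distributions (the
relevant raw data are not public). Passing tests therefore demonstrate
internal correctness and recoverability under the stated statistical
structure, not clinical performance.

## Validation battery sizes

`scripts/acceptance.py` and the mirror tests run at desk scale, chosen as a
balance of Monte-Carlo error against runtime on a single CPU: decoder
recovery uses 20 repeats of 100-epoch sessions with 25 CV folds and 50 null
models; weight-test calibration uses 100 repeats × 1000 iterations with 20
recordings; spatial recovery uses 20 repeats of 36-epoch sessions at 6
sites with opposed full-range gradients (tremor slope 0→4 dorsally,
slowness 6→0, the larger slowness base compensating its intrinsically
weaker epoch-level expression); LMM calibration uses 20 recovery repeats
(20 subjects × 50 observations) and 200 type-I repeats. Rates estimated
from 20 repeats carry a binomial s.d. of ~0.07 near 0.9.

## Known limitations

- The slowness metric is intrinsically noisy at 7 s epochs because slow
  episodes are sub-second: epoch means average most of the signal away.
  This bounds slowness decoding r² well below tremor's at equal envelope
  SNR, as visible throughout the examples.
- The sign-flip voxel test with singleton voxels yields saturated Z values;
  peak coordinates are meaningful, magnitudes are not.
- ε-insensitive SVR with pooled-fold prediction leaves ~1% unexplained
  variance even on noiseless realizable targets (fold-specific spurious
  weights inside the ε-tube).
- No nonlinear decoders, no phase-based synchrony, no spike sorting, no
  imaging registration — all out of scope by design.
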