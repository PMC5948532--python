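# Methods

This note documents the models behind `semgkit`, the parameter choices
that matter, and what the synthetic experiments can and cannot show.

## Signal model

Raw sEMG on electrode c is generated as

    x_c(t) = a · ( Σ_k W_ck · s_k(t) · ξ_k(t) + b(t) ) + n_c(t)

where

* `W` (8×5, dimensionless) are non-negative spatial loadings.  The five
  sources stand for the forearm muscles FR, ER, ED, EU, FU; each column
  peaks at one electrode (2, 4, 5, 6, 8 in 1-based numbering) with 0.25
  on ring-neighbouring electrodes and 0.05 two steps away.  Amplitudes
  are arbitrary units throughout (no physical calibration exists for
  the bracelet).
* `s_k(t)` is the activation envelope: the gesture's per-muscle
  template level, ramped linearly over 100 ms at transitions (avoids
  step transients), multiplied by slow (~1 Hz low-pass, 15 % sd)
  within-gesture execution noise and a per-repetition log-normal level
  jitter (20 % sd) — both independent per muscle.  These two
  variability terms are what makes the muscles statistically separable,
  exactly as trial-to-trial variability does in real recordings.
* `ξ_k(t)` is a zero-mean, unit-variance 20–450 Hz band-limited
  Gaussian carrier, independent per source — the standard
  amplitude-modulated surrogate for raw sEMG (the interface only ever
  uses windowed RMS, so higher-order raw-signal structure is
  irrelevant).
* `b(t)` is physiological background noise (sd 0.05), attenuated
  together with the signal; `n_c(t)` is electrode-referred sensor noise
  (sd 0.15) that does **not** scale with the tissue gain.
* `a ∈ (0, 1]` is the subject's attenuation. The body-fat index is the
  linear, monotonically decreasing map `BF = 44 − 40·a`, so the
  generator's attenuation range (0.15, 1.0) spans BF 4–38 %.

Gesture templates: flexors (FR, FU) drive flexion/left, extensors (ER,
EU, and ED at full level) extension/right, the radial pair (FR, ER,
plus ED at 0.6) radial deviation/up, the ulnar pair (EU, FU, ED 0.6)
ulnar deviation/down.  Diagonal gestures use the sum of their two
parents' templates scaled by 1/√2, keeping total power comparable.
Antagonist co-activation adds `c ×` the *opposite* gesture's template
(c ∈ [0, 1) is the subject's co-activation factor): a poorly
coordinated subject contracts antagonists along with synergists, which
is precisely what lowers the measured SAC and blurs the class
structure the classifier relies on.

## Feature extraction

Trailing (causal) 200 ms windows advanced by 100 ms; the frame
timestamp is the right window edge and partial leading windows are
dropped.  Frame labels are the majority sample label in the window;
frames spanning a gesture transition can be discarded
(`drop_transitions=True`, used throughout the pipeline since the
synthetic protocol uses static gestures).

## Classifiers

The gesture network is 8 inputs → 8 logistic-sigmoid hidden units → 4
logistic outputs (ql, qr, qu, qd), trained full-batch on the mean
squared error against the compound targets with learning rate 1.0,
uniform(−0.5, 0.5) seeded initialization, and biases included (a
`bias=False` option reproduces the bias-free neuron equation exactly).
Training runs at most 5000 epochs and keeps the weights of the
held-out-error minimum, stopping once that minimum is 50 epochs old —
a literal "stop as soon as test error increases" rule is fragile under
frame-level noise.  An optional 7-output encoding adds fist/palm/rest
class neurons.

Inputs are deliberately **not** renormalized per subject by default:
the interface is modeled as calibration-free, so a low-amplitude
(high-BF) subject's features genuinely sit closer to the sensor-noise
floor.  A `normalize="max"` option (per-channel max of the training
RMS) is available.

The LDA baseline classifies the four basic gestures from the same RMS
vectors (scikit-learn, SVD solver); a singular pooled covariance is
reported as an error suggesting the shrinkage (`regularize=True`)
re-fit rather than silently regularizing.

## Muscle-source separation and SAC

The source model treats the RMS envelope vector as a linear mixture of
muscle activations.  Two numerical facts shape the implementation:

1. For independent carriers the windowed *powers* add linearly across
   sources (`V_c² ≈ Σ_k W_ck² s_k²` + noise power), whereas RMS
   amplitudes add in quadrature.  The decomposition therefore runs on
   the squared envelopes, where the linear model is exact, and reports
   loadings/activations as square roots of the power-domain factors.
2. Synergists share the gesture on/off structure, so their envelopes
   are strongly *correlated*; ICA cannot separate correlated sources.
   The fast within-gesture fluctuations, however, are independent per
   muscle.  The unmixing matrix is therefore estimated by FastICA on
   the first-differenced power stream (differencing suppresses the
   slow shared structure) and then applied to the full stream.
   Because the power model is also non-negative, the solution is
   refined by a short non-negative matrix factorization initialized at
   the ICA estimate: ICA resolves the rotational ambiguity NMF alone
   would have, NMF enforces the non-negativity ICA ignores.  On
   simulated recordings this recovers all five sources with
   activation correlations 0.95–0.98; plain ICA on raw envelopes
   recovers only three or four.

Components are ordered by explained variance with peak loadings made
positive.  `m=5` by default; the automatic mode sizes the model from
the PCA spectrum of the differenced powers and retains components that
explain ≥5 % of the variance and peak at an unclaimed electrode.  The
source-localization protocol repeats the four basic gestures eight
times (3 s holds) — repetitions carry the independent trial-to-trial
variance the separation feeds on.

SAC itself never uses the ICA factors: the localization argument
justifies reading electrodes 2, 4, 6, 8 directly as FR, ER, EU, FU
(ED, electrode 5, is excluded), and per basic gesture the two
synergist and two antagonist electrode means form
`SAC = ln(¼ Σ_k S_k/A_k)`.  A pure gain on the recording cancels
exactly.  Two caveats: (i) the log-of-mean form is exactly
antisymmetric under swapping synergist and antagonist roles only when
all four ratios are equal (Jensen's inequality otherwise); (ii) with a
fixed sensor-noise floor, strong attenuation compresses the measured
ratios toward 1, so in this generator the measured SAC is not fully
decoupled from the body-fat factor at the low-SNR end — the exact
gain-invariance statement applies to a recording seen at two gains,
not to two subjects with different tissue but identical muscles.

## Proportional control

`P_max` comes from an explicit maximal-effort calibration stream and
the drift threshold `p_th` is the 95th percentile of the relative rest
power — rest-state muscle-tone jitter then moves the cursor on at most
5 % of frames, and those moves are marginal.  Displacement is applied
once per 100 ms feature frame with the printed gain of 20 screen units.
Screen axes: x rightward, y upward, origin bottom-left.

## Pursuit game and decision analysis

The simulated trial runs at a 100 ms control tick in an 800×600 arena;
the target walks a way-point polyline at constant speed (60 u/s) and
reappears at a random way-point when caught (catch radius 20).  The
simulated user perceives the game state `reaction_delay` seconds late,
aims at the optimal interception direction, perturbs it with Gaussian
angular noise, and quantizes to the nearest of the eight directional
gestures.  Articulation errors are modeled as *delayed evocation*:
with the per-gesture error probability a newly needed gesture only
appears ~0.5 s late while the previous one persists — so the late
gesture lands outside the optimal-decision cone, reproducing the
signature of a "problematic" gesture (high incorrect rate, normal
overall rate).  In the full pipeline the emitted output vector q comes
from the subject's own trained network applied to a held-out feature
frame of the intended gesture, and the effort from that frame's mean
power — classification errors therefore propagate into game play and
the score (targets caught in 120 s) degrades with the subject's E_MS.

Analysis of a trace: decimate to ≤100 points at ≈50 ms-scale spacing
(positions at the retained instants; q block-averaged over each
retained interval so the intent vector δ = (qr−ql, qu−qd) lives on the
same timescale as the finite-difference velocities), estimate
velocities by forward differences, solve the interception quadratic
`(||ω_c||² − ||ω_p||²)t² + 2(d·ω_c)t + ||d||² = 0` for the smallest
positive root (falling back to the one-step lead direction when none
exists), and form the signed angle α (counter-clockwise positive)
between the cursor velocity and the best direction.  Frames where the
target teleports (respawn after a catch) belong to no pursuit
trajectory and are excluded.  Circular statistics summarize α by the
modal histogram bin (36 bins of 10°) and the circular standard
deviation; with mean resultant length < 0.1 the peak is flagged
unstable.  Gestures are optimal when `(δ, n)/||δ|| > 0.6` (a cone of
arccos 0.6 ≈ 0.93 rad) and incorrect otherwise, and are attributed to
the left/right/up/down set of their dominant normalized δ component
when it exceeds 0.2 of that component's standard deviation — dominant-
component attribution keeps the eight sets disjoint, so the rates
(relative to the evaluated frame count L) sum to at most 1.

## Study conditions

The default cohort draws, per subject, co-activation ~ U(0.15, 0.45),
attenuation ~ U(0.15, 1.0), reaction delay ~ U(0.15, 0.45) s, angular
noise ~ U(0.1, 0.5) rad, and a common per-gesture articulation error
rate ~ U(0.02, 0.15).  Each subject performs a training and a testing
recording with three repetitions of every gesture (2 s holds, 1 s
rests).  Under these conditions a 20-subject cohort lands at median
E_MS ≈ 0.019–0.022 with a subject range of roughly (0.007, 0.08), a
Re-on-SAC slope near −1.6, and a Re-on-BF slope of +0.02 to +0.04 per
percent body fat — the three regression signs (Re falls with SAC,
rises with BF, score falls with Re) are significant at p < 0.05 in
nearly every replicate cohort.  These sizes were fixed once for the
study design; the seeds of every stage derive from the single
configured cohort seed, so reruns are byte-identical.

## What the synthetic tests do not show

The generator emulates the statistical structure the analysis assumes
— localized linear mixing, co-activation, tissue attenuation against a
fixed noise floor, execution variability — not forearm physiology.  It
contains no motor-unit discharge structure, electrode lift/shift,
sweat, fatigue drift, or learning within a session; subjects are
stationary processes.  Passing tests therefore validate the analysis
chain (features → classification → indices → decision statistics) and
the internal consistency of the latent-factor story, not the clinical
generalizability of any particular coefficient value.  Absolute game
scores are in package units (targets caught per trial) and only the
sign of their relation to Re is meaningful.
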