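# Methods

This note documents the models, algorithms and design choices behind
`insolecg`, in the order the protocol runs.

## Problem setting

The whole-body center of gravity (CG) moves along three axes during a gait
cycle: a monotone advance in the walking (anterior/posterior, AP)
direction, a single side-to-side oscillation (medial/lateral, ML), and a
double-bump vertical curve (proximal/distal, PD) whose two maxima coincide
with the mid-stance instants of the two legs. The package estimates this
3-axis trajectory over a 100-frame normalized gait cycle from an 18-channel
plantar-pressure insole (9 piezo-resistive sensors per foot, 100
samples/s), using a phase-branched bidirectional LSTM trained on cycles
with motion-capture-grade reference trajectories.

## Synthetic gait generator

No public dataset pairs this insole layout with reference CG trajectories,
so the package bundles a generator that emulates the study conditions and
serves as the test bed for every downstream stage.

**Event schedule.** Gait events live on the normalized cycle: left
toe-off near frame 12 and left heel strike near frame 50, each with
independent integer jitter of +/-3 frames per trial (standard
double-support proportions from the gait literature). Right toe-off is
derived as `lhs + lto` (both double supports equally long), and the two
mid-stance events as the midpoint of each foot's single support (near
frames 31 and 81 by default) — i.e. both fall at stance fraction 1/2 of
the respective foot. This coupling is essential: mid-stance must be a
deterministic function of the contact timing that the pressures encode,
otherwise the phase boundaries (and the CG curve anchored to them) would
carry irreducible jitter that no pressure-based model could recover.

**CG trajectory.** AP is a linear advance at the subject's walking speed
plus a small (3 mm) smooth ripple that preserves monotonicity. ML is a
single sinusoid peaking at right mid-stance whose peak-to-valley (PV)
range is the subject's ML amplitude. PD is a piecewise-cosine curve
anchored at the events (valleys at the heel strikes, peaks at the
mid-stances), so its two local maxima fall exactly on the mid-stance
frames; its PV range is the subject's PD amplitude. Subject amplitudes are
drawn from group distributions matching reference values for healthy young
and elderly male cohorts: ML 45.25 +/- 2.53 mm (young) vs 64.32 +/- 2.87 mm
(old); PD 41.36 +/- 2.11 mm (young) vs 46.84 +/- 2.72 mm (old). This
builds the old-greater-than-young sway contrast into the data by
construction.

**Pressures.** Each sensor's stance-time activation is a Gaussian bump
under a contact envelope, sequenced rear -> midfoot -> forefoot -> hallux,
zero during swing, scaled so the summed peak force is 1.1 x body-weight
force. The subject's ML and PD amplitudes deterministically modulate the
medial-vs-lateral and forefoot-vs-rear loading balance, so with noise
disabled the pressure-to-CG mapping is a well-defined function — the
learnability guarantee the model-recovery tests rely on.

**Noise.** Additive Gaussian noise on pressures (sd 2% of peak force,
clipped at zero) and white measurement noise on the CG markers (sd
0.3 mm). Both are high-frequency by nature and are attenuated by the
Butterworth filters; a low-frequency drift term was deliberately not used
because a lowpass filter cannot remove it.

**What the generator does not emulate:** inter-subject variability of
pressure waveform shapes beyond amplitude modulation, pathological gait,
sensor drift and hysteresis, double-support asymmetry, and any coupling
between walking speed and sway. Passing tests therefore demonstrate that
the pipeline recovers a learnable phase-locked mapping under realistic
group structure and noise — not performance on real human data.

Raw trials are generated at 100 samples/s with cycle durations of
1.0-1.2 s (100-120 raw frames) and pass through the real preprocessing
path. The raw samples span the same continuous interval as the 100
normalized frames, so events land on their scheduled frames after
resampling.

## Calibration

Piezo-resistive sensors respond nonlinearly; the voltage-to-force law is
fitted per sensor as `F = a exp(bV) + c` by nonlinear least squares,
initialized from a log-linear regression. The offset `c` defaults to zero
(it absorbs a sensor baseline when freed). The fit stores its Pearson
correlation and RMSE (N) against the calibration points. The synthetic
pipeline skips calibration — generated pressures are already forces.

## Preprocessing

* 4th-order Butterworth lowpass, applied forward-backward (zero-phase):
  7 Hz on pressures, 10 Hz on CG channels. Zero-phase filtering is not
  stated by most insole protocols but any phase lag would desynchronize
  inputs from targets. Cutoffs are fixed configuration values.
* Cycles are right-heel-strike to right-heel-strike, half-open `[hs1,
  hs2)` so consecutive cycles tile without duplication.
* Time normalization to 100 frames by linear interpolation on a uniform
  grid including both endpoints (first and last samples preserved).
* Pressures divide by body-weight force (kg x 9.81 N); a pure-mass
  variant is config-selectable (the convention only rescales inputs).
* The CG is expressed in a gait-local frame: origin at the double-support
  midpoint (mean ground-plane CG over the initial double support), x along
  the horizontal walking direction (estimated from the net horizontal CG
  displacement), z vertical, y = z x x. It is then divided by leg length;
  the mm version is kept for metric reporting.
* Filtered pressures are clipped at zero: zero-phase filtering overshoots
  slightly below zero at sharp stance onsets, and downstream stages assume
  nonnegative loads.

## Insole parameters and feature candidates

Each foot contributes 15 per-frame parameters — 9 sensor pressures, rear /
mid / forefoot zone sums, total sum, and the two center-of-pressure (COP)
coordinates — 30 in total. The default layout places 2 heel, 2 midfoot and
5 forefoot sensors at nominal adult-foot coordinates and is replaceable
via CSV. The COP is the pressure-weighted mean of sensor positions; when
the foot is unloaded (total below 0.1% of body-weight force) the last
valid COP is held, because a jump to an arbitrary value would poison the
windowed statistics.

A 5-frame sliding window (stride 1, left edge padded by replicating frame
0) yields 7 statistics per parameter — average, max, min, range, mean
absolute deviation, kurtosis, skewness — for 210 windowed features;
adding each parameter's raw value at the window's last frame gives 240
candidates per frame. Zero-variance windows define kurtosis and skewness
as 0 (constant swing-phase windows would otherwise be undefined).

## Gait phases and the phase classifier

The cycle splits into four contiguous phases at right mid-stance, left
heel strike and left mid-stance; boundaries coincide with the poles of the
vertical CG curve, so each phase has homogeneous CG mechanics. In the
synthetic data, ground-truth mid-stance is the vertical-CG maximum per
stance (the kinematic hip/ankle definition is unavailable without
markers).

At inference time an SVM assigns phases from the 240 candidates. The
candidate hyperparameter grid spans C in {0.1, 1, 100, 1000}, kernels
{rbf, poly, sigmoid, linear}, degrees 1-6 and gamma in {1, 0.1, 0.01,
0.001, 0.0001}; grid search uses subject-level folds (frames of one
subject never straddle folds). The pipeline default is the degenerate grid
holding the known optimum (C = 1, rbf, gamma = 0.1), which makes training
a plain fit. Inputs are min-max scaled to [0, 1] first — the same 0-1
convention used for the network. This matters: with 240 standardized
(z-scored) inputs, squared distances concentrate near 480 and
`exp(-0.1 d^2)` vanishes, collapsing an RBF SVM to a majority-class vote;
on 0-1 scaled features the kernel is well-conditioned at gamma 0.1.

Predictions pass through a contiguity repair: a 5-frame majority vote
removes isolated flips, then dynamic programming finds the monotone
1->2->3->4 block segmentation (each phase non-empty) minimizing
disagreement with the smoothed labels. The repair only enforces the
4-block structure when all four phases survive smoothing, so partial-cycle
fragments are left as smoothed. The branched network requires contiguous
segments; the repair guarantees them.

## Feature selection

Per phase, each candidate is scored by its mutual information (MI) with
each CG axis over the phase's pooled training frames:

    I(X, Y) = sum p(x, y) log2 [ p(x, y) / (p(x) p(y)) ]

with both variables discretized into 10 equal-frequency bins (the discrete
MI needs a binning rule; equal-frequency bins make the score invariant to
monotone rescaling of a candidate). Per-axis scores are min-max scaled to
[0, 1] across the 240 candidates and averaged over the three axes;
ranking is by descending score with candidate-index tie-breaks for
determinism.

The per-phase feature count k is chosen by a validation objective: for
each k in the candidate range (default 5-30), one RBF support-vector
regressor per axis (C = 1, epsilon = 0.01, gamma scaled) is fitted on the
phase's training frames restricted to the top-k candidates, and the mean
3-axis rRMSE on held-out-subject validation frames is recorded; the
smallest k attaining the minimum wins and the whole k-to-error curve is
retained. Features and targets are min-max scaled to [0, 1] (training
constants) before the SVR: leg-length-normalized ML/PD excursions are
~0.05, far inside any reasonable epsilon tube, so without scaling the
objective is blind on two of three axes. The epsilon of 0.01 matters for
the same reason — a 0.1 tube on 0-1 targets exceeds the 2-3% error the
regressor can reach, flattening the k-to-error curve so that the
smallest-k tie rule starves the branches. Training frames are subsampled
(default 2000) to bound the SVR cost; smaller subsamples make the chosen
k unstable.

## Augmentation

Training cycles are expanded four-fold (raw + three augmented copies):

* **jittering** — white Gaussian noise (mean 0, sd 0.03) on the
  weight-normalized pressures;
* **time-warping** — a cubic spline through 4 random speed knots
  ~ N(1, 0.2) (clamped >= 0.1 so the map stays monotone) is integrated to
  a strictly increasing time map fixing both endpoints; pressures, CG
  targets and phase labels are all resampled along the same map, keeping
  input-target alignment;
* **pooling** — a centered 3-frame moving average with edge replication
  (resolution reduction at constant length).

Jittering and pooling leave targets untouched. Magnitude-domain
augmentation is deliberately absent: rescaling intensity would corrupt the
amplitude cues the CG targets depend on. Per-trial operator seeds derive
from one master seed.

## The CG network

Inputs and targets are min-max normalized to [0, 1] with training-set
constants (exact affine inverse; values outside the training range map
outside [0, 1] without clipping; constant channels map to 0).

**Proposed (phase-branched) architecture.** Each phase's frames,
restricted to that phase's selected features, pass through an independent
stack of two bidirectional LSTM layers with 64 and 32 units. The four
per-frame branch outputs are reassembled in time into one 100-frame
sequence, pass through a combined trunk of two bidirectional LSTM layers
(32, 32), and a per-frame affine head with sigmoid activation produces the
3 axes. The sigmoid is interpreted as the output activation (targets are
in [0, 1]); the LSTM cells keep their conventional internal gating — a
sigmoid in place of the cell nonlinearities would cripple gradient flow.

Phase segments vary in length between trials, so each branch is padded to
the longest training segment plus a 6-frame margin, with masked steps
implemented as exact identity updates of the hidden and cell state (the
margin covers the +/-3-frame event jitter on both segment boundaries;
without it, held-out cycles with a slightly longer phase would be
rejected). Padded frames are cropped before temporal reassembly. A cycle
whose segment exceeds even the margin raises an error advising to retrain
with longer padding.

**Baseline (unbranched) architecture.** The same layer budget — {64, 32}
then {32, 32} bidirectional LSTM layers — over the whole 100-frame cycle,
fed with whole-cycle-selected features (none / RFE / MI / elastic net).

**Recurrent core.** The bidirectional LSTM, backpropagation through time,
Adam, and the callbacks are implemented in numpy inside the package
(`insolecg.bilstm`), with the per-timestep recurrences JIT-compiled via
numba when available (a pure-numpy fallback keeps the package functional
without it). Gradients are verified against central finite differences in
the test suite, including through masked steps. Training uses
mean-squared-error loss, Adam with batch size 10 and initial learning rate
0.001, an epoch cap (1000 by default), halving of the learning rate after
20 epochs without validation improvement (floor 1e-5), early stopping
after 50 such epochs, and restoration of the best-epoch weights. Runs are
deterministic for a fixed seed under single-threaded BLAS.

## Evaluation

Per axis and trial: Pearson correlation, RMSE in mm, and rRMSE — RMSE as
a percentage of the reference axis's PV excursion over the cycle. The
excursion normalizer (rather than the mean) is the default because the
three axes' excursions differ by an order of magnitude; a mean-normalized
variant is config-selectable. Correlations are summarized as mean with
(min-max) range, errors as mean +/- sd, pooled and per group.

By default the branched model is evaluated with phase labels from the
kinematic events, mirroring how the reference trajectories themselves are
segmented; the pressure-only classifier is assessed as its own component.
(`use_predicted_phases=True` switches to classifier-driven phases end to
end, the deployment condition. The difference is small but systematic:
boundary misplacements of 1-2 frames sit exactly on the vertical-CG
peaks, the most error-sensitive frames of the cycle.)

The comparative study trains all methods with identical subject splits,
seeds and budgets. RFE recursively drops the least important fifth of
remaining candidates (importance = summed absolute coefficients of one
linear SVR per axis) until k remain; the elastic net (L1/L2 mixing 0.5,
penalty path cross-validated) keeps features with a nonzero coefficient on
any axis; MI ranks whole-cycle candidates as in the per-phase procedure.
A method whose training diverges is reported as failed while the others
continue.

Group analysis compares young vs old PV ranges of the ML and PD axes with
a Welch two-sample test and reports the direction of the difference.

## Problem sizes and defaults

The standard study conditions are 15 + 15 subjects x 3 trials: 26 subjects
(13 + 13) train, 1 + 1 validate, 1 + 1 test per cross-validation fold,
giving 78 training cycles -> 312 after augmentation (31,200 frames) and a
3,000-frame 5-fold test pool. The bundled recovery study
(`run_recovery_study`) runs this split with a 100-epoch cap, which is
where validation loss has long plateaued on synthetic cohorts. The
feature-count search uses the grid {5, 10, 15, 20, 25, 30}. Unit tests use
smaller cohorts and narrower networks where the property under test does
not depend on scale.

## Known limitations

* The 30-parameter roster reconstructs the named features of the source
  protocol (sensors, zone sums, totals, COP); the original enumeration is
  not public, so the mid-zone sum is an interpolation to reach 15 per
  foot.
* The discrete-MI binning rule (10 equal-frequency bins) and the SVR
  settings of the k-search are package choices; rankings can shift under
  other estimators.
* Synthetic cohorts are far cleaner than real gait data; absolute metric
  values here do not transfer to hardware recordings.
* The classifier-driven phase segmentation feeds the branched model at
  test time; segmentation errors beyond the padding margin (very long
  predicted phases) abort prediction rather than degrade it silently.
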