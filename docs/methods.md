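# Methods

This note documents the models, procedures and design choices behind
`avoidspace`, in the spirit of a methods appendix: what each stage
assumes, which parameters matter, what the synthetic data do and do not
emulate, and where the design was genuinely open.

## 1. Data model and units

All signals live on a shared 5 Hz clock (`DT` = 200 ms): per-subject
ΔF/F trace matrices (cells × time), five tracked body points (px), a
binary tone trace and a trial table (tone on/off, alignment time, trial
type, task, day, shuttle class). Speeds are px/s; no cm calibration is
applied. Movie-stage preprocessing assumes registered input at any frame
size; the canonical acquisition it models is 1000×1000 px at 20 Hz,
reduced by 2× spatial and 4× temporal block averaging.

## 2. Imaging preprocessing

Order of operations: block-average downsampling → rank-2 bleaching-model
subtraction → spatial lowpass division → ΔF/F. The bleaching model is
fitted by PCA on a temporally smoothed copy of the movie (boxcar, default
50 frames; the smoothing window is exposed because only "temporal
smoothing" is specified, not its form) and the original movie's
projection onto the smoothed movie's mean + two leading spatial
components is subtracted. Because the subtraction is an orthogonal
projection of the mean-removed movie, total variance never increases.
The lowpass normalisation divides each frame by its Gaussian blur
(σ = 7 px); it must run on raw positive intensities, hence its position
before ΔF/F. Multi-session traces are rescaled to the minimal session
s.d. so later sessions with different SNR do not dominate.

Duplicate components (one neuron split in two by the extraction step)
are flagged by Pearson correlation strictly above 0.7 **and** centroid
distance strictly below 20 px; of each flagged pair the member with the
smaller trace s.d. is excluded (the rule had to be chosen; larger s.d. is
taken as the better-isolated component). A greedy pass in descending
s.d. order guarantees that no flagged pair survives chains A~B~C.

## 3. Trial alignment

Shuttle starts are refined from a detected midline-crossing time to the
timepoint of maximal speed increase within the preceding 2 s (ties →
earliest, for determinism). Avoid trials with latency < 3 s are
discarded whenever a window reaching 3 s before shuttle start is used.
Error trials receive *pseudoshuttle* alignment times resampled with
replacement from the avoid-latency distribution clipped to [3 s, 9 s];
the resampling is redrawn per analysis repetition. Shuttle type (X / Y /
XY) is judged by any midline sign change within [−1 s, +2 s] of the
event; the window had to be chosen and spans the full crossing motion.
"Random ITI periods" — the null class for ITI decoding — are 4-s windows
at least 4 s from every tone and shuttle.

## 4. Subject alignment

Six condition averages per subject (avoid/error × task over concatenated
tone-start [−1, 3) s and shuttle-start [−3, 1) s windows; ITI shuttles
over [−4, 4) s) are stacked over subjects, row-centred per cell within
each condition block (the centring is interpreted per cell; it removes
per-cell baseline before PCA), normalised to unit Frobenius norm and
concatenated (240 samples). The left singular vectors give the
coefficient matrix; subject blocks are orthonormalised by unpivoted QR
so dimension indices remain comparable across subjects. Signs follow a
fixed convention (largest-magnitude coefficient positive, positive QR
R-diagonal), making repeated fits bit-identical. k = 10 by default:
large enough to leave degrees of freedom for five coding dimensions,
small enough to align well across subjects.

Trials are split 50/50 into an alignment half and a decoding half so the
alignment step cannot leak class information into decoders; the split is
redrawn per analysis repetition at the study level (within one
decomposition the split is fixed and the repetitions resample trials and
timepoints from the decoding half).

The per-dimension alignment-quality score is the mean pairwise Pearson
correlation, across subjects, of a dimension's projected condition-
average time course; the exact statistic used for this diagnostic was
not specified upstream, and this correlation-based score is the
documented stand-in.

## 5. Decoding

Linear max-margin classifiers (hinge loss, C = 1; `sklearn.svm.SVC`
with a linear kernel), five-fold stratified CV, classes balanced by
subsampling without replacement (300 per class at full scale; 100 per
class in the desk-scale studies; a 150/150 train/test split replaces CV
for per-day evaluation). No feature standardisation is applied —
subspace projections are already variance-controlled; a config flag can
enable it. Avoid trials whose tone turns off within the post-shuttle
second are excluded at the affected time steps via a validity mask so
decoders cannot exploit tone-off information.

Uncertainty: analyses are repeated (typically 80×) with fresh trial
samples; the 95% CI is the 3rd and 78th of the 80 sorted values, and for
other n the floor-based ranks ⌊0.025 n⌋+1 and n−⌊0.025 n⌋. Significance
is CI nonoverlap. The ITI control selects the ten fastest ITI shuttles
per session, matching the kinematic information (as measured by
five-point speed-vector "video decoders") between the avoid and ITI
settings.

## 6. Coding-dimension decomposition

Motion dimensions: PCA of the ITI-shuttle averages (both tasks
concatenated, k × 80) in the joint subspace; the first two define the
motion nullspace (they carry the bulk of ITI variance). Avoid
dimensions: iteratively, a time-independent avoid/error decoder is
trained on one uniformly sampled timepoint per trial from the
shuttle-start window, in the current nullspace; the unit-normalised
weight vector, mapped back through the nullspace basis, is the next
dimension. The tone dimension repeats this for tone-on (first 5 s,
pre-shuttle only in avoid trials) versus the 1-s pre-tone baseline, in
the nullspace of motion-1/2 and avoid-1/2. The canonical basis keeps
two motion, two avoid and one tone dimension plus the orthonormal
residual; five motion and five avoid dimensions are still produced for
removal curves.

Open choice, resolved: whether the canonical dimension vector comes from
one decoder fit or from many was unspecified. Single fits are noisy at
small scale, so each dimension is the principal eigenvector of the outer-
product sum of the per-repetition unit weight vectors (the average that
is invariant to each hyperplane's arbitrary sign), oriented along the
repetition majority; 160 repetitions by default in the pipeline driver.
Sign-aligned arithmetic averaging was rejected as unstable when
individual repetitions are noise-dominated.

## 7. Population metrics

Weight entropy uses base-2 logs (bits; maximum log₂5 ≈ 2.32 for five
dimensions); a cell's weights are its P_s row mapped onto the coding
basis, absolute-normalised to sum 1. Relative VE is normalised within
the k-dimensional subspace. The tone-drop point is the 0-based index of
the step before the maximal consecutive decrease; the drop percentage at
lag L is 100·(x_noshuttle(L) − x_shuttle(L))/x_noshuttle(L), where the
no-shuttle reference uses alignment times resampled to match the shuttle
latency distribution, and the tone dimension is oriented so its
session-wide projection correlates positively with the tone trace.

## 8. Synthetic cohorts

The generator plants five latents — two motion ramps tied to every
shuttle, one avoidance ramp shared across tasks, one avoidance signal
only in task-2 avoid trials (with its own, faster temporal profile:
distinct coding dimensions carry distinct dynamics, and identical
profiles would make the two avoid latents indistinguishable within
task 2), and a tone step whose amplitude decays from 2 steps (400 ms)
after shuttle start over 2.2 s, putting the decrease at 1.2 s near 36%.
Latents are mixed into cells by dense Gaussian, column-orthonormalised
loadings (mixed selectivity, full rank) plus i.i.d. Gaussian noise.

Key defaults and why:

* 3 subjects × 60 cells; sessions mirror the paradigm's in-task days —
  two task-1 sessions (days 3, 4) and five task-2 sessions (days 5–9),
  50 trials each. The 2:5 task imbalance is a feature of the paradigm:
  it determines which avoidance direction the pooled decoders find
  first. Habituation/extinction days are omitted; no analysis stage
  consumes them.
* shuttle latencies uniform on [3 s, 9 s]; tone off 1 s after an avoid
  shuttle; 30 ± 10 s ITIs; spontaneous ITI shuttles with p = 0.35 per
  interval; 57.3% of task-2 avoid shuttles are Y, the rest XY; half of
  task-2 error trials contain an incorrect X shuttle (motion and tone
  drop with the tone staying on — the trial set on which the drop
  percentage is measured).
* `noise_sigma` = 0.15: with orthonormal loadings over 60 cells a unit
  effect spreads to per-cell amplitudes ≈ 0.13, so single-cell
  transients sit near unit SNR — visible in individual traces, as
  validated cells are.
* smooth background locomotion (σ = 0.4 of ramp peak, ~1 s timescale)
  is added to the motion latents in all sessions: animals move
  continuously, so motion is an imperfect proxy for trial outcome.
  Without it, motion alone decodes avoid vs error almost perfectly and
  removing avoidance dimensions would barely change avoid decoding.

What the generator does **not** emulate: calcium-indicator dynamics
(traces are generated directly at ΔF/F level, temporally white noise),
cross-session cell-tracking errors, non-Gaussian noise, electrode/optics
drift, behavioural idiosyncrasies beyond the smoothstep shuttle
kinematics, and any learning dynamics within a phase. Passing tests
therefore demonstrate the correctness and calibration of the analysis
machinery under the planted model, not performance on real recordings.

## 9. Numerical choices and degenerate inputs

Orthonormality is asserted to 1e-8 throughout; PCA/QR signs follow the
deterministic conventions above; ties in argmax-style operations resolve
to the earliest index. Zero-norm condition blocks, zero-variance
sessions, constant traces (undefined correlations), rank-deficient
bleach models and eventless ITI averages raise or warn explicitly
rather than propagating NaNs. The rank-CI rule requires ≥ 4 repetitions.

## 10. Problem sizes used in the validation studies

The bundled studies run at desk scale, chosen to keep the full suite
and the acceptance script in the minutes range on one CPU: 3 × 60-cell
cohorts, 100 trials per class per decoder, 8–10 CI repetitions for
removal curves, 20 cohort seeds for the recovery study and 20 runs for
the null calibration. At this scale the recovery of the task-2-specific
avoid direction is the statistically limiting quantity (median ≈ 20°
over seeds; the other four directions recover within 4–13°); larger
cohorts tighten it, more repetitions alone do not.

## 11. Known limitations

* The iterative avoid-dimension decoder inherits every class difference
  that survives the motion nullspace — including the planted
  behaviour-gated tone drop, which is genuinely avoid/error-informative.
  A small tone component in avoid-1 (~0.13 loading) is therefore
  expected, not a bug.
* `alignment_quality` is a documented stand-in statistic (see §4).
* Dimension labels within a family (motion-1 vs motion-2; avoid-1 vs
  avoid-2) are identified only up to rotation by planted structure;
  recovery is accordingly evaluated against the family span.
* The CLI layer is intentionally absent: the library functions and
  `scripts/acceptance.py` are the interface.
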