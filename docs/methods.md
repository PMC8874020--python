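# Methods

This note documents the models, procedures and numerical choices behind
`painfusion`: a pipeline that synthesizes multimodal cold-pressor
recordings, reduces them to per-window features, classifies pain states
with a two-stage SVM cascade, and fuses per-sensor scores with weights
learned by a genetic algorithm.

## Study design being emulated

A cohort of subjects (default 26) each completes three repeated days.
Each day starts with a 20-s relaxed baseline recording of all sensors,
followed by iced-water immersion split into 20-s sessions.  After every
session the subject reports pain on a 0–10 verbal rating scale (VRS);
the day ends after ten sessions or when the subject withdraws.  Nine
modalities are recorded: facial action-unit probabilities (FE, 30 Hz),
EEG (500 Hz), pupil diameter (EM, 50 Hz), skin conductance, blood volume
pulse, EMG, skin temperature and respiration (2048 Hz), and blood
pressure as exactly two cuff readings per day (pre/post).  Windows are
labeled **B** (baseline, or a session rated 0 — "no pain" on the VRS),
**LP** (VRS 1–5) or **HP** (VRS 6–10).

## Synthetic cohort model

The generator is two-layered.

**Latent window model.** Every 20-s window has per-modality feature
targets

    target = subject_baseline + effect_size × code × noise_sd + N(0, noise_sd)

where `code` is the pain-level class code (B=0, LP=1, HP=2), so
`effect_size` is a standardized mean shift per class step.  Subject
baselines are population means plus Gaussian random effects.  Default
directions encode the qualitative physiology the pipeline is built
around: skin conductance (+0.6), pupil diameter (+0.6), systolic
blood-pressure delta (+1.2) and parietal EEG log band power (+0.8 in all
five bands) respond positively; skin temperature (−0.4) and
centro-parietal alpha/beta/gamma power (−0.5) respond negatively; facial
AU4/AU9/AU10 carry the largest effect (+0.8) with no effect on AU45
(blink); heart rate, EMG amplitude and respiration rate are null.  The
magnitudes were chosen once so that the cohort sits in a realistic
operating regime — 5-fold macro-F1 around 0.73–0.86, clearly away from
both chance and ceiling — with inter-individual differences (subject
random effects of the same order as window noise, and for EEG a global
spectral offset of SD 0.3 plus independent per-channel-band offsets of
SD 0.4) dominating enough that cross-subject generalization is visibly
harder than within-subject generalization.

**VRS trajectory.** Latent pain grows as a saturating exponential
`10·(1 − exp(−r·sensitivity·k))` over session index `k` (r = 0.25),
perturbed by multiplicative lognormal noise (log-SD 0.15), shifted up by
1 rating point on day 1 (subjects are least acclimatized on the first
exposure), then rounded and clipped to [0, 10].  Sensitivity is
lognormal across subjects (log-SD 0.3, median 1).  After a rating
strictly above the subject's tolerance (uniform on [7, 10]), the subject
withdraws with logistic probability in (vrs − tolerance); at or below
tolerance the withdrawal probability is exactly zero, so a tolerance of
10 deterministically yields ten sessions.

**Signal renderer.** Each window's latent targets are realized as raw
samples at the published sampling rates: AU probability series as
clipped Gaussian jitter around the target mean; EEG as a sum of five
band-limited noise components (4th-order Butterworth band-pass of white
noise) rescaled so each band's variance equals the exponential of the
latent log-power; pupil diameter as low-pass (≤2 Hz) noise rescaled to
the latent window SD, keeping sample-to-sample velocity physiological;
BVP and respiration as sinusoids at the latent heart/breathing rate with
additive noise; SC/ST as the target mean plus a slope centered on the
window midpoint plus small measurement noise; EMG as white noise with
the latent RMS.  The extractors recover the latent targets up to
averaging error over tens of thousands of samples, verified by the
rendering fidelity tests (e.g. a configured standardized SC shift of 1.0
is recovered within ±0.2 over 200 rendered windows per class; a doubled
gamma-band variance doubles estimated gamma power within ±20%).

Monte-Carlo evaluations at cohort scale (cross-validation replicates,
significance screens) sample the latent layer directly via
`simulate_features`; rendering all nine modalities at 2048 Hz for
hundreds of cohort replicates would add nothing statistically, since the
latent layer is the distribution the extractors recover.  On-disk
datasets (`generate_dataset`) always go through the renderer.

**What the generator does not model.** No biophysically realistic
waveform morphology (no heart-rate variability spectra, pulse-wave
shapes, electrodermal response kinetics), no ocular/muscle artifacts in
EEG by default, no within-window nonstationarity beyond linear slopes,
and no rating–physiology feedback.  Passing tests therefore demonstrate
that the analysis recovers the statistical structure it assumes — effect
directions, subject heterogeneity, class geometry — not that it would
reach the same numbers on real recordings.

## Feature extraction

* **EEG**: zero-phase 6th-order Butterworth band-pass 1–50 Hz
  (forward–backward, ≥20 dB one octave beyond the edges), then Welch
  averaged periodograms (2-s Hann segments, 50% overlap) integrated over
  the half-open bands delta [1,3), theta [4,8), alpha [8,13), beta
  [13,30), gamma [30,50) Hz.  The [3,4) gap between delta and theta is
  deliberate and mirrors the printed band definitions; energy there
  belongs to no band.  Features are log band powers
  (variance-stabilizing; effects are specified on the log scale).
* **Pupil**: velocity-based artifact rejection — samples adjoining a
  first-difference velocity above 10 mm/s, plus one neighbor each side,
  are linearly interpolated from the nearest clean samples; an error is
  raised if more than half the window is flagged.  The filter is
  idempotent on its output.  Features: window mean and SD.
* **BVP / respiration**: peak detection (prominence 0.3 of the window
  range) with refractory distances 0.33 s and 1.5 s respectively; rate =
  60·(n_peaks − 1)/(t_last − t_first).  Fewer than two peaks is a
  data-quality error, not a feature.
* **SC / ST**: window mean and least-squares slope per second (time
  origin at window start).  **EMG**: RMS of the mean-removed window.
  **FE**: column-wise mean of the 17 AU probability series.
* **BP**: only two cuff readings exist per day, so the post−pre systolic
  and diastolic deltas are broadcast to every window of that day.

## Cascade classification

Features are z-scored with training-set statistics.  Stage 1 (RBF SVM,
C = 1, bandwidth by the median pairwise squared-distance heuristic,
inverse-frequency class weights — baseline windows are ~1 in 11)
separates B from {LP, HP}; stage 2, trained only on pain rows, separates
LP from HP.  Each stage's margin is calibrated by a Platt-style sigmoid
(logistic fit on training margins).  Routing: stage-1 probability below
0.5 yields B without consulting stage 2; ties at exactly 0.5 break
toward the higher-pain branch at both stages, so pain is never
under-called at a boundary.  The continuous sensor score is
`p(pain)·(1 + p(HP|pain)) ∈ [0, 2]`, the expected class code, which puts
per-modality outputs on the same scale as the fusion truth.

## Decision-level fusion

The fused score is `fs = Σᵢ wᵢ sᵢ` over the nine sensor scores with
weights constrained to the unit simplex (nonnegativity and unit sum are
imposed for identifiability and to keep `fs` on the class-code scale).
The "true score" is the class code 0/1/2.  Weights are learned by a
real-coded GA: population 50, at most 50 generations, crossover rate
0.8 (arithmetic blend), per-gene mutation rate 0.02 (Gaussian, SD 0.1),
tournament selection (size 3), one elite, simplex projection after every
operator.  Fitness is lexicographic: first the number of windows whose
|fused − true| exceeds a threshold of 0.5 class-units (half the spacing
between adjacent codes), then mean absolute error as tie-break.  By
default the GA spends its full generation budget refining the MAE;
stopping as soon as the violation count reaches zero is available via
`GAConfig.stop_on_zero_violations` but leaves the weights wherever the
threshold was first satisfied, which on planted-weight problems is far
from the optimum.  On two-sensor problems the GA matches an exhaustive
0.01-step simplex grid search to within 10% MAE, and it recovers planted
weights (0.7/0.3 among seven noise sensors) to the first decimal.

The modality-set ablation holds out ~30% of subjects, trains
per-modality cascades on the rest, learns weights per set (excluded
modalities pinned to zero), and reports held-out confusion matrices and
per-class F1 for: all nine modalities; EEG+FE only; everything except
EEG and FE.

## Evaluation and significance

Cross-validation operates on 20-s windows: stratified 5-fold (seeded,
redrawn once if a training split loses a class) and leave-one-subject-out
(per-class F1 averaged over folds where the class occurs in the test
subject).  Macro-F1 — the unweighted mean of per-class F1 — is the
single-number summary.

The significance screen tests each summary feature across the three
states with a repeated-measures one-way ANOVA on the subject-by-state
mean table (subjects as blocks; F = MS_state/MS_interaction, df =
(2, 2·(n_subjects − 1)); subject df = n_subjects − 1, i.e. 25 at the
default cohort size).  Day is pooled into the subject-state mean.  The
implementation is validated against an independent repeated-measures
ANOVA routine.  Blood-pressure deltas carry no within-day state
variation, so they are tested as a one-sample t on subject-mean deltas,
reported as F = t².  Raw p-values are primary; a Bonferroni column is
appended for convenience.  Because subjects contribute unequal window
counts per state, the state-mean sampling variances are unequal (a mild
sphericity violation); the measured per-feature type-I rate under a
zero-effect generator stays within [0.02, 0.08] at α = 0.05.

## Problem sizes and determinism

Every random draw descends from a single seed through spawned seed
sequences, so datasets, CV partitions and GA runs are bit-reproducible;
regenerating an on-disk dataset with the same seed yields byte-identical
files.  The bundled analyses use the default cohort (26 subjects × 3
days, ≈680–860 windows): ten seeded cohort replicates for the
cross-validation and fusion comparisons, one hundred replicates for the
significance pattern, and two hundred for type-I calibration — sizes at
which every Monte-Carlo check above has comfortable resolution while the
whole suite runs in a few minutes on one CPU.

## Known limitations

* Per-sensor scores feeding the GA are computed in-sample on the
  training subjects; weights can favor modalities whose cascades overfit.
* Frame-level facial-expression classification is not implemented; all
  modalities are classified at the 20-s window level.
* The default 8-channel montage has no true centro-parietal electrodes;
  C3/C4 proxy that region (the 32-channel montage maps CP1/CP2/CP5/CP6).
* ICA-based EEG artifact removal is replaced by the (optional)
  amplitude-threshold screen; the default generator injects no
  artifacts, so the pipeline's robustness to real ocular artifacts is
  untested.
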