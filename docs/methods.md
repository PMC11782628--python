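# Methods

`memtrace` implements, end to end and against simulated ground truth, the
analysis chain used to study how memory errors drive the upregulation of
stimulus representations during associative learning: a feedback-based
face–orientation association task and a face/house 1-back localizer are
simulated as BOLD time series; univariate GLMs localize memory-error
signals; least-squares-separate (LSS) deconvolution yields single-trial
betaseries; a localizer-trained, probability-calibrated classifier reads
out face-processing evidence from a fusiform-like ROI during memory
epochs; and a linear mixed model links that evidence to encoding demand
and subsequent recall success.

## Task model

**Association task.** 5 runs × 8 faces × 4 presentations = 160 trials.
Each trial contains four epochs — recall (face alone, 2.5 s), confidence
selection (1.0 s), feedback (0.8 s, after a 0.2 s delay) and re-encoding of
the correct face–gabor pair (1.5 s) — followed by an inter-trial interval
jittered uniformly on 2.5–6 s (the assumed jitter law; only the range is
specified by the task). Re-presentations of the same face occur at least 2
and at most 15 trials after the previous one; schedules are built by a
randomized greedy sequencer with deadline forcing and bounded restarts.
The recall and confidence phases are self-paced in the scanner task; their
durations here are fixed design parameters (2.5 s / 1.0 s) chosen as
plausible medians, and epoch onsets follow the stated durations in
presentation order.

**Localizer.** 5 runs × 16 trials; 2 new faces and 2 new houses per run,
four presentations each, stimulus duration 1.5 s, same ITI jitter. Exactly
2 trials per run are direct repetitions of the immediately preceding
stimulus/gabor pair (never the first trial, never a triple); the task is
to press only on repetitions, giving hit / miss / correct-rejection /
false-alarm trial types and, under optimal behavior, 70 correct rejections
across the task.

## Behavioral model

Recall accuracy follows a logistic learning curve in presentation number
`k`: `P(correct) = expit(logit(1/8) + λ·(k−1))`. The default
`λ = 1.7622` is the analytic solution making the mean accuracy across the
four blocks exactly 59.35%, the regime the generator emulates; first
presentations are pure guesses at the 12.5% chance level. Confidence is
high with probability 0.8014 on correct trials and low with probability
0.7622 on errors. Meta-memory d′ is the z-difference of the
confidence-conditional hit and false-alarm rates; boundary rates are
adjusted by one trial's proportion (1 → 1−1/n, 0 → 1/n) to keep z finite.
The bias measure is the criterion c = −(z(hit)+z(fa))/2, labeled as such
because the bias convention is otherwise underdetermined. Localizer
exclusion uses the scalar performance (hit rate + CR rate)/2 and removes a
participant strictly below cohort mean − 2 SD.

## BOLD forward model

Volumes are a 12 × 12 × 10 grid at 2.2 mm isotropic (the acquisition voxel
size at desk scale), TR 2 s. An 18-voxel contiguous block stands in for
the face-selective mid-fusiform ROI; face and house response patterns are
random non-collinear vectors with the face pattern stronger on average, so
face-preferring voxels exist for ANOVA selection. Each pattern-carrying
event contributes `amplitude × pattern × HRF-convolved boxcar`; the HRF is
the Glover double-gamma, evaluated through the same nilearn regressor code
used by every GLM in the package, which makes noise-free forward/inverse
recovery exact by construction. On association trials the face-pattern
amplitude is `base + demand_effect·demand + success_effect·success`,
scaled by a per-epoch gain. Nuisance structure: cosine drift with random
weights, motion/physiology-like confound signals (random walks and
jittered sinusoids) with random voxel loadings, and AR(1) Gaussian noise
(default lag-1 r = 0.3, stationary SD 0.35).

Two defaults were calibrated once, before the acceptance suite was
written, and are part of the study conditions the generator defines:

- **Noise SD 0.35** places default-condition localizer decoding in the
  low-70s% balanced-accuracy regime that comparable single-trial fMRI
  decoding attains — the regime the downstream analyses are meant to
  operate in.
- **Epoch gains (recall 1.2, encoding 0.7, ITI 0.15).** The stepwise LSS
  rule (below) leaves epochs *later* than the target unmodeled, and their
  signal projects with negative sign onto the residualized target
  regressor: noise-free, recall betas recover ~0.7× and encoding betas
  ~0.3× of truth when the following ITI carries signal, while ITI betas
  (fully modeled) are exact. Gains were therefore calibrated noise-free so
  that the *measured* amplitude gradient declines recall > encoding > ITI,
  emulating the declining face-prediction gradient across memory epochs.
  Naively decreasing raw gains can invert the measured encoding/ITI order
  through this estimation geometry.

## GLMs

Design matrices hold one HRF-convolved regressor per condition
(deterministic, sorted naming), confound columns, a cosine drift basis
with 128 s high-pass cutoff, and an intercept. Two association-task
variants mirror the two univariate analyses: recall (accuracy ×
confidence) + confidence (low/high) + feedback (valence); and recall +
confidence + encoding split by the (current, next) recall-outcome
transition, with feedback omitted for its temporal overlap with encoding.
Final presentations have no next outcome and form an `encoding_Last`
condition. Estimation is plain OLS per voxel (no prewhitening; AR(1)
prewhitening is an extension point), with rank-deficiency reported as an
error naming the collinear columns. Contrasts return effect, t, z
(two-sided tail-matching t→z map), partial R² = t²/(t²+df) and 95% CIs.
Collinearity diagnostics compute VIF per event regressor against the
other event regressors (flags at 5 and 10) and pairwise Pearson r (flag at
|r| ≥ 0.90).

## Group inference

Participant contrast maps are Gaussian-smoothed (8 mm default) before a
one-sample t per voxel (zero-variance voxels are capped, not infinite).
Thresholding is Benjamini–Hochberg FDR (q = 0.05) over in-mask voxels on
two-sided p-values, followed by removal of clusters below 5 voxels under
face (6-neighbor) connectivity — 53.24 mm³ at 2.2 mm isotropic.
Conjunction across contrasts intersects the thresholded maps and tests the
per-voxel minimum t statistic against a sign-flip permutation null:
participant signs are flipped identically across contrasts (valid under a
symmetric null and preserving between-contrast dependence), p < 0.05.
Sign flipping was chosen over label shuffling because the second-level
test is one-sample. Network overlap reports the fraction of significant
voxels per label of an integer parcellation, plus `unassigned`; a
seven-slab toy parcellation ships for pipeline runs.

## LSS betaseries

For each target trial one GLM is fit containing: the target event's
regressor, one nuisance regressor per included epoch aggregating all
other events of that epoch, confounds, drift and intercept. Epoch
inclusion is stepwise — recall: {recall}; encoding: {recall, encoding};
ITI: {recall, encoding, ITI}; localizer stimulus: {stimulus} — and
violating the rule is a specification error. GLMs are fit per run; events
never cross runs. Beta maps are smoothed (6 mm default) *after*
deconvolution, then masked voxels are extracted into the trial × voxel
betaseries (the alternative, smoothing raw data first, is a configuration
away via the extraction FWHM).

**Known bias.** With aggregated nuisance regressors, a single nuisance
coefficient cannot absorb other trials' amplitude heterogeneity, so
overlapping responses leak deterministically into the target beta. At the
task's native 2.5–6 s jitter the noise-free amplitude-recovery correlation
is ≈0.90–0.98; on a temporally separable schedule (ITI 14–18 s) it exceeds
0.99. Both numbers are reported by the acceptance script. With a single
event per run, LSS and the ordinary GLM coincide exactly.

## Decoding

Within the ROI betaseries of localizer correct rejections: per
leave-one-run-out fold, a StandardScaler and the feature selector are fit
on the four training runs only; the selector keeps the 14 voxels with the
largest one-way F among voxels whose face mean exceeds their house mean
(if none qualify, as can happen under label permutation, the top-F voxels
are used regardless of sign). A balanced, L2-regularized linear SVM
(C = 1) is scored by balanced accuracy, implemented as the mean of
per-class recalls. The full model refits scaler, selector and SVM on all
runs and adds Platt calibration (sigmoid, internal 5-fold CV via
scikit-learn's CalibratedClassifierCV with deterministic folds). Applied
to association-task epochs it yields a calibrated face probability per
trial; `predicted_class` is face iff probability ≥ 0.5 (ties to face). A
Spearman check verifies per participant that mean probability tracks the
face-prediction rate.

## Evidence–behavior linkage

Trials are coded by the transition between current and next recall
outcome for the same face: encoding demand = 1 for ErrorError/ErrorCorrect
and 0 for CorrectCorrect; subsequent recall success = 1 for
ErrorCorrect/CorrectCorrect and 0 for ErrorError; CorrectError trials and
final presentations are excluded. The mixed model regresses
face probability on demand + success with a participant random intercept
(REML, Wald z; random slopes were not specified and are out of scope); a
singular fit downgrades, with a warning, to OLS with participant-clustered
robust errors. Coefficients read directly as probability-scale increments.
A control variant restricted to error trials (success as sole fixed
effect) checks that the success effect is not carried by CorrectCorrect
trials. The whole-brain extension regresses every voxel's betaseries on
the participant-centered evidence (centering prevents a participant's
overall evidence level from leaking into the slope) and carries the slope
maps to the second level.

A probability-scale evidence generator (`simulate_evidence_table`)
bypasses the imaging stages: evidence = intercept (0.35) + Gaussian
participant intercept (SD 0.05) + 0.04·demand + 0.015·success + Gaussian
trial noise (SD 0.15), clipped to [0, 1] (clipping affects ~1% of trials
at these defaults and is negligible for the fits). It provides the exact
ground truth for mixed-model parameter recovery at 28 participants.

## What the simulation does and does not show

The generator reproduces the trial economy, learning dynamics,
confidence–accuracy coupling, HRF-convolved multivoxel patterns,
autocorrelated noise and nuisance structure of the study design. It does
not emulate real physiological noise spectra, spatial noise correlations,
anatomical geometry, inter-subject anatomical variability, or
non-stationary pattern drift. Green tests therefore certify the
*estimators and their calibration* (recovery of injected effects, nominal
false-positive rates, absence of train/test leakage), not the empirical
findings themselves.

## Problem sizes and numerical choices

Simulated grids are 12 × 12 × 10 voxels; calibration suites use 200 null
replicates with 500 permutations, decoding calibration 200 label
permutations, and mixed-model recovery 100 replicates of 28 participants —
sizes chosen so the whole suite and the acceptance script each run in a
few minutes on one CPU while keeping Monte-Carlo error well inside the
asserted tolerances. Degenerate inputs are handled explicitly: empty
conditions are dropped with a warning, zero-variance group maps cap t
rather than overflow, rates of 0/1 are one-trial adjusted, schedules that
cannot satisfy the gap constraints raise a schedule-infeasible error, and
permutation counts below 100 are refused as unstable.
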