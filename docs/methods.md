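# Methods

This note documents the generative model behind the simulator, the
estimation and decoding procedures, the numerical conventions, and the
design choices made where more than one reasonable option existed.

## The simulated experiment

The generator emulates a two-session slow event-related design. Session
1 runs pair body stimuli (visual run half) with voice stimuli (auditory
run half); session 2 pairs face with voice. Defaults
(`ExperimentDesign`):

| parameter | default | note |
|---|---|---|
| sessions × runs | 2 × 6 | 12 runs total |
| volumes per run | 160 at TR = 3 s | 480 s per run, halves of 240 s |
| trials per run half | 18 = 16 regular + 2 catch | |
| regular trials | 4 per emotion (anger, happy, neutral, fear) | order randomized per half |
| stimulus duration | 1 s | boxcar, not impulse |
| ISI | uniform on [10.7, 11.3] s | per-gap jitter |
| lead-in | 10 s | before the first trial of each half |
| actors | 4, round-robin | stored, no signal by default |

Catch trials occupy schedule slots and enter the GLM as a nuisance
regressor; their stimulus content (tone modulation / fixation change) is
orthogonal to the decoded labels and is not otherwise simulated. Which
half of a run is visual vs auditory is randomized per run under the
schedule seed. All subjects of one dataset share a single schedule:
the shared-label permutation test applies identical label
randomizations to every participant, which is exact only when trial
orderings are aligned across subjects.

## Ground truth and the hypothesis space

Effect regions are spheres in voxel space, each holding zero-mean,
unit-norm condition pattern vectors scaled by a per-region amplitude:

- `modality_region` — one pattern per stimulus category (face, body,
  voice). Modality (and category) is decodable; emotion is not.
- `emotion_{face,body,voice}_region` — one pattern per emotion, applied
  only to trials of that category, drawn independently per category.
  Emotion is decodable within that modality; nothing transfers across
  modalities.
- `supramodal_emotion_region` — one pattern per emotion shared by all
  categories. This is the configuration under which cross-modal
  decoding succeeds; leaving it out encodes the modality-specific
  hypothesis.

Overlapping regions are rejected unless explicitly allowed. With all
amplitudes at zero the generator produces pure noise — the null used
for chance calibration.

The default positive-control amplitude is 6.0. The pattern is unit-norm
over a region of ~33 voxels (radius 2), i.e. ~1.0 signal units per
voxel, against trial-beta noise of roughly 0.5–0.7 sd after GLM
estimation at sigma = 1 — a strong but not physically absurd multivoxel
effect, chosen so positive controls exercise the inference chain rather
than the detection threshold.

## Signal and noise model

A voxel's time series is

```
y(t) = baseline + Σ_trials a_v(trial) · h(t; onset, 1 s) + AR(1) noise + drift
```

where `h` is the 1 s boxcar convolved with the canonical double-gamma
HRF (peak delay 6 s, undershoot delay 16 s, unit dispersions,
peak:undershoot 6:1, 32 s kernel, peak-normalized; the continuous
kernel peaks near 5 s), built on a 0.1 s grid and read out at volume
times. Noise is stationary AR(1) Gaussian (defaults sigma = 1.0,
lag-1 autocorrelation 0.3) plus low-frequency cosine drift with random
coefficients (sd 0.5, 3 components) and a constant baseline of 100.
No physiological noise, motion artifacts, or acquisition physics are
simulated; passing tests therefore validate the statistical machinery,
not robustness to real-scanner artifacts.

## GLM estimation

Trial-wise betas use a least-squares-all model: one model per run with
every non-catch trial as its own regressor, plus catch, cosine drift
(128 s cutoff — the GLM-equivalent of high-pass filtering) and a
constant. At ISIs above 10 s with TR 3 s the trial regressors are
nearly orthogonal (interest-block condition number < 10), so per-trial
single-trial models would add complexity without benefit. Estimation is
plain OLS; no prewhitening (the AR(1) in the generator mildly inflates
beta variance but leaves estimates unbiased, and all group inference is
on cross-validated accuracies, not on GLM standard errors).

The condition GLM fits the 12 stimulus-category × emotion predictors
jointly across runs (interest columns shared, nuisance — block-start,
catch, 6 motion parameters, drift, constant — block-diagonal per run).
Conditions absent from a run are flagged, never zero-filled. Univariate
maps come from a per-voxel one-way repeated-measures ANOVA across
subjects on factor-level means (error term = subject × level
interaction; no sphericity correction). Smoothing (Gaussian, FWHM in
mm, per-axis voxel sizes honored) applies to the univariate path only;
decoding consumes unsmoothed betas.

## Decoding

The GNB classifier uses per-class feature means, maximum-likelihood
variances, and empirical priors. Variances are floored at
`1e-9 × pooled variance of that feature + 1e-12`: the floor is
per-feature (not a sphere-global mean) so that whole-ROI decoding,
single-voxel decoding, and the searchlight engine share one convention
— a searchlight at radius 0 is bit-identical to single-voxel GNB.
Prediction ties break toward the earlier class in the model's ordered
label set.

The searchlight uses the lattice metric ‖v‖² ≤ r² (radius in voxels,
not mm; 515 offsets at r = 5). Because GNB sufficient statistics are
additive over trials and independent across voxels, the engine computes
per-voxel per-fold class statistics once from run-wise sums, converts
them to per-trial per-class per-voxel log-density contributions, and
sums over sphere members with a sparse adjacency matrix — exactly
equivalent to fitting a GNB per sphere. Centers whose sphere ∩ mask
falls below `min_voxels` are NaN and excluded from group statistics,
never zero-filled. Fold accuracies are averaged with equal weights
(folds are equal-sized by design). Cross-modal tasks are a single
train/test split; the voice trials come from the session of the paired
visual category, and train/test overlap is an error.

## Group inference

One-sided tests throughout (above-chance accuracy is the only direction
of interest). Voxels with fewer than two defined subjects are
undefined. Zero-spread samples (e.g. saturated accuracies) get limiting
values (t = 0 or ±inf, p = 0.5/0/1) rather than NaN; exact zero spread
is detected by max − min, not by a floating-point sd test. FWE control
is Bonferroni by default with a max-statistic permutation option
(random-field theory is out of scope); FDR is Benjamini–Hochberg via
statsmodels. Cluster connectivity defaults to 26 neighbors
(configurable 6/18); cluster-level p values are reported only under the
permutation method.

The permutation test applies the *same* label randomizations to all
subjects, shuffling emotion labels only among the task's selected
trials and within run, which preserves leave-one-run-out fold balance
by construction. Per permutation the full per-subject cross-validated
decoding is re-run; a paired t map (true − permuted accuracy across
subjects) is computed per permutation; the n t maps are averaged and
thresholded (default t > 3.9). The "one paired-t map per permutation,
then average" reading is the only one under which a single averaged
group t map follows from a paired test.

## ROI analysis

ROIs are spheres (default radius 5 voxels) at the fixture table's
Talairach mm coordinates, mapped through the grid affine; bilateral
ROIs are unions of their parts. The published ROI sizes in the fixture
are informational (they derive from subject-specific localizers) and
are not reproduced. ROI decoding uses all ROI voxels as one feature
set, leave-one-run-out CV (single split for cross-modal), a one-sample
t against chance per ROI × task, and BH-FDR across the entire
ROI × task grid (per-column correction is a supported alternative but
across-grid is the default, and is flagged in the report). The 16 RDM
conditions are condition-averaged trial betas per subject, ordered
body / face / voice-session-1 / voice-session-2, each block anger,
happy, neutral, fear; dissimilarity is 1 − Pearson r, with
zero-variance patterns flagged as NaN.

## Reproducibility and problem sizes

Every stochastic stage draws its seed from a master seed via a fixed
`SeedSequence` spawn order (schedule, patterns, per-subject noise,
permutations), so any stage can be re-run in isolation. The pipeline
writes a manifest with the sha256 of every output.

The default grid is 24³ voxels at a nominal 2 mm spacing; validation
experiments in the test suite use 6³–16³ grids, 4–8 subjects, and —
where a full 12-run schedule is not needed — a shrunken 4-run schedule
with 9-trial halves. Null calibration of the group t test uses 500
replicates of label-exchangeable white-noise trial betas with the real
schedule's labels: the t test consumes accuracy maps, for which this is
the exact null, without re-simulating BOLD series 500 times. These
sizes are the package's own validation choices; all are configurable.

## Known limitations

- No realistic vascular/physiological noise, motion, or multiband
  physics; no preprocessing stage (drift regressors stand in for
  high-pass filtering, and motion regressors are synthetic stand-ins).
- No prewhitening in estimation; no random-field-theory thresholds or
  TFCE.
- GNB only (no SVM or feature selection); no multivariate noise
  normalization.
- The ANOVA assumes sphericity (no Greenhouse–Geisser correction).
- Emotion × actor combinations are balanced only over emotions within a
  run half; actors induce no signal unless explicitly configured.
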