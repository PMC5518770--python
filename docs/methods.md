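# Methods

This note documents the models, parameter choices and numerical conventions
behind `seqpos`, and what the synthetic validation does and does not show
about real data.

## Task model and regressor bookkeeping

A session is a sequence of trials: 1–3 items shown for 3.5 s each, a 2-s
delay, an optional recognition replay of the same items, and 6–16 s of
uniform-jittered rest.  One third of trials omit the replay so that
presentation- and recognition-phase responses can be estimated separately;
changed-order probes keep attention on the task, and any replayed item not at
its originally presented position is excluded from analysis, as are all
events of incorrectly answered trials.

`replicate_table_design()` constructs the published per-set schedule
deterministically rather than by rejection sampling: 48 trials (8 one-item,
18 two-item, 22 three-item; 5/12/15 probed per length) whose item orders are
built from complete permutation sets plus Latin-square completions, so that
identity counts per position are exactly as equal as the integers allow
(presentation 16/16/16, 14/13/13, 8/7/7; recognition 11/11/10, 9/9/9, 5/5/5).
Grouping each label's occurrences in threes then gives ceil-division counts
of 42 presentation and 27 recognition regressors — 69 beta images per
participant.  A full two-set (houses and faces) session is two such units;
all published per-position bookkeeping applies per set.  The general
generator (`generate_design`) instead randomizes everything (96 trials, 44/39/17%
lengths, 2/3 probed, 8 changed probes) and offers greedy identity balancing.

Occurrence grouping assigns onset-ordered occurrences round-robin to
`ceil(count/n)` groups (trailing groups absorb the remainder), which spreads
each regressor's members across the run; equal-onset ties and group order are
seed-determined.  Random grouping was measured to behave identically in
downstream decoding; the spread rule is kept because it guarantees the
members of one regressor are never temporally clustered.

## BOLD simulation

Signal: each event contributes, over a region's voxels, `amplitude ×
pattern`, where patterns are unit-RMS Gaussian vectors per (region, position,
phase) — identical across phases (`shared`), independent (`phase_specific`),
or independent only at position 1 (`drifted_first_position`) — plus an
identity pattern (orthogonalized by QR projection against all position
patterns, so identity cannot proxy position) and an optional load term,
linear in position and applied *uniformly over the whole mask*.  Load is
modelled mask-wide because it stands for diffuse univariate processes (memory
load, adaptation); confining it to a labelled blob would manufacture a
genuine spatial code at the blob boundary, which is not the confound being
modelled (a per-region option exists).  Event trains are 3.5-s boxcars
convolved with the canonical double-gamma HRF (SPM parameterization, via
nilearn) and sampled at TR = 1.75 s.

Noise: per-voxel AR(1) (coefficient 0.4) white noise of sd 1.0, two slow
cosine drift components (amplitude 2), aliased cardiac (1.1 Hz) and
respiratory (0.3 Hz) sinusoids (amplitude 0.3) whose 20-Hz traces are
recorded alongside, a slow motion random walk, and Bernoulli motion spikes
(rate 0.005/scan, 2-mm jumps) coupled as step artifacts into the data.
Baseline is 100 signal units.

Effect sizes are not published anywhere; the position amplitude default
(0.4 signal units at unit-RMS patterns) was calibrated once, on a coarse grid,
so that the shared-code scenario yields in-region cross-phase accuracies in a
plausible 40–60% band, and then frozen.  Desk-scale grids (12³–14³ voxels at
2 mm, masks of ~900–1400 voxels, regions of 130 voxels) keep a full cohort
analysis under a minute per subject.

## GLM (least-squares-separate)

Each event regressor is estimated by its own ordinary-least-squares model:
the target regressor; one regressor pooling all other events (optionally one
per phase); nuisance columns — six motion parameters, cardiac/respiratory
traces low-pass filtered below the scan Nyquist frequency and sampled at the
frame times, and one one-hot column per flagged scan; and an intercept.  Data
and design are first residualized against an orthonormal discrete-cosine
basis (K = ⌊2·N·TR/cutoff⌋, cutoff 128 s); the filter is a projection
(idempotent) and no pre-whitening is applied at task frequencies, since
whitening rapid event-related data manufactures dissimilarity between
adjacent events.  Scan flags: inter-scan translation > 0.5 mm, rotation >
1.33°, or mean squared consecutive-image difference over the squared global
mean > 0.035; a participant is excluded when the flagged fraction strictly
exceeds 10% (exactly 10% is kept).  Constant/zero nuisance columns are
dropped with a warning (their content is the intercept's job); a genuinely
collinear design raises an error naming the offending columns.

Two properties of this estimator matter for interpretation:

- **Pooling is lossless only under orthogonality with a common amplitude.**
  When events have disjoint HRF support *and* share a per-voxel amplitude,
  LS2 equals the joint GLM to machine precision (the oracle test asserts
  1e-8 relative agreement).  With heterogeneous amplitudes the single pooled
  coefficient cannot absorb all other events exactly, leaving a small
  intercept-mediated cross-talk; on the rapid replicated design, noiseless
  per-regressor recovery correlations are ~0.85–0.95 (class means ≥ 0.8),
  while well-separated designs recover > 0.99.
- **Cross-phase transfer is conservative.**  A recognition item's replay
  follows its own presentation by 5.5–12.5 s, so their regressors overlap and
  the separate GLMs split the shared haemodynamic variance, anti-correlating
  every test item with its own class in the training set.  Under the null
  scenario this depresses mean cross-phase searchlight accuracy to ≈ 0.267
  (vs 1/3); a control in which training and test betas come from runs with
  independent noise restores 0.338.  The permutation inference is built from
  the same pipeline and therefore calibrates this bias away; absolute
  accuracies, however, should be read against the pipeline's own null rather
  than against 1/3.

## MVPA

Searchlights contain every in-mask voxel whose centre-to-centre Euclidean
distance (in millimetres, honouring anisotropic voxel sizes) is ≤ 6 mm from
the centre; on a full 2-mm grid that is 123 voxels (the lattice count for
squared voxel distance ≤ 9 — one fewer than the often-quoted 124, whose
inclusion convention is unknown; 123 is the enumeration oracle used here).
Spheres with fewer than 33 in-mask voxels score exactly zero.

Normalization operates on the items × voxels matrix of one searchlight:
first each item's uniform component (its mean over the sphere's voxels) is
removed — this is what makes the analysis provably insensitive to signals
that move a region up or down uniformly, such as the load gradient — then
each voxel is z-scored across items.  For cross-phase analyses both phases
are normalized together as one matrix before splitting (the published
convention); this matters: normalizing each phase separately subtracts
phase-specific grand means, and whenever representations differ between
phases that offset is unknown to the classifier and collapses its predictions
into a single class.  Per-phase and train-statistics scaling remain available
as configuration.

Classification uses binary linear SVMs (libsvm via scikit-learn, C = 40) for
each class pair with one-vs-one vote counting; vote ties go to the lowest
position label (LIBSVM's convention).  Training classes are subsampled to
equal size (seeded) before fitting, honouring the design's balanced-training
intent; within-phase cross-validation pairs items of equal within-class rank
after a seeded shuffle, with the fold count equal to the smallest class
count.  Decision-space analyses use the 3-vector of signed distances to the
three pairwise hyperplanes (`decision_function / ‖w‖`).

## Group inference

Only *test* labels are permuted (100 times; the true-labelling accuracy is
appended), which leaves the trained classifier untouched — permuted
accuracies are simply agreements between fixed predictions and shuffled
labels.  Group resampling draws one accuracy per participant per sample
(1000 samples, with replacement) and averages; the empirical p is
`(1 + #{samples ≥ true}) / (n_samples + 1)`, guaranteeing validity and a
floor of 1/1001.  Because ties count toward "≥" and 27-item accuracies are
discrete, the test is mildly conservative on real inputs (~2–4% rejections at
α = 0.05 under the null; exact-to-interval with continuous accuracies); it is
never anti-conservative.  No voxelwise multiplicity correction is applied by
default.

## Representational analyses

Confusion matrices are row-normalized counts with empty rows flagged (NaN)
rather than silently zeroed.  Cross-phase similarity correlates the region's
phase×position mean patterns (normalized as above) for all nine position
pairs; the informative statistic at realistic SNR is the diagonal-minus-
off-diagonal contrast, since the estimator's adjacency anti-correlation puts
the whole matrix on a negative baseline.  The position shift maps every
pattern to decision space and takes the Euclidean distance between phase
means per position (a voxel-space variant exists); shifts feed a two-way
region × position ANOVA with participants as replicates (statsmodels OLS +
anova_lm).  The variance comparison — a reconstruction, as the published test
is under-specified — computes per-participant, per-phase mean dispersion
(mean distance of patterns to their class mean, averaged over positions) and
applies a paired two-sided t-test across participants.

## What the synthetic validation shows, and what it does not

The generator reproduces the statistical structure the analysis assumes:
HRF-linear event responses, the exact trial bookkeeping, confound gradients
collinear with position, autocorrelated noise with recorded physiological
and motion traces.  It does not model spatial noise correlations, vascular
or susceptibility structure, slice timing, inter-subject anatomical
variability (all subjects share one grid), or genuinely nonlinear neural
dynamics.  Passing tests therefore demonstrate that the pipeline recovers
the hypothesis classes it was designed to separate — shared vs phase-specific
vs drifted codes, and immunity to uniform load — under its own assumptions,
not that real data satisfy those assumptions.  Degenerate inputs (zero-
variance voxels, constant motion, empty confusion rows, zero dispersion) are
flagged or zeroed explicitly rather than propagated as NaN.
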