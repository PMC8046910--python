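# Methods

This note documents the models, numerical choices and limitations behind
`ctpnet`. It covers what each stage assumes, which parameters matter, what
the synthetic generator does and does not emulate, and where the design was
genuinely open.

## Critical time point classification

Sampling every 5th retained volume (34 of 170 at TR = 2 s) decorrelates
successive samples; the sampled indices are 1-based (1, 6, ..., 166).
Z-scoring is **temporal**: each ROI voxel's full retained time course is
standardised (mean 0, SD 1, ddof = 1) and then read off at the sampled
points. The alternative — spatial standardisation of each sampled volume
across ROI voxels — is available via `zscore_roi(mode="spatial")`, but the
temporal direction is the default because the 2.5% count bound is justified
by Gaussian exceedance of a voxel's own fluctuations (1 − Φ(2) ≈ 2.28%),
which only makes sense for standardisation over time. Standardising over
the full 170 volumes rather than only the 34 samples gives stabler moments.

Classification ranks sampled points by suprathreshold (Z > 2) count,
descending, ties broken by earlier acquisition time. If the two top-ranked
counts both *strictly* exceed 2.5% of the ROI voxel count they seed the CTP
set; each later point in rank order joins iff its count strictly exceeds
the same bound *and* strictly more than 30% of its suprathreshold voxels
lie in the cumulative union of the suprathreshold sets of already-accepted
CTPs. The pass is single and in rank order; acceptance is never revisited.
If the top-two condition fails the subject has zero CTPs and is flagged
(`top2_failed`) — this branch is undefined in the method's source
description, and flag-and-exclude is the conservative reading.

Per-subject contrast maps use Welch's two-sample t (CTP volumes vs RTP
volumes, per voxel); the mean-difference map is emitted alongside since
"contrast image" is ambiguous between the two. The group map is a
voxelwise one-sample two-tailed t across subjects, Benjamini–Hochberg FDR
at q = 0.05 over in-mask voxels, followed by a cluster-extent rule keeping
26-connected components of strictly more than 50 voxels (6-connectivity is
a config switch).

## Preprocessing

Only temporal operations are implemented; synthetic inputs are generated
already aligned, and a config flag records that slice timing, motion
correction and spatial normalisation are assumed done upstream for real
data. The band-pass (0.01–0.08 Hz) is a zero-phase forward–backward
order-2 Butterworth after per-voxel linear detrending; zero-phase filtering
avoids shifting event timing, which matters because CTPA classifies single
volumes. Filtering precedes nuisance regression by default (the method
lists them in that order); the order is configurable and logged. Nuisance
regressors are the Friston-24 motion expansion [p, p(t−1), p², p(t−1)²]
(first lag row zero-filled) plus white-matter and CSF compartment means;
collinear design columns are dropped with a warning. Motion exclusion is
strict: a subject is excluded only if displacement exceeds 1.5 mm or
rotation exceeds 1.5° — exactly 1.5 is kept. Task runs are high-passed by
projecting out a discrete-cosine basis up to 1/128 Hz. Spatial smoothing is
a separable Gaussian with σ = FWHM/(2√(2 ln 2)) per axis (kernel truncated
at 6σ so it matches the analytic Gaussian to < 1e−6).

## Networks

Cubes are 3×3×3 voxels, tiled from the minimum corner of the mask bounding
box; a block is a node iff **all 27 voxels** are in-mask, so every pattern
vector has full length (a majority rule would create unequal-length
patterns; mean-imputation is deliberately not offered). Each cube records
the dominant label of a supplied parcellation volume for regional
reporting; edges may cross parcel boundaries. Edge weights are Pearson
correlations between 27-voxel patterns in fixed raster order;
zero-variance (constant-pattern) cubes are excluded before correlation and
non-positive correlations are stored as absent. Condition averages are
element-wise means with absent edges entering as 0 — equivalent to
averaging rectified matrices; averaging only where present would change
density per edge and is not what the method describes. A node excluded in
any constituent network is excluded from the average (union rule).

The task GLM is a beta series: one regressor per trial (24 s boxcar
convolved with the canonical double-gamma HRF — response peak 6 s,
undershoot 16 s, dispersions 1 s, ratio 6, unit peak), plus the
discrete-cosine drift basis and an intercept, solved by ordinary least
squares per voxel. Per-condition beta maps average the trials of each
condition; both the per-trial and per-condition routes are exposed.
Zero-variance cubes in either condition's beta map are excluded from both
task networks so their bookkeeping stays mirrored.

## Graph metrics

Thresholding is proportional: the round(S·n(n−1)/2) strongest positive
edges are kept and binarized (sparsity = retained ÷ maximum possible
edges). Ties at the cut break deterministically by (weight desc, node_i
asc, node_j asc). Graphs are binary throughout — the small-world criteria
cited by the method are binary-graph quantities. Efficiencies follow the
Latora–Marchiori convention (1/∞ = 0 for disconnected pairs); the
characteristic path length is computed on the giant component with the
disconnection fraction logged, since unreachable pairs are already
captured by E_glob. Distances come from breadth-first search on sparse
adjacency; tests verify them against networkx and a Floyd–Warshall oracle.

Null networks preserve the degree sequence by edge-swap rewiring (10·|E|
attempted swaps per null, seeded); γ, λ and σ use the mean clustering
coefficient and path length of 100 nulls. σ > 1 is the operative
small-world criterion (the verbal "γ ≫ 1 and λ ≈ 1" has no numeric
tolerance). If no swap succeeds the ensemble is degenerate and σ is
reported as 1 with a flag. Integration over sparsity is the step-weighted
sum ΔS·Σ_K X(K·ΔS); for a constant profile c this is 0.25·c.

E_glob is provably non-decreasing in sparsity for nested thresholded
graphs; E_loc is **not** (adding a neighbour can dilute a node's
neighbourhood subgraph), and random-matrix counterexamples exist, so only
the E_glob monotonicity is asserted as a property.

## Inference

Condition comparisons are within-subject, so the permutation scheme flips
the sign of each subject's difference (10,000 draws, seeded); the
two-tailed p is (1 + #{|null| ≥ |observed|})/(1 + n_perm) and rejection at
α = 0.05 corresponds to exceeding the 95th percentile of the absolute null
distribution. With covariates, simple residualization of the differences
before flipping is **miscalibrated**: the projection removes the
covariate-subspace variance from the null but not from the observed
statistic, and measured type I error at n = 16 ranged from 6.5% to 10.7%
depending on the construction. The implementation therefore uses the
Freedman–Lane scheme — residuals of the covariates-only model are
sign-flipped, the covariate fit is added back, and a studentized intercept
of the refitted full model is the permuted statistic — which measures
5.1% at the nominal 5% level. Without covariates the classic mean-difference
sign-flip test is used unchanged. An unpaired label-shuffle variant exists
behind `method="unpaired"`.

Predictor screening is a per-candidate Pearson correlation with the
dependent variable at p < 0.01, deliberately uncorrected; the report
records how many candidates were screened. The regression is OLS with
intercept (statsmodels); adjusted R² = 1 − (1−R²)(n−1)/(n−p−1). If the
screen retains more than n − 2 predictors the smallest-p subset is kept so
the fit stays identifiable, with a logged warning. Per-predictor "variance
explained" is the squared zero-order Pearson correlation; the squared
semi-partial (drop-in-R² when the predictor is removed) is reported
alongside since the quantity is not defined in the method's description.
Cross-application refits the fixed predictor set on new data; "fails to
transfer" means the refit's overall F-test p ≥ 0.05.

## Synthetic data

The generator is the package's study-condition stand-in, not a fixture.
Defaults: 24×28×24 voxels at 3 mm, TR 2 s, 180 resting volumes (10
discarded), an ellipsoidal brain mask (~6,600 voxels, ~160 cube nodes), a
compact 213-voxel posterior ROI, 80-voxel white-matter and CSF
compartments, and a 90-parcel block labelling. Background noise is white
plus 30% spectrally shaped 1/f noise, spatially smoothed at 6 mm FWHM and
rescaled so the in-brain marginal SD equals `noise_sd`; a linear drift
(0.01 SD/volume with a random spatial pattern) and a motion-correlated
component (random-walk rigid-body parameters coupled through smooth random
weight maps) are added.

Seven transient events (near the reported per-subject mean of ~6.9) are
planted at sampled retained indices; each recruits ~9.5% of the ROI at
amplitude 4 noise-SD units. The temporal profile is the canonical HRF
peaking at the event volume: a single-volume delta would be annihilated by
the 0.01–0.08 Hz band-pass, so a hemodynamically plausible transient is
the faithful choice. Recruited sets model a recurring coactivation
pattern: every event shares a common core of `overlap_frac·k` voxels plus
an event-specific contiguous slice, so any two events overlap by
~`overlap_frac` — this matters because CTP acceptance is a single pass in
rank order, and purely chain-wise (consecutive-only) overlap makes
acceptance depend on the rank permutation. Task runs carry 18
non-overlapping 24 s blocks at 40 s spacing (conditions alternating
creative/control, 9 each) within 385 volumes (5 discarded), with known
per-condition effect maps; with zero noise the GLM recovers the planted
betas to numerical precision, which is the identity the tests freeze.

What the generator does **not** emulate: anatomy and registration error,
physiological (cardiac/respiratory) noise, multi-band artifacts,
inter-regional functional coupling structure, or any true coupling between
resting events and task responses. Passing tests therefore demonstrate the
pipeline's correctness and calibration on data satisfying its assumptions,
not empirical claims about real cortex; in particular the regression stage
on default synthetic cohorts usually finds no screened predictors, which
is the correct null behaviour.

Determinism: every dataset is a pure function of (config, seed); cohort
subject seeds are spawned from the master seed so adding a subject never
perturbs earlier subjects' streams. All derived seeds stay below 2³¹.

## Problem sizes in tests

The default scene (16 subjects, 24×28×24 grid) is used for the small-world
acceptance check (100 nulls across the five sparsity levels) and the
event-recovery study (50 seeds); pipeline smoke and determinism tests use
a reduced scene (18×20×18, 5 subjects, 4 events, 4 nulls, 200
permutations) that preserves the statistical structure at a few seconds
per run. Permutation calibration uses the full 1,000 replicates × 1,000
permutations at n = 16.

## Known limitations

- The cube tiling is anchored to the mask bounding box; anchoring to the
  volume origin shifts node identities and slightly changes results (the
  anchor is logged).
- With a 4 mm re-smooth on top of the generator's already-smooth noise,
  noise exceedances cluster spatially and occasionally outrank planted
  events in the CTP ranking; module-level recovery studies therefore use
  the temporal chain only.
- The near-saturated regressions reported for real data (10 predictors at
  n = 16) are reproducible mechanically but statistically fragile; the
  implementation refuses p + 1 ≥ n and truncates the screened set instead.
- Permutation and rewiring nulls are Monte-Carlo: quantities derived from
  them carry ~1/√N noise (N = 100 nulls, 10,000 permutations by default).
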