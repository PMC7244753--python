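# Methods

This note documents the models, estimators, numerical choices, and
calibration designs behind `brainstates`, and what the synthetic-data tests
do and do not establish about real data.

## Brain-state model

Each imaging frame is treated as a point in regional activation space after
z-scoring every region's time series within its scan. Standardizing *within
scan* (rather than across the concatenated matrix) puts subjects on a common
scale before pooling and makes a state's sign interpretable as activity
above/below that subject-scan's regional mean; the alternative (global
z-scoring) would let between-subject amplitude differences leak into state
definitions. States are k-means centroids under correlation distance
d(x, c) = 1 − r(x, c).

**Correlation-distance k-means.** Lloyd iterations run on row-centered,
unit-norm vectors, for which the Euclidean and correlation argmins coincide;
centroid updates are means followed by re-centering/re-normalization
(spherical k-means), preserving the monotone-objective convergence
guarantee. Of `n_reps = 20` random restarts the lowest-error partition is
kept. Stored centroids are the means of the (standardized) member frames in
their original units; the final labelling is recomputed from the stored
centroids so assignment is exactly reproducible from the model object.
Empty clusters are re-seeded at the globally worst-fit frame; assignment
ties go to the lowest state index. Both rules are deterministic given the
seed.

**Choice of k.** k is always a parameter. The elbow diagnostic reports
variance explained — between-cluster sum of squares over total, computed
with Euclidean sums of squares about the grand mean — and its unit-k gain;
split-half reliability reports aligned centroid correlations over random
subject splits (greedy alignment by maximal Pearson correlation). On the
default synthetic cohort the gain collapses below 1% beyond the planted
k = 5 and median split-half correlations exceed 0.9.

**State naming.** For a centroid c, the positive part p = max(c, 0) and the
magnitude of the negative part n = max(−c, 0) are compared by cosine
similarity with each system's binary indicator; the name is the argmax over
all 2 × 7 component similarities with a +/− suffix for the winning
component. The alternative rule (cosine of the full signed centroid against
signed indicators) gives the same answer whenever one component dominates;
the component-max rule is the default because it also produces the
per-component alignment table used for interpretation.

## Dynamics estimators

Fractional occupancy is 100 × (frames in state)/(frames); dwell time is the
mean run length × TR in seconds (NaN for unvisited states); appearance rate
is runs per minute. These satisfy FO_i = rate_i × dwell_i × 100/60 exactly.
Runs truncated by scan or block boundaries count toward dwell time and
appearance rate (simple mean-run-length definition); block restriction
assigns distinct segment ids to non-adjacent retained frames, so a boundary
terminates runs and is never counted as a transition.

The transition statistic is persistence-excluded: consecutive duplicates are
collapsed and T_ij is the row-normalized count of j following i in the
compressed sequence, with a structurally zero diagonal. Rows of states never
exited are stored as NaN and excluded (not imputed) from group averages. The
frame-to-frame lagged matrix, which keeps the diagonal, is provided for
non-randomness checks; on chains with geometric dwell, zeroing its diagonal
and renormalizing recovers the persistence-excluded matrix.

**Permutation test.** The rest-vs-task statistic is the element-wise
difference of group-average transition matrices. Null draws repeatedly split
subjects into random halves and difference the two mixed averages (rest of
one half pooled with task of the other, and vice versa). P-values are
two-sided with the add-one correction (p ≥ 1/(n_perm+1)), Bonferroni-
corrected over the k(k−1) off-diagonal elements; the default is 100,000
permutations with a 5,000-permutation fast path used in tests. The null
distribution's conditional variance equals s²/n, so the scheme behaves like
a z-test with plug-in variance: its per-element type-I rate is
P(|t_{n−1}| > z_{0.975}), ≈ 0.054 at n = 200 and ≈ 0.0504 at n = 879.
Calibration is therefore verified at the full cohort size (879 subjects,
120-frame scans, 500 replicates), where the residual inflation is
negligible; at strongly reduced n the scheme itself — not its
implementation — is measurably anticonservative, which users comparing
small groups should keep in mind.

## Network control

Stabilization uses A_sys = A/(λ_max(A) + c) − I with c = 1 (configurable),
the standard convention in the minimum-control-energy literature; for
symmetric nonnegative A all eigenvalues of A_sys are real and negative. The
finite-horizon controllability Gramian is computed by the Van Loan block
exponential (one `expm` of a 2P × 2P matrix), not quadrature, for accuracy
and determinism; it is symmetrized and Cholesky-factored once per system
and reused across all k² centroid pairs. Singular or indefinite Gramians
raise a diagnostic error with the eigenvalue range rather than returning
garbage. The energy integrates uᵀu (input energy, independent of B's
scaling of *state* impact); doubling B therefore quarters E exactly, which
is asserted numerically.

The control horizon T = 1 is a model-time default, not a fitted value; a
built-in log-spaced sweep over T ∈ [0.1, 10] reports how mean transition and
persistence energies move with the horizon in place of a single tuned
choice. The input up-weighting κ = 1 (regions of the chosen system get
diagonal weight 1 + κ) is likewise exposed in config.

Correctness is established against an independent discretized oracle: the
minimum-norm piecewise-constant input solving the zero-order-hold endpoint
constraint on a 2,000-step grid. Gramian energies agree with the oracle to
well under 0.5% relative error on random 8-node networks.

## Null models

*Degree-preserving*: double-edge swaps on the binarized graph (via
networkx), then a random permutation of the original weight multiset onto
the new edges. *Strength–length-preserving*: swaps are constrained so both
replacement edges fall in the same Euclidean-length quantile bin (10 bins by
default) as the replaced ones, preserving the degree sequence exactly and
the binned length histogram by construction; weights are then reassigned by
length rank, preserving the weight multiset exactly and the weight–length
Spearman correlation to within ±0.05. Bins too sparse to swap are left
unrewired. *Null states*: zero-mean Gaussian draws with the empirical
regional covariance, rescaled to the real centroid's norm; near-PSD
covariance estimates are repaired by eigenvalue clipping with a warning.
The fixed-norm rescaling removes radial scale, so the recoverable
second-moment structure of the null states is their correlation matrix (the
distortion vanishes as P grows). Every generated member is checked against
its preservation contract before being returned.

One-sided comparison p-values, p = (1 + #{null ≤ real})/(1 + n_null) per
matrix entry with Bonferroni over k², quantify whether the real network
supports states/transitions with less energy than its randomized
counterparts.

## Group statistics

Paired t-tests compare per-subject task vs rest metrics, corrected within
each metric family (the k states, or k(k−1) transitions). Regressions
z-score the outcome and all continuous predictors (age, volume, handedness,
mean framewise displacement); sex stays 0/1, so β_sex is a per-category
shift in outcome standard deviations. Rank-deficient designs are rejected
with the collinear columns named. In the single-predictor case the
standardized β equals the Pearson correlation, which is tested in closed
form.

## Synthetic cohorts: what they emulate and what they don't

Sequences follow a semi-Markov model chosen to mirror the analysis's own
decomposition: run lengths are geometric with mean `dwell` frames
(per-state, per-subject configurable) and between-run jumps follow a
diagonal-zero row-stochastic matrix — so the planted jump matrix is exactly
the quantity the persistence-excluded estimator recovers. BOLD frames are
the active state's planted centroid plus stationary AR(1) noise per region
(innovation sd `noise_sd`, coefficient `ar_coef`), giving controllable
temporal autocorrelation. Planted centroids place amplitude +1 on one
system and about −0.4 (rippled across regions so names are unambiguous) on
an anticorrelated partner system, emulating observed task-positive/negative
coactivation. Default study conditions mirror the analysis design at
reduced scale: 40 subjects, 50 regions, 120-frame rest + 225-frame task
scans (nine 25-frame blocks cycling 0/1/2-back), TR 3 s, mean dwell 3
frames, noise sd 0.5, AR coefficient 0.3. All randomness flows from one
seeded generator per cohort.

The generator does **not** model hemodynamic convolution, scanner noise
spectra, spatial smoothness, head motion, or individual topography of
states. Passing tests therefore establish that the estimators recover the
quantities they claim from data satisfying their assumptions — not that
those assumptions hold in any empirical dataset.

**Covariate effects.** Age effects are planted on subject-level dwell
parameters: dwell_s = dwell + σ_b(β z_age + √(1−β²) ε) with between-subject
sd σ_b; d′ effects are planted through subject jump-matrix traits. The
regression-recovery calibration uses 200 subjects, 1,200-frame rest scans,
base dwell 5, σ_b = 2 frames and β = 0.3, sized by a variance budget so the
per-scan measurement error of mean run length (≈0.5 frames) is small
against the planted between-subject spread and the attenuation of the
standardized β stays inside the 95% CI half-width (≈0.14 at n = 200);
empirical coverage over 200 cohorts is ~93–96%.

## Numerical and engineering choices

Matrices are written as headerless TSV at 17 significant digits (lossless
double round-trip); tables carry headers. The pipeline is pure in
(config, seed): stage sub-seeds derive deterministically from the config
seed, and provenance (config hash, seed) is stamped into every run. Problem
sizes in the test suite (e.g. 8-node oracle networks, 10⁵-frame chains,
40-subject clustering cohorts, 500-replicate calibrations) were chosen as
the smallest scales at which the targeted statistical properties are
identifiable with comfortable margins.

## Known limitations

- The half-sample-mixing permutation scheme is mildly anticonservative at
  small n (see above); a sign-flip permutation of paired differences would
  be exact but is not what the pipeline's comparison scheme specifies.
- The strength–length null preserves the length *histogram* at bin
  resolution, not exact edge lengths; very sparse length bins are left
  unrewired, reducing randomization there.
- Consistency thresholding for a group-representative network preserves the
  average per-bin edge count, which keeps the length distribution but does
  not guarantee connectedness of the result.
- Correlation-distance k-means is locally optimal; with few restarts on
  weakly separated data, solutions can vary across seeds. The reliability
  diagnostics exist to detect this.
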