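# Methods

## The problem

Functional-connectivity (FC) profiles are candidates for individualized
clinical measures only if they are reliable across repeated scans and
discriminate between individuals.  This package implements a complete
comparison of two acquisition conditions (canonically "movie" and
"rest") on four reliability-based statistics, at the ROI level and
parcelwise across the brain, together with the permutation machinery
needed to decide whether an observed condition difference exceeds
chance.

## Data model and FC construction

A scan is a T × V matrix of vertex time series with subject, condition
(one of two labels), scan index (1 or 2), session, and a mean framewise
displacement (FD) motion summary in millimetres.  Processing follows a
standard naturalistic-fMRI recipe:

- subjects with mean FD > 0.2 mm (default) in **any** run are excluded;
- the first `n_initial` TRs are dropped; stimulus-boundary epochs plus a
  post-epoch padding window are excised, with interval coordinates in
  the original 0-based, half-open TR frame.  The same epoch table is
  applied to both conditions so their lengths and temporal structure
  match;
- runs are cropped from the end to the common minimum length within each
  session;
- parcel time courses are unweighted means of member vertices (no
  vertex-area weighting — inputs carry no geometry);
- the FC matrix of an ROI is the Pearson correlation of each ROI vertex
  with each parcel time course.  ROI vertices are not excluded from
  their own parcel.  Zero-variance series yield NaN entries and a logged
  warning.

NaN edges are handled by a dataset-wide mask: an edge that is NaN in any
scan is dropped from every scan before vectorization, so distances
always compare identical coordinates.  Zero-filling would deflate
distances asymmetrically and is deliberately not offered.  An optional
Fisher z (atanh) transform of the correlations before distance
computation is exposed (`fisher_z`, default off, values clipped to
±(1 − 1e−7)).

## Reliability statistics

**Edgewise ICC(2,1).**  Per edge, the two-way random-effects,
absolute-agreement, single-measurement intraclass correlation from the
n × k subject-by-scan table:

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

with MSR, MSC, MSE the row (subject), column (measurement) and error
mean squares.  Edges with zero total variance return NaN.  The ROI
summary averages ICC across parcels within each vertex, then across
vertices (equal to the flat mean when no edge is missing).  Values are
binned with the conventional labels poor (< 0.2), fair [0.2, 0.4),
moderate [0.4, 0.6), good [0.6, 0.8), excellent (≥ 0.8); the published
bin edges leave small gaps (0.39→0.4 etc.) which are closed upward as
half-open intervals.

**I2C2.**  The image intraclass correlation 1 − trace(Ku)/trace(Ko)
with

    trace(Ko) = Σ_ijv (X_ij(v) − X̄..(v))² / (Σ_i J_i − 1)
    trace(Ku) = Σ_ijv (X_ij(v) − X̄_i.(v))² / Σ_i (J_i − 1),

grand-mean demeaning per variable.  The statistic may be negative in
noise-dominated data and equals 1 exactly when each subject's scans are
identical.  Inside the permutation loop it is computed equivalently from
pairwise squared distances via Σ_a‖x_a − x̄‖² = Σ_{a<b} d²_ab / M (and
its per-subject analogue); the identity is asserted against the direct
formula to 1e−10 in the tests.

**Discriminability.**  For every subject and ordered pair of that
subject's scans (anchor, repeat), the within-subject distance is
compared with the anchor's distances to other subjects' scans; the
statistic is the mean fraction of comparisons in which the between
distance is strictly larger, ties counting ½.  Perfectly reliable data
scores 1 and exchangeable data 0.5 in expectation.  (Some published
verbal definitions invert the inequality, which would make perfectly
reliable data score 0; this implementation follows the construction in
the statistic's source literature, where high = reliable.)  Two
comparison sets are exposed: `cross_scan` (default) compares the anchor
only against other subjects' scans from the repeat's session, mirroring
the paired-session design; `all` compares against every scan of every
other subject, the general literature definition.

**Fingerprinting.**  A subject is identified in the scan1→scan2
direction when the distance to their own scan 2 is strictly smaller
than to every other subject's scan 2; any tie is a failure.  Accuracy is
averaged over both directions by default (`direction="both"`); the
one-way variants are available.

Both distance-rank measures are invariant to monotone increasing
transforms of the distances, and all four statistics are invariant to
subject relabelling; both properties are under test.

## Nested permutation test

Each subject contributes two scans per condition.  A permutation swaps,
independently per subject with probability ½, the whole pair of
condition-A scans with the whole pair of condition-B scans.  Pairs are
never split, so permuted "reliability" is never measured across
conditions — the null hypothesis is exchangeability of condition labels
within subject, not exchangeability of scans.  Multivariate measures
are permuted at the level of the distance matrix (computed once over
all 4N scans and re-indexed per permutation); mean ICC is permuted at
the level of the FC matrices.

The p-value is `#{|d_perm| ≥ |d_obs|}/B` (non-strict, no smoothing) by
default: a permutation distribution can legitimately produce p = 0 at
resolution 1/B, which matches how such tests are commonly reported.  A
strict `>` rule and a (count+1)/(B+1) smoothed rule are options.
Default permutation counts are 5000 for the multivariate measures and
500 for mean ICC (whose inner ANOVA over all edges is the expensive
step); at B = 500 the smallest attainable nonzero p is 0.002.

Because discriminability and fingerprinting take values on a discrete
grid (multiples of 1/(anchors·comparisons) and 1/(2n)), their
permutation nulls are tie-heavy and the resulting p-values are
conservative: under a true null their rejection rate at α = 0.05 is
well below 0.05.  The continuous-valued measures (mean ICC, I2C2) are
calibrated — their null rejection rates sit inside the exact binomial
confidence band in the acceptance tests.

**FDR.**  Benjamini–Hochberg step-up adjustment, implemented directly
(monotonicity enforced, capped at 1, input order preserved) and checked
against statsmodels on random vectors.  The ROI family (3 ROIs × 4
measures = 12 tests) and the parcelwise family (n_parcels × 3
multivariate measures; 1137 for a 379-parcel map) are corrected
separately.  Mean ICC is excluded from the parcelwise level.

## Scan-duration sweep

FC matrices and all four measures are recomputed on scan prefixes of
20, 40, …, 680 TRs (34 points).  Truncation operates on the cleaned
(trimmed/excised/cropped) series, so the sweep's largest point
reproduces the full pipeline bit-for-bit.  If scans are shorter than
the grid maximum the grid is truncated with a warning.

## Synthetic data generator

The generator defines the study conditions under which everything is
validated.  Two modes:

**direct_fc** — each edge value is X_ij = μ_i + ε_ij with
μ_i ~ N(0, σ²_b), ε_ij ~ N(0, σ²_w), drawn independently per edge.  The
edgewise ICC is then exactly σ²_b/(σ²_b + σ²_w) (`theoretical_icc`).
Values are unbounded Gaussians, i.e. implicitly Fisher-transformed
connectivity, which keeps the variance components exact.  An optional
low-rank shared component adds inter-edge correlation (contributing
`shared_var` to the between-subject variance) for stressing the
multivariate measures.

**timeseries** — each subject's parcel signals mix iid normals through
L_i = (A_shared + √(σ²_b·effect)·B_i)/√P, with A_shared common and B_i
subject-specific; scan-level parcel noise and vertex noise scale with
√(σ²_w·effect).  There is no closed-form ICC; ground truth is by
Monte-Carlo and limit behaviour (within-subject FC distance → 0 as
T → ∞ when σ²_w = 0).

A `condition_effect` multiplies either variance component per
condition; the identity effect makes conditions exchangeable, which is
the basis of the type-I-error checks.  An optional lognormal mean-FD
covariate exercises QC filtering.  Randomness uses one root
`SeedSequence` with per-subject child streams, so enlarging the cohort
never changes existing subjects' data.

What the generator does **not** emulate: hemodynamics, autocorrelated
BOLD noise spectra, spatial smoothness, motion artefacts correlated
with signal, or family structure (twins).  Passing tests therefore
demonstrate correctness of the estimators and the inference machinery
under the declared variance model, not performance claims about real
fMRI data.

## Validation conditions (problem sizes)

Chosen once as realistic desk-scale study conditions:

- **Variance-ratio recovery**: 100 subjects × 2 scans × 500 edges;
  mean edgewise ICC and I2C2 within ±0.05 of the analytic ratio (0.5
  and 0.75).
- **Oracle equivalence**: ICC against an explicit sums-of-squares
  oracle on 200 random 6×2 tables (1e−10) and against an independent
  reference implementation; discriminability against exhaustive
  triple-loop enumeration on 100 random distance matrices of 5–10
  subjects, both comparison modes, including exact-tie grids.
- **Calibration**: 200 exchangeable-condition datasets (20 subjects,
  100 edges, B = 500); mean-ICC and I2C2 rejection counts inside the
  exact binomial 95% band around α = 0.05.
- **Power**: halved within-variance for one condition at σ²_b = 0.15,
  σ²_w = 1, 100 edges, 30 subjects — a regime where discriminability is
  off its ceiling — detected in ≥ 80% of 50 replicates (observed:
  ~90–100%).
- **Duration trend**: 20 simulations of a strong-signal stationary
  regime (σ²_b = 25, σ²_w = 0.25, 8 subjects, 24 × 4 FC, 680 TRs) in
  which the identification measures sit at their ceiling and the
  variance-ratio measures rise across the whole grid; the seed-averaged
  curve of every measure is non-decreasing over all 34 points.

## Numerical choices and edge cases

- Pearson correlations are clipped to [−1, 1] to absorb float error;
  degenerate (zero-variance) pairs are NaN, never 0.
- ICC denominators of exactly 0, or zero total variance, yield NaN.
- Distance matrices are validated for symmetry, zero diagonal and a
  balanced subject × scan index.
- TSV outputs use a fixed `%.10g` float format so identical runs are
  byte-identical.
- The per-anchor discriminability fractions are averaged in a fixed
  subject-major order so the vectorised path and naive enumeration
  agree bitwise.

## Known limitations

- The permutation design requires exactly 2 scans per condition per
  subject (the nested swap is defined on pairs); discriminability's
  `all` mode accepts k > 2 scans outside the permutation machinery.
- Parcel means are unweighted; surface-area weighting would require
  geometry inputs that are out of scope.
- No family-structure-aware permutation: related subjects violate the
  exchangeability assumption and would bias identification measures
  downward.
- CIFTI/NIfTI ingestion is not built in; the interchange format is a
  dense TSV matrix per scan plus a manifest table, to keep the package
  free of neuroimaging-IO dependencies.
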