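# Methods

`sbspca` implements an unsupervised workflow for prioritizing temporally
dynamic features (trends and spill events) in LC-HRMS non-target
screening feature tables: preprocessing, elastic-net sparse PCA with
per-component cardinality control, stability selection via stratified
bootstrap over a penalty grid, permutation-based significance,
Procrustes comparison of peak tables, and cross-tool aggregation. This
note records the models, the parameters that matter, the numerical
choices, and the limits of what the synthetic studies demonstrate.

## Preprocessing chain

The chain is fixed in order; each stage's output satisfies the next
stage's preconditions or fails loudly.

1. **Internal-standard (IS) normalization.** Each sample is divided by a
   response factor: the geometric mean over IS channels of that sample's
   IS intensity relative to the IS's own across-time geometric mean.
   Factors are centred at 1, so the correction removes per-sample
   sensitivity drift without changing the overall intensity scale. An IS
   with a non-positive intensity anywhere is an error (the offending
   time point is named). IS columns are kept in files but excluded from
   modeling.
2. **Near-zero-variance (NZV) filter.** A feature is removed iff the
   frequency of its most common value divided by the frequency of its
   second most common value exceeds `freq_cut` (default 95/5 = 19,
   strict >) AND its percent of distinct values is at most `unique_cut`
   (default 8, non-strict). Constant features are always removed; when
   all values are distinct the ratio is mode-frequency over 1. On 52
   time points this keeps any spill with >= 4 consecutive distinct
   non-zero values while dropping single-spike artifacts.
3. **Row-wise total-abundance normalization + log10.** Each sample row
   is rescaled to the median row total, then `log10(x + pseudocount)`.
   The pseudocount default is 1 intensity unit on the normalized scale
   (the data are raw detector counts of order 1e4-1e5, so 1 is far
   below any real signal); it only regularizes exact zeros
   (non-detects). Logging follows normalization, so output rows do not
   share a common sum.
4. **Autoscaling.** Each feature is centred and scaled to unit *sample*
   standard deviation (ddof = 1). The per-feature mean/sd are kept for
   inverse mapping. Zero-variance columns (possible only if the NZV
   filter was skipped) are an error.

## Sparse PCA (regression formulation)

For an autoscaled matrix `X` (n samples x p features), components are
fitted by alternating two steps, with the Gram matrix `G = X'X`
computed once:

- **Loading step.** For a fixed orthonormal helper `A` (p x A), each
  loading column `b_j` is obtained from the elastic-net regression of
  `X a_j` onto `X` with ridge penalty `lambda` and the L1 level chosen —
  by bisection on the L1 penalty of the coordinate-descent subproblem —
  so the solution has exactly `k` non-zeros. The returned column is the
  ridge solution restricted to that support (path truncation): the
  support carries the selection information, and de-shrinking makes the
  inner step a deterministic function of the support so the alternating
  scheme has a well-defined fixed point. With shrunk coefficients the
  bisected L1 level varies between iterations and the convergence
  criterion on `B` never settles.
- **Helper step.** `A` is refreshed as the orthogonal polar factor of
  `G B` (SVD-based), the standard update of the regression formulation.

Sparsity is specified as the targeted fraction of zero loadings per
component and mapped to the cardinality `k = max(1, round((1 - s) p))`
(ties away from zero), so s = 0.9 keeps 10% of the features. The ridge
penalty (default grid 0.1-100) stabilizes correlated features; at
`s = 0, lambda = 0` the procedure reproduces PCA loadings exactly
(tested to 1e-6 over random matrices).

Numerical choices:

- **Initialization**: PCA loadings (deterministic).
- **Convergence**: max absolute change of the unit-normalized,
  sign-aligned loading matrix < `tol` (default 1e-6, `max_iter` 500).
- **Support freeze**: with many near-tied features the exact-k support
  can cycle indefinitely among equally good sparse solutions (a known
  behaviour of cardinality-constrained sparse PCA). After 40% of
  `max_iter` without convergence each component's support is frozen at
  its current set and the remaining iterations run the fixed-support
  ridge problem to convergence. The frozen support is one member of the
  cycle; which member is immaterial for selection-frequency estimation
  and the choice is deterministic.
- **Sign convention**: each loading column is flipped so its
  largest-magnitude entry is positive.
- **Scores** are `T = X B` on the full (non-deflated) autoscaled matrix.

**Adjusted explained variance.** Sparse components are correlated, so
their raw score variances over-count. The scores are QR-factorized,
`T = Q R`, and component `a` is credited `R[a,a]^2 / trace(X'X) x 100` —
the variance it adds beyond the preceding components. For orthogonal
PCA loadings this reduces to the classical percentages; the per-model
values are reported and their sum is bounded by 100.

**Control limits.** Per-component normal-theory limits
`mean +/- z_{1-alpha/2} sd` with alpha = 0.01 ("99% limits"); time
points outside are flagged. This is a univariate rule per score series;
no joint (Hotelling-type) chart is attempted.

**Ranking.** Within a component, non-zero loadings are ranked by
absolute value (ties by feature id) and the top 10 reported — the ad
hoc prioritization threshold of the workflow.

## Stability selection (SBS)

Daily samples are partitioned into consecutive strata of five time
points (a trailing remainder of >= 2 forms its own stratum; a remainder
of 1 joins the last full stratum). Each bootstrap replicate resamples
rows with replacement *within* strata, preserving stratum order, so the
local temporal structure that spill patterns live on survives
resampling. Replicates are re-autoscaled (duplicated rows change column
scales; every fit stays on the autoscaled contract). The default
production protocol is 500 replicates x 16 penalty configurations
(sparsity {0.6, 0.7, 0.8, 0.9} x ridge {0.1, 1, 10, 100}) x 10
components = 80,000 model fits; resample draws are shared across
configurations so every penalty setting sees the same replicates.

**Alignment.** Bootstrap replicates do not preserve component order or
sign, and a marker's component can surface at different positions in
different replicates. Replicate components are therefore matched to a
full-data reference model per configuration by greedy maximal-|cosine|
assignment of loading columns (a permutation; positional matching is
available as an option and recorded in metadata). Selection frequency
of (feature, component) is the fraction of replicates in which the
feature has a non-zero loading in the aligned component. A cumulative
"subspace" frequency (selected in any of the first a components) is
recorded alongside as a diagnostic; its null baseline is much higher,
so thresholds published for per-component frequencies do not transfer
to it.

Per-replicate fits use `max_iter` 75 and `tol` 1e-3: the support —
the only thing frequency estimation consumes — stabilizes within ~10
iterations, while full 1e-6 convergence of loading values is slow on
noise-dominated resamples (near-degenerate trailing eigenvalues).
Non-converged replicates are dropped and the effective replicate count
reported; a configuration losing more than 20% of replicates is flagged
invalid.

**Permutation p-values.** Null datasets permute every feature
independently across time, destroying temporal structure while
preserving marginals (an autoscaled column stays autoscaled, so no
re-scaling is needed). The full SBS frequency computation is repeated
per null dataset (optionally with a reduced replicate count, recorded),
and null frequencies are pooled across features and permutations into
one null distribution per component:

    p = (1 + #{null >= observed}) / (1 + N_null).

At least 19 permutations are required to resolve p <= 0.05. The scheme
(within-feature time permutation) is recorded in run metadata. Because
the observed frequencies of one dataset are mutually dependent (feature
competition for `k` slots, chance correlation clusters) while the null
pools over many permuted datasets, the p-values on pure noise are
uniform only approximately; finer frequency grids (more replicates)
bring them closer (see the calibration study below).

**Robust markers** combine frequency strictly above a threshold
(default 0.70; 0.50 is the secondary reading, and a 0.40-0.60 band is
reasonable for narrow/abrupt spills) with permutation p < 0.05.

**Consensus penalties.** Configurations are scored by the number of
(feature, component) cells above the frequency threshold, subject to
the reference model retaining a minimum adjusted total variance; all
configurations within 95% of the best score are returned, ordered by
score, then lower sparsity, then ridge nearest 1.

**Final model.** A single deterministic fit at the chosen configuration
at full precision (max_iter 500, tol 1e-6), with per-component rankings
and control limits.

## Procrustes comparison

Two matrices with matched columns (samples x targets) are compared by
optimal translation + rotation/reflection + scaling of the comparison
onto the reference; the dissimilarity is the residual sum of squares
over the total sum of squares of the column-centred reference, bounded
by [0, 1] with scaling enabled and 0 iff the comparison is an exact
similarity transform. Centring and scaling are togglable (both on by
default). Column matching is delegated to the cross-tool matcher.

## Cross-tool prioritization

Features from >= 2 tool outputs are grouped into unified variable
indices by greedy nearest-neighbour agglomeration over candidate pairs
within 5 ppm m/z and 0.1 min RT (defaults for the synthetic emulation),
processed in order of (m/z distance, RT distance); a merge is accepted
only if the group keeps at most one feature per tool and all members
stay pairwise within tolerance. A unified feature is a consensus
candidate when, in the same aligned component, at least two tools
select it above the moderate-stability bound (>= 0.50; "high" is
> 0.70) and at least one of those tools ranks it in the component's
top 10 by absolute loading. Tool components are aligned to the first
tool's via cosine matching of reference loadings restricted to shared
unified features. Candidates sort by (supporting tools desc, mean
frequency desc, mean loading rank asc, unified id), a total order, so
reports are byte-stable at fixed seed. Features with single-tool
evidence go to an appendix rather than being discarded silently.

## Synthetic data generator

The generator emulates the statistical structure of influent-wastewater
screening data, not its chemistry:

- **Background features** (default 200; the real studies' table sizes
  vary by extraction tool and are not canonical): log-normal intensities
  around per-feature base levels (1e4-4e5), AR(1) temporal
  autocorrelation on the log scale (default coefficient 0.6 —
  consecutive daily composites are moderately persistent), multiplied
  by a smooth seeded sensitivity drift shared by all channels
  (default magnitude 0.1) that IS normalization is meant to remove.
  `noise_cv` (default 0.35) is the marginal coefficient of variation of
  the matrix variability. Zeros (non-detects) are injected on
  background features at rate 0.05.
- **Internal standards** (5): constant true level x drift x small
  (2% log-sd) analytical noise.
- **Spiked targets**: background-level baseline + profile x
  multiplicative log-normal noise with `spike_noise_cv` (default 0.15) —
  smaller than the matrix CV because spiked standards follow predefined
  concentration profiles, so their variability is analytical rather
  than environmental. Default amplitude 1.5e5 (about 5-6x the linear sd
  of a spiked feature's own baseline fluctuations). Profiles: monotone
  trends, stable, fluctuating, and five spill shapes — left-sided
  (contiguous prefix), wide (centred interior block), short-lived
  (<= 5 points, seeded interior placement), right-sided (suffix), and
  episodic (>= 2 disjoint short blocks, seeded placement). Support size
  is `round(exposure x n_times)` (ties away from zero); on 52 days the
  stock left-sided target covers 20 days (38%) and the episodic one 7
  days (13%).
- **Artifacts** (10): all-zero rows with 1-2 huge single-point
  detections; the NZV filter removes them.
- **Stock designs**: dataset II (52 daily samples, 9 spill-type
  targets), dataset I (53 replicate injections, 8 trend/stability
  targets).
- **Tool variants**: seeded feature dropout, duplicate insertion within
  matching tolerance, correlated isotope-like satellites (+1.00335 Da),
  per-feature intensity rescaling, and per-time-point missed detections,
  with a provenance map to parent features. Internal standards are
  exempt from dropout and missed detections (they are spiked high and
  every real tool detects them; losing one would break normalization,
  which is not the failure mode the variants emulate).

What the generator does *not* emulate: triplicate injections (the
studies measure in triplicate but all modeling operates per time point
— one value per time point is generated), chromatographic/centroid-level
structure, isotope-pattern chemistry, concentration-to-intensity
calibration, cross-feature correlation of the real matrix (background
features are independent given the drift), and co-eluting features of a
spiked compound in the base table (satellites exist only in tool
variants). Passing recovery tests therefore shows the statistical
machinery works under the designed signal/noise structure; it does not
certify performance on real matrices, where markers are typically
reinforced by correlated adduct/isotope features but also face
structured interferences.

## Scaled-down study protocols

Production-scale stability selection (80,000 fits) is a batch
computation. The packaged study protocols are sized for a single CPU:

- **Marker recovery** (`workflows.dataset_ii_recovery_study`): 100
  replicates, grid {0.6, 0.7} x {ridge 1} (the consensus neighbourhood),
  10 components with statistics read from aligned components 1-3, 20
  permutations x 20 null replicates. Persistent spill classes
  (left-sided, wide, right-sided) are scored by their best marker: wide
  spills are a correlated pair whose selections split across a shared
  component subspace, so the class, not each twin individually, is the
  stable unit. Across generator seeds the individual persistent markers
  straddle the 0.70 threshold (roughly 0.6-0.95) — the same
  threshold-straddling the production-scale studies report for the lone
  right-sided marker — while transient (short-lived/episodic) markers
  average systematically lower.
- **Null calibration** (`workflows.null_calibration_study`): 52 x 200
  i.i.d. noise, one configuration (sparsity 0.9, ridge 1, one
  component), 200 replicates for observed and null runs, 30
  permutations; reports the KS statistic of the p-values against
  U(0,1). Observed replicate counts below ~100 visibly inflate the KS
  statistic through frequency-grid discreteness.

## Known limitations

- The alternating cardinality-constrained fit finds a local optimum;
  the brute-force support oracle is matched on small toys (>= 95% of
  seeds), not guaranteed globally.
- Permutation p-values inherit dependence across features (shared
  dataset, slot competition); they are calibrated approximately, not
  exactly, and are best used with the frequency threshold, as in the
  robust-marker rule.
- The consensus-penalty score counts stable cells only; it does not
  model the trade-off between sparsity and interpretability beyond the
  variance floor.
- Cross-tool component alignment uses shared unified features; with
  very few shared features it falls back to positional matching.
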