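# Methods

This note documents the models and procedures implemented in `follitime`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish
about real data.

## Design and coding of time

The in vitro design is 2 culture conditions (5X, 10X follicles per bead) ×
7 sampling days (2, 4, 6, 7, 8, 10, 12), one array per condition-day — 14
samples, no replication.  All polynomial fits use the coded grid
x = (−3, −2, −1, 0, 1, 2, 3), placing day 7 at x = 0; calendar days are kept
in the sample metadata.  Day 7 breaks the even-day spacing deliberately (it
brackets antrum formation), so the coded grid is an ordinal, not linear,
transform of calendar time; every statistic here depends only on the
ordering and the fixed grid.

## Preprocessing

* Gene filter: retain genes with summary intensity > 3 **and**
  across-sample SD > 0.3, applied conjunctively in one pass.  The summary
  statistic for "intensity" is the per-gene mean across samples (a `max`
  switch exists); the upstream description does not pin this down, and on
  log-scale microarray data the two differ little.
* Standardization uses the sample SD (ddof = 1); mean-centering preserves
  per-row variances exactly.
* Quantile normalization replaces each value by the mean, across all pooled
  columns, of the sorted values at its rank; ties receive the mean of the
  reference values over the whole run of tied sorted positions (the
  standard mean-of-tied-ranks convention, matching preprocessCore's
  behavior).  Joint normalization of several matrices pools all their
  columns, so afterwards every column of every matrix has the identical
  sorted value vector.

## Trajectory statistics

For each gene and condition the 7-point series y is scored by:

* **PVE** — least-squares cubic fit y = ax³ + bx² + cx + d on the coded
  grid; PVE = V_C/V_T where V_T is the (sum-of-squares) total variation
  about the mean and V_C the part captured by the fit.  The n vs n−1
  normalization cancels in the ratio.  Cubic order is fixed: a quartic term
  would let rugged series score well, defeating the purpose of the
  statistic.  PVE is computed for the 5X and 10X series separately and
  averaged.  Constant series (V_T = 0) have undefined PVE (NaN sentinel)
  and always fail the filter.
* **Cohesion** — from the 7×7 matrix of absolute pairwise differences,
  C = SSD_A/SSD_{N−A} with SSD_A the sum of squares over the 6 adjacent
  pairs and SSD_{N−A} over the 15 non-adjacent pairs (6 + 15 = C(7,2) = 21).
  Cohesion is computed per condition and averaged, mirroring the PVE
  averaging (a combined-series variant would change little; the per-series
  choice keeps the two smoothness statistics symmetric).  Both PVE and C
  are invariant to shifting and positive scaling of y.
* **Two-factor ANOVA** — the 2×7 table decomposes exactly as
  SS_total = SS_group + SS_time + SS_int (balanced layout), with 1, 6 and 6
  degrees of freedom.  With one observation per cell the saturated factor
  model leaves **zero** error df, so an error term must be supplied:

  * `cubic_residual`: error MS = (RSS_cubic,5X + RSS_cubic,10X)/6, reusing
    the PVE machinery (3 residual df per series).  This treats departure
    from a smooth cubic trend as noise.
  * `moderated` (default for the table-level `compute_scores`): the same
    per-gene error MS, additionally shrunk across genes by the
    empirical-Bayes squeeze described below (df = 6).  Rationale: the three
    filter statistics are strongly positively correlated under pure noise —
    a noise gene whose wiggle happens to look cubic also has a small cubic
    residual, so its F_int is inflated exactly when its PVE and C look
    good.  With per-gene denominators the joint false-positive rate of the
    PVE/C/F filter on white-noise genes is ≈9–10%; borrowing error
    information across genes (standard practice in unreplicated genomics
    designs, and consistent with the moderated-t machinery used elsewhere
    in this pipeline) decouples the denominator from the gene's own
    realized smoothness and brings the joint rate to ≈1–2% while retaining
    >99% of genuinely smooth condition-divergent genes at the default
    noise level.
  * `interaction`: classical main-effects test against the interaction MS
    (F_int is then identically 1 and only F_group/F_time are meaningful).

  Degenerate cells: if the error MS is exactly zero (an exactly-cubic
  series) a nonzero effect MS yields F = +inf — the effect is infinitely
  significant relative to zero residual — while 0/0 is a NaN sentinel and
  the gene fails the filter.  Effect mean squares at roundoff level
  (< 1e−12) are treated as exactly zero, so additive tables give F_int = 0,
  not 1e−32.

* **Filter** — retain genes with PVE_mean > 0.6, C_mean < 0.35 and
  F_int > 2 (all strict; all configurable).  The F criterion applies to the
  interaction by default because the selection targets condition-dependent
  temporal divergence; an `any` mode accepts max(F_group, F_time, F_int).

## Moderated t

For groups A and B, logFC = mean(B) − mean(A) and s²_g is the pooled
within-group variance with d = (n_A−1) + (n_B−1) df; single-sample groups
contribute a mean but no variance.  The prior is fitted by method of
moments on e_g = log s²_g − ψ(d/2) + log(d/2): the excess of Var(e) over
the trigamma term implied by chi-square sampling determines d₀ via the
inverse trigamma (Newton iteration), and s₀² follows from the mean of e.
If the observed spread is at or below the chi-square-only level, d₀ = ∞ and
every posterior variance equals s₀²; if all s²_g are literally identical,
s₀² is that common value (so moderation reduces to the identity, as it
should).  Posterior variance is the df-weighted blend
(d₀s₀² + d·s²_g)/(d₀ + d); t̃ is referred to a t distribution on d + d₀ df
(standard normal at d₀ = ∞).  The implementation is cross-checked against
R/Bioconductor limma (t, p, df.prior, s2.prior) in the test suite.

Multiple testing uses Benjamini–Hochberg.  Ranking within temporal clusters
is by logFC, ties broken by |t̃| then gene ID (stable).

## Clustering

* **k-means** (default k = 6) runs on standardized consensus 7-point
  profiles (the 5X/10X average), matching the idea of clustering shared
  temporal structure; `use_consensus=False` clusters the full standardized
  14-sample vector instead.  k-means++ with 10 restarts and a fixed seed;
  scikit-learn provides the solver.
* **Contrast derivation**: each cluster's High group is the set of days
  where its standardized centroid is positive, Low the rest; centroids
  whose sign flips ≥ 3 times across the course are flagged oscillatory and
  skipped, reflecting that oscillatory clusters do not support a meaningful
  High/Low contrast.  Explicit per-cluster day tables can be supplied
  instead (e.g. High = days {4,6,7,8,10}, Low = {2,12}).
* **SOM**: a 3×3 lattice trained by deterministic batch updates on the
  standardized 14-sample vectors (consensus profiles would erase the
  5X-vs-10X divergence the map is meant to separate).  Codebooks are
  initialized on the grid spanned by the first two principal components
  (signs fixed by the largest-magnitude loading), which already imposes the
  topological ordering; the Gaussian neighborhood therefore starts narrow
  (σ: 0.6 → 0.15 linearly over 30 epochs).  After each update, a node left
  without members is reseeded at the profile farthest from its current
  best-matching codebook (deterministic dead-unit repair) — without this,
  two well-separated pattern groups can share a node while another node
  stays empty, which is fatal when the number of planted patterns equals
  the number of nodes.  Node merging unions nodes whose mean member
  profiles correlate above ρ = 0.95 (transitive closure), off by default.

## Concordance

The time course is condition-averaged to 7 day-columns and grouped
Early = {day 2}, Middle = {4,6,7,8}, Late = {10,12}; day 0 is excluded
because it was never profiled, so the Early group is a single observation
whose variance information comes entirely from pooling and shrinkage.  The
comparator contributes replicated Primary / Multilayer Secondary / Antral
stages.  After gene-set intersection and joint quantile normalization, each
dataset is tested per transition with the moderated t, and the paired
t-score vectors are compared by Pearson r (the Fisher z = atanh(r) test
presumes Pearson), two-sided p from z·√(n−3).  Genes with t = 0 in either
vector are reported separately from the sign-agreement and disagreement
lists.  Note that Pearson r between transition t-scores of the two designs
is intrinsically capped below 1 even for perfectly shared biology: within
the in vitro Middle group the trajectory keeps moving (days 4→8), and that
real temporal change enters the pooled variance of the 1-vs-4 comparison.

## Synthetic data

The generator plants nine archetypes over the coded grid: logistic decline
(early activator), Gaussian bump (transient mid), logistic rise with a late
logistic decline (delayed activator, rising from day 4), late logistic rise,
flat background, a smooth cosine oscillation, and three condition-divergent
pairs (5X quadratic U vs 10X linear rise; inverted U vs linear fall; linear
fall vs rise).  Defaults: amplitude 2.0 and noise SD 0.3 on the log scale —
a signal-to-noise regime in which the analysis is expected to work but not
trivially so; an option draws gene-specific noise variances from a scaled
inverse-chi-square prior (df d₀, scale noise_sd²), exercising exactly the
variance model the moderated t assumes.  Values sit on a baseline of 6.0 log
units so the intensity filter behaves realistically.  The stage comparator
derives its Primary→MultilayerSecondary→Antral mean changes from the in
vitro Early/Middle/Late consensus stage means: a chosen fraction of genes
keeps the sign (and magnitude) of both transitions, the rest get
independently randomized signs.

What the generator does **not** emulate: probe-level microarray signal,
RMA, batch or chip effects, correlated noise across genes, or platform
differences beyond what joint quantile normalization removes.  Passing
recovery tests therefore demonstrates correctness and calibration of the
algorithms under their stated assumptions, not robustness to the full messiness
of real microarray data.

## Problem sizes and tolerances

The test suite and acceptance script use 10³–10⁴ genes per check: 2,000
genes × 10 seeds for filter discrimination, 600 × 10 for k-means recovery,
360 × 10 for SOM purity, 5,000 genes for hyperparameter recovery, 20
replicates × 1,000 genes for null calibration, 20 seeds × 210 genes for
concordance calibration, and 10,000 permutations for the Fisher-vs-
permutation comparison — sizes at which the Monte-Carlo error of each
quantity is comfortably below the margin it is checked against.  Exact
identities (cohesion closed forms, PVE on cubic-span trajectories, the
ANOVA decomposition) are asserted at 1e−10 or tighter; parameter recovery
at 15% relative error; calibration rates at ±1 percentage point.

## Known limitations

* The unreplicated design admits no model-free error term; all F_int
  readings are conditional on the chosen error model (see above).
* PCA orientation is fixed by a sign convention (largest-magnitude loading
  positive); only the orientation, not the subspace, is convention.
* The SOM neighborhood schedule and epoch count are heuristics; quality is
  monitored via the per-epoch quantization error, which is nonincreasing on
  the packaged fixtures but not guaranteed monotone in general.
* Quantile normalization assumes comparable global distributions; it cannot
  correct gene-specific platform effects, which is why cross-dataset
  comparison is done on t-scores rather than expression values.
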