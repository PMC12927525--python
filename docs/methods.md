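# Methods

## The question and the procedure

A droplet scRNA-seq cluster that co-expresses the signatures of two other
clusters ("parents") admits two explanations: a genuine cell population,
or doublets formed when two tightly associated cells enter one droplet.
`doubletnull` operationalizes the artifact hypothesis as an explicit null:
if the query cluster consists of doublets of parents A and B, its cells
should resemble *computationally constructed* A+B mixtures more than they
resemble either parent alone or unrelated cells.

The null is built from the log-normalized expression matrix restricted to
the highly variable genes (HVGs).  For each of `n_pairs = 5000` pairs —
one cell drawn uniformly with replacement from each parent — the two
log-normalized vectors are un-logged, averaged gene-wise, and re-logged:

    m(a, b) = ln(1 + ((e^a − 1) + (e^b − 1)) / 2)

Averaging in the *unlogged* (transcript-count) domain matters: a physical
doublet contains the union of two cells' molecules, so its depth-normalized
profile is (approximately) the arithmetic mean of the two parents'
normalized profiles, not the geometric mean that averaging log values would
produce.  The formula is exact with respect to the `log1p` normalization
convention (`expm1` inverts it to machine precision), commutative, and the
identity for equal inputs; these identities are asserted in the tests.

A negative-control pool of `n_negative = 5000` cells is sampled from every
cluster except the two parents and the query (without replacement when the
pool is large enough, otherwise with replacement and a warning).  All
pairwise Euclidean distances are then computed between the query cells and
each of: the query itself (self-pairs excluded), parent A, parent B, the
simulated doublets, and the negative control.  The verdict rule is strict
dominance on pooled means: *doublet-like* iff the mean query↔simulated
distance is smaller than each of the three alternative means.  Margins
(alternative mean − simulated mean) are reported so users can apply their
own thresholds, and the median and 5th/95th percentiles of each distance
distribution are retained for auditability.

Two aggregation choices were genuinely open and are fixed as follows: the
summary statistic is the pooled mean over all pairwise distances (not a
mean of per-cell means — equivalent for equal set sizes, simpler to audit),
and distances are computed on the log-normalized layer, *not* the per-gene
z-scaled layer, because the unlog/relog mixing arithmetic is defined on
normalized transcript counts and z-scaling would destroy that
correspondence.  A `scale_genes` operation is provided for completeness but
is not part of the distance pipeline.

## Upstream stages

**QC.**  Cells are removed when the number of detected features (genes
with count > 0) exceeds 2500 or falls below 200, or when mitochondrial
counts (genes whose name starts with `mt-`, case-insensitive) exceed 5% of
the cell total.  All three comparisons are strict, so cells sitting
exactly on a threshold are retained.  Filtering is idempotent and the
per-cell report records the reason(s) for each removal.  Thresholds are
applied pooled across the dataset (per-sample application is a
configuration away but not the default).

**Normalization.**  `value = ln(1 + count / total × 10,000)`.  Cells with
zero total are an error, named individually.  After unlogging, every
cell's values sum back to 10,000 within floating tolerance — an invariant
the acceptance tests check on a 1000-cell dataset.

**HVG selection.**  Genes are ranked by variance-stabilized standardized
variance: fit a locally weighted regression (span 0.3) of log10 variance
on log10 mean across genes with positive mean and variance; standardize
each gene's raw counts by the trend-predicted standard deviation; clip
standardized values at `sqrt(n_cells)`; rank by the variance of the
clipped values, ties broken by ascending gene index.  The local regression
is statsmodels' locally linear `lowess`; implementations of loess differ
in degree and weighting, so numerical equality with other toolkits is not
promised — the contract is internal consistency, verified against a
brute-force reimplementation of the same formulas on small matrices.  The
HVG set is computed once on the full post-QC matrix and reused by the
doublet null.

## Negative-binomial differential expression

For a cluster-vs-rest comparison, genes are prefiltered: detected in at
least 10% of one of the two groups, and |logFC| ≥ 0.25 where logFC =
`ln(mean_in(e^x − 1) + 1) − ln(mean_out(e^x − 1) + 1)` on the normalized
layer (natural-log scale; 0.25 natural-log ≈ 1.28-fold).  Each surviving
gene is fitted with an NB regression of raw counts on a membership
indicator with `ln(cell total)` as offset.  The per-gene dispersion α
(variance = μ + αμ²) is a method-of-moments estimate using group-specific
depth-scaled means, floored at 1e-8; the membership coefficient is tested
with a Wald z-test, and p-values are Bonferroni-adjusted over the tested
genes by default (Benjamini–Hochberg available).  Significance requires
adjusted P < 0.01.

The fitter is an IRLS vectorized across genes: the design matrix and
offset are shared by all genes, so the per-gene weighted least-squares
updates reduce to closed-form 2×2 solves evaluated for all genes at once.
This makes ~10,000 gene fits take about a second; the test suite checks
per-gene agreement with statsmodels' GLM (same family, same dispersion) to
~1e-6.  Method-of-moments dispersion was chosen over maximum likelihood
for speed and robustness at this scale; the Wald test, not ML-exact
dispersion, is the inferential contract.

**Marker sharing.**  The query's markers (significant, logFC > 0) are
classified as *shared* if they are also significant up-regulated markers
of parent A or parent B; `shared_fraction = |shared| / |markers|`.  A
doublet cluster inherits essentially all its markers (shared fraction ≈
1); a genuine population retains unique ones.

## The synthetic-data generator

The generator emulates the situation the procedure is designed for, not
any particular dataset: a shared baseline transcriptome (log-normal gene
weights, heavy-tailed), clusters defined by multiplicative fold changes on
disjoint marker-gene sets, per-cell library sizes from a log-normal, and
NB (gamma-Poisson) counts with a single global size parameter.
Mitochondrial genes (13, `mt-` prefixed) carry 3% of the baseline library
with extra per-cell log-normal variation so the 5% QC filter has a
realistic tail to act on.

Defaults (the study conditions for the tests): median depth 2000 counts
(σ = 0.45), NB size 2 (variance ≈ μ + 0.5μ²), and for the benchmark
datasets 5 clusters × 800 cells over 2000 genes with 80 markers per
cluster at log-normal(ln 4, 0.4) fold changes, plus a 200-cell hybrid
cluster.  Injected doublets sample two real parent cells, sum their
expected counts (what a physical doublet does), and thin back to a
singlet-like library size; a `count_mean` option averages instead.  The
genuine-hybrid *decoy* is an intermediate population: the arithmetic mean
of the parents' expression profiles plus 50 unique marker genes at
8-fold — a population that co-expresses both signatures but has a
signature of its own.

What the generator does **not** model: ambient RNA, batch effects, cell
cycle, per-gene dispersion variation, or correlated gene programs.
Passing tests therefore demonstrate the procedure's behaviour under clean
NB sampling with known structure, not its robustness to those real-data
complications.

## What the test can and cannot decide (limitations)

The distance verdict has high sensitivity but intrinsically limited
specificity, for a geometric reason worth stating plainly.  Write S for
the squared distance between the parents' mean profiles and V for the
within-cluster noise variance summed over the HVGs.  (1) Simulated doublet
profiles are averages of two cells, so their residual noise variance is
about V/2: every comparison against them starts with a ~V/2 advantage
over comparisons against real cells.  (2) For any query whose mean profile
sits near the parents' midpoint, the parallelogram law gives
d²(query, parent) ≈ d²(query, midpoint) + S/4.  (3) Any displacement of
the query that is orthogonal to the parent axis — in particular the
decoy's unique-marker signature, however strong — adds *equally* to every
squared comparison and cancels from every margin; taking square roots
shrinks margins toward zero but never changes their sign.

Consequently a genuine intermediate population that co-expresses both
parental programs in a balanced way is *always* called doublet-like by the
strict-dominance rule, no matter how distinctive its unique signature; and
in noise-dominated regimes (V ≫ S, typical of raw HVG-space distances in
droplet data) even unrelated clusters can show positive margins.  The
discriminating statistic for the artifact-vs-genuine question is therefore
the marker-sharing test: in the benchmark replicates the injected doublet
clusters show shared fractions ≥ 0.98 while the decoys show ≤ 0.43, a
clean separation.  The distance verdict remains the right tool for its
original purpose — confirming that a suspected-artifact cluster matches
the explicit doublet null — and the package reports both lines of
evidence side by side, as the underlying analysis did.

Other limitations: the verdict is cluster-level (no per-cell doublet
scores); pair sampling is with replacement, so very small parent clusters
yield duplicated pairs; and with fewer than two query cells the
query↔query context comparison is omitted.

## Problem sizes and determinism

The benchmark replicates use 4200-cell datasets (5×800 + 200 hybrid) over
2000 genes with the full 5000 pairs / 5000 negative controls; twenty
seeded replicates per scenario run in a few minutes on one CPU, and the DE
calibration uses 10,000 null genes at 200 vs 200 cells.  All randomness
flows from explicit integer seeds: the generator is bitwise reproducible
given its config, and the pipeline derives per-stage seeds from one master
seed via `numpy.random.SeedSequence`, so a re-run with the same
configuration reproduces the report exactly (timestamps aside).
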