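# Methods

This note documents the models, estimators and design choices behind
each stage, what the synthetic data emulate, and the limits of what the
test suite shows about real data.

## Study design being emulated

The package targets a two-condition bulk RNA-seq design with pooled
replicates: two pooled samples per condition (alcohol-exposed vs
control), exon-level counts from a featureCounts-style quantifier, and
a downstream machine-learning characterization of the exons that pass
an FDR filter.  All defaults in `SimulationConfig` encode that design:
2 replicates per condition, negative-binomial counts with dispersion
0.01 (biological CV 0.1 — the canonical value for genetically uniform
model organisms, appropriate here because each pooled sample averages
many inbred-strain embryos), exon means log-uniform on [50, 2000],
library size factors on [0.7, 1.4], 10% of exons with planted
differential usage, and a planted log₂ usage effect of 1.5 by default.
Planted effects take a random sign per exon, so a gene can carry exons
moving in opposite directions and show no net gene-level change — the
situation exon-level analysis exists to expose.

## Differential exon usage

**Normalization.** Median-of-ratios: per-sample median of
count/(geometric row mean) over exons positive in every sample,
rescaled to geometric mean 1.  Samples with no all-positive exon rows
raise an error rather than silently producing factors.

**Model.** For exon *e* of gene *g*, the response stacks per sample the
counts of *e* and the summed counts of *g*'s other exons.  The full
NB GLM is `counts ~ condition + exon + condition:exon` with log
size-factor offsets; the reduced model drops the interaction, and the
p-value comes from the chi²(1) likelihood-ratio statistic.  The
condition main effect absorbs gene-level differential expression, so
the interaction isolates *usage* — a change in the exon's share of its
gene.  We use condition + offsets rather than per-sample intercepts:
with two samples per condition, per-sample intercepts leave only two
residual degrees of freedom and make small-sample behaviour of the
test hopeless, while the offset formulation spends those degrees of
freedom on the residual where they stabilize inference.  A consequence
worth knowing: when one exon of a gene truly changes usage, its
siblings' usage shares shift in compensation, so sibling detections
are genuine relative-usage changes, not false positives.

**Dispersion.** Per this-vs-rest pair, a clipped within-condition
method-of-moments estimate `max((s² − m)/m², 0)` is computed on
normalized counts for both response rows and both conditions; the
estimates are averaged across all testable exons of the dataset and
the pooled value (floored at 1e-8) is plugged into every fit.  Purely
per-exon estimates from two replicates are so noisy that the chi²(1)
reference collapses (measured type-I error ≈ 0.12 at nominal 0.05);
pooling restores calibration (≈ 0.046–0.048 at true dispersions
0.01–0.05) while keeping power above 0.9 for 4-fold usage shifts at
mean 500.  The pooled estimator assumes a common dispersion scale
across exons — adequate for the simulated conditions and for pooled
samples, but real heterogeneous tissues would warrant a trended
(mean-dependent) estimator in its place.  The per-exon table still
reports each exon's own MoM estimate for inspection.

**Conventions.** log₂FC = log₂((mean control + 0.5)/(mean alcohol + 0.5))
on normalized counts — control over alcohol, so up-under-alcohol is
negative.  Usage coefficients are the fitted exon terms of the full
model per condition (control: β_exon; alcohol: β_exon + β_interaction).
Non-convergent fits report p = 1 with a flag; single-exon genes are
skipped with a logged warning.  BH adjustment is the standard step-up
(statsmodels), verified against a brute-force oracle.

## Feature assembly and annotation

Feature matrices take per-sample normalized counts and per-condition
usage coefficients (optionally the log₂FC columns, as in the miRNA
matrix) and are z-scored with the population standard deviation;
constant columns are dropped with a warning.  Meta-pathway labels
collapse a gene's (possibly dozens of) pathway annotations to at most
five functional super-groups, ranked by how many of the gene's terms
map to each group (ties alphabetical) — a guard against the
hyper-annotation that arises when every exon inherits every pathway of
its gene.  The five-label cap and frequency ranking are this package's
choice of truncation rule.  miRNA host exons are recognized by three
strand-aware locus rules on 1-based inclusive coordinates: contained
in one significant exon; overlapping the boundary of two adjacent
significant exons (both exons are reported, which is why one miRNA can
contribute several observations); or intronic with *both* flanking
exons significant.

## PCA

Standardized PCA via SVD.  Eigenvalues are score variances (population
convention), so they sum to the number of variables.  Contribution of
observation *i* to component *j*: 100·s²ᵢⱼ/(n·λⱼ); each component's
contributions sum to 100.  cos²ᵢⱼ = s²ᵢⱼ/Σ_c s²ᵢ_c; each observation's
cos² sums to 1 over all components.  Qualitative labels are projected
as barycenters of member scores and take no part in the fit.  Top
contributors are ranked by summed contribution over the chosen
components with lexicographic tie-breaks.

## Clustering

**k-means** is multi-restart Lloyd (scikit-learn, `init="random"`,
best of 50 starts).  Cluster indices are arbitrary;
`order_clusters_by_abundance` relabels them so cross-references like
"the five most abundant exons" are index-free.

**HCPC** applies Ward linkage to the factor scores; if k is not given
the tree is cut at the largest relative jump between successive merge
costs (k in 2..min(10, n−1)), then k-means consolidation seeded at the
cluster barycenters refines the partition — descent guarantees the
consolidated WSS never exceeds the hierarchical one.

**Cluster-number selection.**  The elbow is automated as the point of
maximum perpendicular distance between the (normalized) WSS curve and
its end-to-end chord — a reproducible surrogate for reading the bend
off a plot.  Silhouette maximizes mean silhouette width over k ≥ 2.
The gap statistic follows the reference R implementation's convention:
W_k is the within-cluster sum of pairwise Euclidean distances over
2n_c (not squared), references are uniform in the data's bounding box
(B = 100), and selection uses the first-k 1-SE rule.  With the
squared-distance W_k the gap curve on small matrices is monotone and
the rule degenerates; the pairwise-distance convention is what makes
the statistic informative at n in the tens.  The consensus is the
rounded mean of the three choices.

**Fuzzy c-means** is the standard Bezdek alternating scheme
(fuzzifier 2.0, tolerance 1e-6, ≤1000 iterations), implemented here
directly since no FCM library is available in the stack; membership
rows sum to 1 and hard labels take the argmax.  On the bundled miRNA
matrix (raw variables) the FCM hard partition reproduces the k-means
partition exactly.  The source study reported two borderline
observations differing between the algorithms; that detail depends on
the R implementation's initialization and is not asserted.

**Scaling mode.**  Whether to cluster scaled or raw variables is
exposed everywhere.  On the miRNA matrix the abundance-ordered
{5, 3, 14} partition arises on the *raw* variables (clusters are
defined by shared transcript abundance, which standardization
deliberately removes), while silhouette/gap/elbow selection operates
on the standardized matrix.

## Hopkins statistic and VAT

Per repeat, m = max(2, ⌈0.1 n⌉) real observations are sampled without
replacement and m uniform probes are drawn in the per-variable data
range; H_repeat = Σ(real NN distances)/(Σ real + Σ uniform), where a
real point's NN excludes only itself.  H is the mean over repeats
(default 100).  Orientation: the real-point distances sit in the
numerator, so H ≈ 0.5 for spatially random data and → 0 for clustered
data — the orientation consistent with the reported values this
package reproduces (H ≈ 0.5 random, ≈ 0.12–0.15 for the miRNA
matrix).  For generated reference data whose true column ranges are
known, passing `ranges=` uses them for the probe box; the default
sample min/max box is shrunken in high dimension and biases H upward
by ~0.015 at n = 22, p = 6.  The m and repeat defaults are package
choices.  VAT orders observations by a Prim-style MST traversal of the
Euclidean dissimilarity matrix, seeded at the observation on the axis
of maximum dissimilarity, and emits the permuted matrix for heatmap
rendering.

## SOM

Online Kohonen updates: one randomly drawn observation per step
("epoch"), Gaussian neighbourhood with radius decaying linearly from
half the larger grid side to 0.5, learning rate decaying linearly to
10% of its initial value; codebooks initialize uniformly in the data's
bounding box.  Defaults follow the emulated study's settings (learning
rate 0.01, 15,000 steps); the grid defaults to ≈ 5√n nodes.  The map
refuses data with fewer than nodes/3 observations or fewer than 3
variables: such maps cannot reduce the observation-to-node mean
distance, so the refusal is an explicit error rather than a silently
meaningless fit.  The 22-observation miRNA matrix on the study's
15×10 grid is exactly this case.  Trained codebooks are partitioned by
Ward linkage and the partition is mapped back through best-matching
units.

## Enrichment with a permutation null

Observed enrichment is the one-sided hypergeometric upper tail on the
2×2 overlap table (the EASE variant decrements the overlap by one);
fold enrichment is (k/n)/(K/N); BH across terms.  The null ensemble
draws `reps` (default 1000) gene lists of the observed size uniformly
without replacement from the universe and records every term's
p-value.  Uniformity of a term's null p-vector is judged by the KS
distance of its *mid-p* values (P(X > k) + P(X = k)/2) from
Uniform(0, 1) at threshold 0.1: ordinary upper-tail p-values of a
discrete test sit on conservative atoms and would flag every finite
term, while mid-p is near-uniform unless the term's null is genuinely
degenerate (a handful of genes with only a few attainable overlaps).
Verdicts: observed p < α with a uniform null ⇒ validated-enriched;
observed p < α with a non-uniform, low-concentrated null (null
fraction below α exceeding 2α) ⇒ false-discovery-prone; otherwise
not-enriched.  The raw (not BH) observed p drives the verdicts,
matching the histogram logic the procedure models.  Null ensembles
depend only on list size and are cached accordingly.

## What the synthetic data do and do not show

The generator reproduces the count distribution family, the pooled
two-by-two design, planted usage effects with within-gene sign
opposition, miRNA-hosting exons and a meta-grouped catalog.  It does
not model dispersion trends with expression level, correlated exons
within a transcript, GC/length biases, mappability artifacts or
annotation errors — so passing tests demonstrate correctness of the
statistical machinery under the stated model, not robustness to those
real-data pathologies.  Test and acceptance problem sizes (hundreds to
~2000 exons, 22-observation fixture matrices, B = 100 gap references,
1000-list nulls) were chosen so the full suite and the acceptance
script each run in minutes on one CPU; they are the package's
reference scales, and all of them are parameters.

## Numerical choices

Dispersion floor 1e-8; log₂FC pseudocount 0.5; FCM distance floor
1e-12; PCA rank cut at 1e-12 of the leading singular value; gap W_k
floored at 1e-300 before logs; KS uniformity threshold 0.1; fuzzy
tolerance 1e-6.  Empty k-means clusters are handled by scikit-learn's
relocation rule.  Stochastic operations take explicit seeds; pipeline
stages derive per-stage seeds from the master seed by hashing, and
every report directory embeds the config hash and stage seed.
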