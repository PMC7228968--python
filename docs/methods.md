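# Methods

`leukotype` implements an intra-sample transcriptional-heterogeneity analysis
for droplet scRNA-seq of acute lymphoblastic leukemia: consensus clustering of
cancer cells within a sample, transfer of a developmental-state pseudotime
learned on healthy lymphoid maturation, ribosomal-protein (RP) expression
fraction analysis, metacell copy-number profiling against healthy controls,
and per-cell mutant-allele enrichment testing. Every stage is exercised
end-to-end on synthetic data with known ground truth; this note records the
models, the defaults and why, and what the synthetic conditions do and do not
establish about real data.

## Synthetic study conditions

The generator draws cells along a latent maturation axis `t ∈ [0, 1]`
(pseudotime), uniform within each of three equal populations (stem-like,
intermediate, mature — thirds of the axis). A configurable fraction of genes
(default 0.3) carries a log-linear trajectory signal: the gene's expected
share of the library is proportional to `w_g · exp(b_g (t − 1/2))` with
gene-specific slopes `b_g ~ N(0, 1.2²)`, so maturation is recoverable without
hand-picked markers. Counts are gamma-Poisson (negative binomial) with a
single shared size parameter θ (default 5, `var = µ + µ²/θ`), library sizes
log-normal around 2,500 UMIs — in the range of median UMI counts typical for
10x bone-marrow data.

The expected RP fraction of each cell is `base + slope · t`, clipped to
(0, 1); the expected counts are constructed so this law holds exactly
(RP mass `f(t)` of the library, non-RP mass `1 − f(t)`). Defaults
`base = 0.35`, `slope = −0.15` give RP fractions falling from ~35% in
stem-like to ~20% in mature cells — a realistic range for lymphoid cells and
the inverse maturation/RP relation the analysis is designed to detect. The
baseline is exposed as a parameter, not a constant of the method.

Leukemia samples consist of transcriptional subclusters: cluster 1's latent
pseudotime is Normal(0.3, 0.08) clipped to [0, 1]; cluster k is shifted by
`(k−1) · shift` (default 0.3). By default one copy-number block — a 1.5×
gain over ~11.5% of the genome (genes 260–490 of 2,000) — multiplies gene
means in the last cluster, emulating the cluster-specific chromosome-arm
gains observed in ETV6-RUNX1-like samples. The block is part of the default
study conditions because intra-sample clusters in real data differ by more
than a pseudotime shift; without any cluster-private expression signal the
subclusters are not a detectable transcriptional structure at these sample
sizes. Allele calls are tri-state (no coverage / ref / alt): each
cell×variant pair is covered with probability 0.25; covered pairs are alt
with probability 0.10, except one designated variant whose alt odds are
multiplied by 8 in the last cluster.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, gene-length or GC biases, cell-type-specific dispersions, and any
read-level structure. Passing tests therefore show the pipeline recovers the
stated statistical structure under a clean negative-binomial world; they do
not certify performance under real-data artifacts.

## Preprocessing

Genes expressed in at least 5 cells, cells with at least 200 detected genes
and mitochondrial fraction strictly below 8% are retained; the gene filter
runs first, then the cell filter, in one pass (no fixpoint iteration —
iterating changes the result only marginally and is deliberately off).
Expression is library-size normalized to 10,000 and ln(1+x)-transformed (the
scale factor is a parameter; the analysis is insensitive to it). Cell-cycle
S and G2/M scores are the module-score construction: mean expression over
the signature minus the mean over a control set sampled (seeded) from
expression-matched bins (25 bins, 50 controls per bin); the phase rule is G1
iff both scores ≤ 0, otherwise the larger score's phase (ties to G1 —
a documented convention, since no standard rule exists). Per-gene OLS
residuals remove nUMI, mitochondrial fraction and the two cycle scores.

Highly variable genes are selected per sample by binned standardized
dispersion — var/mean of normalized expression, z-scored within 20
equal-frequency mean bins — and pooled: a gene is kept when it is in the
top-1000 list of at least two samples. Two numerical guards: the bin count
adapts so each bin holds at least ~10 genes, and the within-bin SD is floored
at 5% of the global dispersion SD so bins of near-identical dispersion cannot
turn numerical noise into large z-scores.

## Consensus clustering

Cells are embedded with the top 20 principal components (deterministic sign
convention: each component's largest-magnitude loading is positive), joined
in a k=20 shared-nearest-neighbor graph with Jaccard edge weights
(neighborhoods include the cell; edges below the conventional 1/15 prune
threshold are dropped), and partitioned with Louvain at resolutions 0.1 to
3.0 in steps of 0.1 — 30 solutions, grid built by integer steps so the 3.0
endpoint is exact. All pairwise Adjusted Rand Index values are computed and
the solution with the highest mean ARI against the others (self-comparison
excluded; including it would shift all means equally) is retained, ties
going to the lowest resolution (prefer coarser, more stable solutions).
Clusters holding less than 10% of a sample's cells (strict, against the
pre-filter count) are discarded.

One Louvain restart is run per resolution. Each restart's RNG stream is
derived from the global seed (`seed + 7919·i`): reusing the byte-identical
stream at every resolution makes high-resolution fragmentations artificially
similar to one another through the shared random vertex-processing order,
inflating their mutual ARI and biasing the consensus toward fragmented
solutions — an artifact of the RNG, not a property of the data.

Known limitation: on small samples (fewer than ~1,000 cells per cluster at
the default noise) the consensus can prefer fine fragmentations and the
small-cluster filter then discards everything; the pipeline surfaces this as
an explicit error rather than producing a degenerate DE comparison.

## Differential expression and over-representation

Single-cell expression is zero-inflated, so each gene is tested in two
parts: a Fisher exact test on the 2×2 detection table (expressed vs not ×
group) and a two-sided Wilcoxon rank-sum test on the positive values, the
two p-values combined by Fisher's method; when only one part is defined it
stands alone, and a gene with no expression in either group gets p = 1,
log-fc = 0. The log fold-change is the difference of mean log-normalized
expression (natural log), matching the convention under which thresholds of
0.75 and 1 are interpreted. Benjamini–Hochberg correction is applied within
each comparison; the top list is ordered by q, ties by |log-fc|. This
two-part test follows the same hurdle logic as covariate-adjusted hurdle
GLMs but is self-contained and exactly testable; its null behaviour is
verified by simulation (false-positive rate within [0.03, 0.07] at α=0.05).
Gene-set over-representation is a one-sided hypergeometric upper tail per
set with BH across sets; no length-bias correction is applied.

## Pseudotime and the developmental-state regressor

The healthy maturation spectrum is a LOWESS fit (span 0.5) of the second
embedding coordinate on the first, densely sampled at 500 points; vertical
spectra are rejected with advice to swap axes (documented limitation of the
fixed regression direction). The curve is oriented so the end nearer the
stem-like cells' centroid is pseudotime 0. Cells project to the nearest
sample point (ties to the smaller arc length; projection is checked against
exhaustive search); cells farther than mean + 3 SD (sample SD, one pass) are
discarded; arc positions of the retained cells are min–max scaled to [0, 1].

The regressor is a feed-forward network with one hidden layer of 15 sigmoid
units and a linear output, L2 decay 1e-4, trained by L-BFGS to tolerance
1e-6 or 500 iterations on per-gene standardized expression of the variable
genes. Validation uses 100 independent random 70/30 splits; the mean
held-out RMSE is reported. The final model is trained on all healthy cells
and applied to leukemia cells; genes missing at prediction time are imputed
as standardized zero (error above 50% missing), and raw outputs are clipped
to [0, 1] with the clip count recorded.

## RP fraction and shift tests

The RP fraction is computed on raw UMI counts (the count matrix stores UMIs;
"raw reads" is read as raw UMIs): RP-gene counts over total counts per cell.
The RP set defaults to the RPS/RPL prefix rule; an explicit curated list
(e.g. a 97-gene set) can be supplied and takes precedence. Pseudotime shifts
between intra-sample clusters use a two-sided Mann–Whitney U test (KS
available as an option; the choice is a documented default) with BH across
cluster pairs; the pseudotime/RP relation is Spearman rank correlation.

## Metacell CNV profiling

Each cluster is split at random (seeded) into 30 equal-sized metacells
(sizes differ by at most one) whose raw counts are summed; totals are
conserved exactly. Profiles are windowed log2 ratios against healthy control
metacells: normalize each metacell to 1e5, log2(1+x), subtract the control
mean per gene, smooth with a centered 101-gene moving average within each
chromosome (window truncated at chromosome edges), and re-center each
metacell at its genome-wide median. Segments are maximal runs of ≥ 50 genes
beyond ±0.2; a cluster-level call requires the same-direction segment in at
least half the cluster's metacells. The thresholds are documented defaults
chosen for the 1.3–2× events of interest; single-cell-resolution CNV calling
is out of scope. Chromosome ordering is lexicographic on the annotation's
chromosome names.

## Mutant-allele enrichment

Variants with alt calls in more than 0.1% of a sample's cells (strict) are
testable. For each testable variant and cluster pair, the 2×2 table of
alt-carrier vs covered non-carrier × cluster is tested with Fisher's exact
test (two-sided by the sum-of-smaller-probabilities rule; odds ratio ad/bc,
infinite when bc = 0 with ad > 0); uncovered cells are excluded as
uninformative. BH spans all (variant, pair) tests in the sample; with more
than two clusters, pairwise tables are used. Sparse tables make the discrete
p-values conservative (stochastically larger than uniform), which the null
simulation confirms.

## Orchestration and problem sizes

`run_pipeline` executes the stages in dependency order, persisting each
stage's outputs so stages can be re-run individually; per-stage seeds derive
from the master seed by hashing the stage name, and a manifest echoes every
resolved parameter. The packaged analyses run at 2,000 cells per sample,
2,000 genes, 100 cross-validation splits and 2,000-variant null panels —
sizes chosen so each recovery property is measured with comfortable
statistical margin while a full run stays under a minute on one core.
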