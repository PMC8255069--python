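# Methods

This note documents the statistical models, the tunable parameters, the
synthetic-data generator, and the numerical choices behind `coexrules`.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Differential expression stand-in

The pipeline's DE stage is intentionally a simple, transparent stand-in
for a negative-binomial GLM engine:

* **Low-count filter.** A gene is removed when its count is below
  `min_count` (default 10) in *strictly more than* `sample_frac`
  (default 0.9) of samples; a gene low in exactly 90% of samples is
  retained. The filter is idempotent.
* **Normalization.** Median-of-ratios size factors: factor<sub>j</sub>
  = median over genes with a positive geometric mean of
  count<sub>gj</sub> / geomean<sub>g</sub>. Requires at least one gene
  with nonzero counts in every sample. Factors are relative (only
  their ratios matter); multiplying one sample's counts by *c*
  multiplies its factor by *c* relative to the others.
* **Test.** Welch's two-sample t-test on log2(normalized + 1) per gene
  (pseudocount 1). Genes with zero variance in both groups and equal
  means — including all-zero genes — get p = 1.
* **Fold change.** log2 of the ratio of group means of normalized
  counts with pseudocount 0.5.
* **Multiple testing.** The Benjamini–Hochberg step-up,
  padj<sub>(i)</sub> = min<sub>j≥i</sub> min(1, p<sub>(j)</sub>·m/j),
  implemented directly (a few lines) and cross-checked in the tests
  against both the brute-force definition and statsmodels.
* **Selection.** padj strictly below `fdr` (default 0.05) *and*
  |log2FC| ≥ log2(`min_fold`) (default 2, inclusive).

This stand-in is adequate for the pipeline's purpose — everything
downstream consumes only the normalized expression matrix and a DE gene
list — but it does not shrink dispersions or fold changes and will be
less powerful than a dedicated NB engine at n = 3 replicates.

## Co-expression modules

* **Similarity.** s<sub>ij</sub> = |Pearson cor(x<sub>i</sub>,
  x<sub>j</sub>)| on log2(normalized + 1); the network is unsigned.
  Constant genes are dropped with a warning. At least three samples are
  required.
* **Soft threshold.** a<sub>ij</sub> = s<sub>ij</sub><sup>β</sup>,
  β ≥ 1. Raising β shrinks weak correlations toward zero while keeping
  the network weighted; every off-diagonal entry is non-increasing
  in β.
* **Scale-free fit index.** Weighted connectivities k<sub>i</sub> =
  Σ<sub>j≠i</sub> a<sub>ij</sub> are split into `n_bins` (default 10)
  equal-width bins on the raw k scale; the per-bin frequency p(k) is
  regressed on log10(mean k per bin) in log10 space, and the index is
  −sign(slope)·R². Empty bins are dropped; all-equal connectivities
  give NaN. Binning on raw k (not log k) is the convention of the
  standard co-expression tooling and behaves canonically: the index
  rises with β and clearly separates preferential-attachment from
  Erdős–Rényi degree laws.
* **Choosing β.** `select_beta` scans candidates 1–20 and returns the
  smallest β whose fit index reaches `target_fit` (default 0.8),
  otherwise the β with the maximal fit. Two robustness guards are part
  of the design: (a) candidates whose mean connectivity falls below
  `min_mean_connectivity` (default 1.0) are excluded — the fit index
  keeps climbing as large powers dissolve the network into isolated
  nodes, so an unguarded first crossing can select a degenerate β; and
  (b) the fit curve is smoothed with a centered rolling median of
  width 3 before thresholding, since the binned index is noisy in β.
  The full fit table is always returned for auditing.
* **TOM.** Unsigned topological overlap, TOM<sub>ij</sub> =
  (L<sub>ij</sub> + a<sub>ij</sub>)/(min(k<sub>i</sub>, k<sub>j</sub>)
  + 1 − a<sub>ij</sub>) with L<sub>ij</sub> = Σ<sub>u≠i,j</sub>
  a<sub>iu</sub>a<sub>uj</sub>; self-adjacency is zeroed internally,
  the diagonal is 1 by convention, and the result is clipped to [0, 1]
  and symmetrized against floating-point drift. Cliques have TOM ≡ 1.
* **Clustering and cutting.** Average-linkage agglomerative clustering
  of 1 − TOM (scipy). Modules come from a *static* tree cut: the tree
  is cut at `cut_height_quantile` (default 0.99) times the maximal
  merge height; subtrees below the cut with at least `min_module_size`
  (default 30) genes become modules, labelled by decreasing size
  (1 = largest, with the conventional turquoise/blue/brown color
  aliases); everything else is unassigned (grey, label 0). The static
  cut is the simple published mode of tree cutting; the adaptive
  ("hybrid") variant is out of scope.
* **Eigengenes and merging.** A module eigengene is the first right
  singular vector (per-sample scores) of the row-standardized module
  submatrix, unit norm, sign-fixed to correlate positively with the
  module's mean profile (ties broken by making the first nonzero entry
  positive, so output is deterministic and gene-order invariant).
  Modules whose eigengene dissimilarity 1 − cor is below `merge_cut`
  (default 0.25, i.e. more than 75% similarity) are merged iteratively,
  closest pair first, recomputing eigengenes after each merge; the
  procedure is idempotent at a fixed cut. Note that two perfectly
  anticorrelated standardized profiles are a rank-one configuration:
  the first component explains all the variance, not half.

## Network analysis

Edges are pairs with TOM (or adjacency) weight ≥ `edge_threshold`
(default 0.2; the bound 0 < t ≤ 1 is inclusive on the right so that a
threshold of 1 legally yields an empty edge set). Centralities follow
the common network-analyzer conventions: unweighted (hop-count)
shortest paths by default with a `weighted=True` option using 1/weight
distances; betweenness normalized by (n−1)(n−2)/2 with endpoints
excluded; closeness as the simple per-component variant
(n<sub>reachable</sub> − 1)/Σ h(i, j), 0 for isolated nodes; clustering
coefficient as the neighborhood edge density, 0 for degree < 2.
Density is 2|E|/(n(n−1)). The degree filter removes nodes of degree <
`min_degree` (default 5) in a *single pass* over degrees computed on
the input graph; an iterative k-core variant is available behind a
flag. Hubs are nodes with degree ≥ `hub_degree` (default 8), ranked by
degree, then betweenness, then id. All of these are computed via
networkx; the tests check them against an independent brute-force
shortest-path-enumeration oracle.

## Discretization and rule mining

Equal-frequency binning per gene: sort, split into k contiguous groups
whose sizes differ by at most one (earlier groups take the extra
element), put each boundary at the midpoint between adjacent group
extremes, and label each value by its interval. Two deliberate
conventions: tied blocks that would straddle a boundary move entirely
into the lower bin (sizes rebalance; a gene with no valid strictly
increasing boundary, e.g. a constant gene, is dropped with a warning),
and labels depend only on ranks, so any strictly increasing transform
of a gene leaves its labels unchanged. A floating-point guard keeps
each boundary strictly below the upper group's minimum even when the
midpoint of two adjacent representable numbers rounds onto one of them.
With k = 2 the labels are 0 = under-, 1 = over-expressed, and samples
become transactions whose items are the over-expressed genes
(under-expression is absence, in the market-basket sense).

Apriori is level-wise with prefix joins and anti-monotone subset
pruning. All supports, confidences and lifts are `fractions.Fraction`
rationals: support thresholds compare as count ≥ ceil(min_support·|D|)
(with 9 transactions, support 0.5 means at least 5 of 9), and the
inclusive lift ≥ 2 bound is exact rather than subject to float wobble.
Rule generation emits X ⇒ Z∖X for every frequent Z (default maximum
itemset size 5) and every non-empty proper subset X with confidence ≥
`min_confidence` (default 0.99); output order is lift desc, support
desc, lexicographic — deterministic and diffable.

**A parity constraint worth knowing.** With |D| transactions and
min-support s, every rule's consequent has support ≥ ceil(s·|D|)/|D|,
so lift ≤ |D|/ceil(s·|D|). At s = 0.5 this cap is exactly 2 for even
|D| and 2|D|/(|D|+1) < 2 for odd |D|. Combined with two-bin
equal-frequency discretization (each item over-expressed in ⌊|D|/2⌋ or
⌈|D|/2⌉ samples), a lift ≥ 2 rule at support 0.5 can exist only for an
even sample count, where a perfectly co-binarizing pair attains
support 1/2, confidence 1 and lift exactly 2. With nine samples the
thresholds are jointly unsatisfiable — no dataset whatsoever can
produce a surviving rule — which is why the worked example and the
end-to-end tests use an even (12-sample) design for rule recovery.

## Function prediction

For each unannotated gene appearing in any lift-filtered rule
(antecedent and consequent membership count equally), the annotated
partner genes across its rules are tallied per category, counting a
partner once per rule. The majority category is predicted; ties are
flagged ambiguous with all tied categories listed; genes with no
annotated partner are excluded. Predictions are order-invariant and
re-derivable from the stored supporting rules. This majority-vote
formalization is the package's own; no probabilistic confidence score
is attached beyond the partner counts.

## Synthetic data

`generate_counts` emulates a 3-treatment × replicate antennal RNA-seq
design (default 9 samples = 3 × 3):

* Gene baselines: log2 mean μ<sub>g</sub> ~ N(`baseline_log_mean` = 6,
  `baseline_log_sd` = 1), i.e. typical means of ~64 counts spanning
  roughly 16–256.
* Per-sample biological variation: `gene_noise_sd` (default 2.0, log2
  units) times a latent standard normal. Module genes share a per-
  module factor with loading √ρ; rule-group genes share a group factor
  with loading √`rule_group_cor` (default 0.99, "designed to
  co-binarize").
* Counts: negative binomial with dispersion `nb_dispersion` (default
  0.1; Poisson at 0) around 2^(log2 mean).
* Planted DE: a `de_gene_frac` subset of genes (outside rule groups)
  gets +`de_log2fc` (default 2) in the `de_treatment` samples.

Two calibration details make the planted correlation a *contract*
rather than an aspiration: factor loadings are inflated by the
delta-method attenuation of log-count correlations (NB noise with the
lognormal E[1/mean] correction), and each shared factor is
standardized to zero mean and unit sample variance, because the
realized variance of a raw n-sample Gaussian draw scatters by tens of
percent and would otherwise make the realized within-module
correlation drift far from its target for unlucky seeds. At the
default target 0.7 the realized within-module |cor| of log2 counts is
≈ 0.7 ± 0.05 (asserted within ±0.15 in the tests).

What the generator does *not* emulate: library-size variation beyond
the lognormal means (size factors are ≈ 1 by construction), gene–gene
correlation outside planted structure, outlier samples, batch effects,
length/GC biases, or the sequencing depth of a real antennal library.
Passing tests therefore demonstrate correctness of the algorithms on
data satisfying the stated model, not robustness to every artifact of
real RNA-seq.

`generate_transactions` plants jointly-inserted itemsets
(probability `itemset_prob` per transaction) over independent
Bernoulli(`noise_prob`) item noise; `generate_test_graph` provides
path/star/complete/Erdős–Rényi/preferential-attachment fixtures. All
generators take an explicit seed, use one private RNG stream, and are
bit-reproducible.

## Pipeline defaults and determinism

The driver runs preprocess/DE → co-expression → network → discretize →
rule mining → prediction with the study defaults (min_count 10 /
frac 0.9; FDR 0.05; two-fold; β 12 or `auto`; min module size 30;
merge cut 0.25; edge threshold 0.2; degree filter 5; two bins; support
0.5; confidence 0.99; lift 2; max rule length 5), validates the
configuration up front (unknown keys are rejected), logs each stage,
and writes a JSON manifest with the package version, parameters, input
SHA-256 checksums and per-file record counts. No stage uses a random
number generator, so identical inputs give byte-identical outputs.

## Problem sizes used in the checks

The bundled checks run at desk scale, chosen so the full suite and the
acceptance script each finish in seconds on one CPU: module recovery
uses 500 genes (4 × 50 planted + 300 background) × 20 samples across
10 seeds; the global-null FDR simulation uses 300 genes × 9 samples
across 200 (tests) or 100 (script) replicates; oracle equivalences use
≤ 10 items / ≤ 8 transactions and graphs of ≤ 30 nodes; end-to-end
rule recovery uses 40 genes × 12 samples across 50 seeds.

## Known limitations

* The DE stand-in trades power for transparency (no dispersion
  shrinkage).
* The static tree cut needs a clear height separation between module
  clades and the background; at extreme soft-threshold powers TOM
  compresses toward zero and any fixed-quantile cut degrades — the
  `select_beta` connectivity guard exists precisely to avoid that
  regime.
* Apriori is exponential in the worst case; the default maximum
  itemset size of 5 keeps mining tractable and matches the shape of
  rules of interest (four-gene antecedents, one-gene consequents).
* With an odd number of samples, the support-0.5 / lift-2 thresholds
  are jointly unsatisfiable under two-bin equal-frequency
  discretization (see the parity note above); analyses on odd designs
  should either relax the lift bound or use a different support
  threshold.
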