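# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `valvemir`.

## Study design being modeled

The package implements the analysis chain of a two-group valve-tissue
expression study: diseased aortic valves (cases) against non-diseased
controls, with log2-scale miRNA and mRNA matrices from the same samples, a
precomputed miRNA→gene target-prediction score table (scores in [0, 1]),
gene sets in GMT format, a drug–gene interaction export, and a qPCR Ct
table for validation. Default group sizes follow that design: 15 cases vs
16 controls for array-based differential expression, a 10+10 paired subset
for miRNA/mRNA integration, and 16 vs 36 for qPCR validation.

## Differential expression

Per feature, Welch's unequal-variance *t*-test on log2 values. The groups
differ in size and provenance (surgical vs post-mortem tissue), so equal
variances are not assumed. P-values are adjusted with the
Benjamini–Hochberg step-up procedure implemented directly from its
definition (`adj_(i) = min_{j≥i} min(1, p_(j)·m/j)` on the sorted scale);
the test suite cross-checks it against statsmodels. Degenerate features
(zero variance in both groups) get *t* = 0, *p* = 1 when means agree, and
*p* = 0 otherwise. No variance pre-filter is applied before testing.

Fold change is the signed log2 mean difference (case − control) and its
linear ratio `2^Δ`; "more than 2-fold up" means `log2FC > 1`. When probe
matrices need collapsing to unique gene identifiers, the probe with the
highest mean expression per gene is kept.

Group-structure summaries are deliberately plain: PCA via full SVD with a
deterministic sign convention, and average-linkage hierarchical orderings
(correlation distance for features, Euclidean for samples) with rows
pre-sorted by feature ID so the ordering is invariant to input row order.

## Co-expression network and Markov clustering

Edges join differentially expressed miRNAs with pooled-sample Pearson
*r* > 0.5 by default; because the literature tool this emulates does not
document whether the rule was signed or absolute, an `|r| > threshold` mode
is provided. Signed correlations are stored as edge weights either way.
Constant features are dropped with a warning rather than raising.

MCL is implemented from scratch on the dense adjacency matrix:

1. take edge-weight magnitudes (transition probabilities must be
   non-negative), add self-loops of weight 1 (standard practice; damps
   oscillation on bipartite-like structure), column-normalize;
2. iterate expansion (matrix power, default 2) and inflation (entrywise
   power, default 2.0, then column renormalization), pruning entries below
   1e−5 and renormalizing, until the maximum entry change is below 1e−6 or
   100 iterations (non-convergence returns a flagged result, not an error);
3. attractors are rows with nonzero diagonal mass; attractors exchanging
   flow are merged into one attractor system; each node joins the system of
   the attractor with the largest incoming mass, ties to the smaller
   cluster id. Cluster ids are renumbered by each cluster's
   lexicographically smallest member, making output deterministic given the
   node set.

Nodes in different connected components can never share a cluster, and the
partition is invariant to node relabeling (verified by test).

## Integration and the permutation null

Candidates are (DE miRNA, DE gene) pairs present in the target-score table
with mean score ≥ 0.8 (duplicate pair rows, e.g. per-transcript scores, are
averaged at load). Spearman ρ is computed per candidate on the paired
samples via midranked, centered, unit-norm rows (a dot product per pair),
with the t-approximation p-value on *n* − 2 df; exact enumeration is not
useful at *n* = 20. The default test is **one-sided for negative ρ**,
because repression is the mechanism being modeled; a two-sided mode exists
and is a documented open choice. BH adjustment runs across all candidates.

The permutation null shuffles the assignment of DE-miRNA identities to
DE-miRNA expression rows — breaking the identity→target-score link while
preserving the expression correlation structure — and re-runs the identical
calling procedure. With *b* of *N* permutation counts ≥ the observed count,
`p = (b+1)/(N+1)`: the observed data is counted as one permutation, so *p*
is never 0, and "observed above all of 100 permutations" yields
`1/101 ≈ 0.0099 < 0.01`. The exact Clopper–Pearson CI on *b/N* comes from
Beta quantiles: for 0/100 at 95% the upper bound is
`1 − 0.025^(1/100) ≈ 0.0362`.

## Enrichment

Two-sided hypergeometric p-value as the doubled smaller tail
(`min(1, 2·min(P(X≤k), P(X≥k)))`) — the exact two-sided construction used
by common enrichment GUIs is not published, and tail-doubling is the
conventional, conservative choice. Sets are trimmed to the universe (by
default, all genes of the collapsed mRNA matrix) before testing; only sets
overlapping the query are tested unless depletion is requested. The
implementation is checked against brute-force mass summation on all small
universes.

## Drug-target prioritization

The integrated network is the bipartite graph of significant interactions.
A gene qualifies if it is in the network, up-regulated more than the fold
threshold (default 2), and has at least one drug whose interaction type
(case-insensitive exact token) is in {inhibitor, antagonist, antibody}.
The degree threshold semantics are ambiguous in the source workflow
("more than two" vs "two or more"); the default here is **degree ≥ 2**,
matching the reported tables, and it is configurable.

## qPCR statistics

Ct values above 35 cycles are censored as not detected and excluded (not
imputed). ΔCt subtracts the arithmetic mean Ct of the reference probes
(equivalent to the geometric mean of linear quantities); samples missing a
detected reference are dropped with a logged count. Group comparisons use
Mann–Whitney U: the exact permutation distribution when the combined sample
is ≤ 20 and tie-free, otherwise the normal approximation with tie and
continuity corrections (the method used is recorded in the output).
Extreme-outlier trimming is a display concern only; statistics always use
all retained data.

Reference stability follows the NormFinder model: each sample is centered
across the candidate panel (removing loading effects), then per group each
candidate's intragroup variance is estimated from two-way residuals with a
sampling-error correction — for G candidates,
`σ̂²_g = (G·s²_g − s̄²·G/(G−1)) / (G−2)` clamped at 0, which is unbiased for
the generating variance under the model — and its intergroup deviation is
the difference of its group mean from its overall mean after centering.
Stability is the group-average of `|intergroup deviation| +
sqrt(intragroup variance / n_group)`; lower is more stable. The Bayesian
shrinkage of the original formulation is omitted as unnecessary at the
panel sizes used here; the estimator's parameter recovery is verified by
simulation.

## The synthetic-data generator

`valvemir.synth` emulates the statistical structure the pipeline must
recover, with every planted feature recorded in a ground-truth object:

- **Samples**: 15 cases / 16 controls by default; ages older in cases,
  mirroring surgical vs post-mortem sourcing.
- **DE miRNAs**: 106 of 300, with 80/106 down-regulated in cases; log2
  shift ±1.5 (≈2.8-fold, the magnitude of reported array fold changes) on a
  within-group SD of 1.0.
- **Clusters**: 5 direction-homogeneous clusters over the DE miRNAs, each
  driven by one latent factor, `x = √ρ·z_c + √(1−ρ)·ε`, giving pairwise
  correlation exactly ρ (default 0.7) in expectation.
- **Repression**: 150 planted couplings (10 "hub" genes with 3
  direction-concordant parent miRNAs each, the rest one-to-one). A target
  is a negative linear function of its standardized parent(s) plus noise;
  the slope is the Gaussian-copula inverse `r = 2·sin(π·ρ_s/6)` of the
  requested Spearman magnitude (default 0.8). Targets also receive a small
  direct disease shift (0.75 log2) in the de-repression direction —
  biologically, target genes respond to the disease partly through miRNA
  loss and partly through co-regulation — which makes hub genes exceed the
  2-fold drug-target threshold naturally.
- **Target scores**: planted pairs score in [0.85, 1.0]; decoy
  (predicted-but-uncoupled) pairs in [0.5, 0.95], so about a third of
  decoys pass the 0.8 threshold and genuinely compete. Decoys are drawn
  between **direction-concordant** DE features: in a two-group design, an
  uncoupled pair with discordant fold-change directions is statistically
  confounded with true repression at the pooled-sample level — that
  confound is precisely what the permutation null quantifies — so a
  false-positive rate is only identifiable against the concordant class.
- **Gene sets**: one set equal to the planted target genes plus random
  background sets. **Drug table**: actionable drugs on the planted hub
  genes and some peripheral targets, non-actionable types and unknown genes
  as decoys.
- **qPCR**: reference probes at Ct ≈ 20 with a shared per-sample loading
  offset, one target with a planted fold change (`ΔΔCt = −log2(fold)` by
  construction, exact at zero noise), null targets, and one low-abundance
  probe straddling the detection limit to exercise censoring.

All randomness flows from a single seed through named numpy generators;
outputs are byte-reproducible.

What the generator does **not** emulate: probe-level array artifacts, batch
or RNA-degradation effects, heavy-tailed noise, correlated decoy structure
beyond group shifts, or realistic miRNA–target score distributions. Passing
recovery tests therefore demonstrate correctness of the inference machinery
under the stated generative model, not performance on real arrays.

## Problem sizes and runtime

Tests and the acceptance script run the full default design (300 miRNAs ×
1000 genes × 31 samples, 100 permutations) and 20-seed recovery loops for
the stochastic summaries; the complete suite runs in a few seconds on one
CPU. The pipeline writes a manifest (tool version, config hash, seed,
per-stage counts) and headers every output file with the same triple;
reruns with identical config and seed are byte-identical, which the suite
asserts.

## Known limitations

- The one-sided-vs-two-sided choice for interaction calling, and whether
  the 0.8 score threshold belongs inside the integration step, are
  documented defaults, not settled facts about the emulated workflow.
- BH controls FDR across candidates but candidate p-values share samples;
  the permutation null is the intended global check, not the per-pair FDR.
- The MCL attractor-overlap resolution (largest incoming mass, ties to the
  smaller cluster id) forces a disjoint partition; native MCL can produce
  overlapping clusters.
- Fold-change-based drug filtering inherits any compositional or
  normalization bias present in the input matrices; the package starts from
  normalized data and cannot detect such bias.
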