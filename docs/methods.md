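# Methods

`grafttx` re-implements, as a tested library, a comparative time-series
transcriptome analysis of interfamily plant grafting: three species
(a focal species with interfamily grafting ability plus two comparators)
are profiled by bulk RNA-seq at 0 (intact), 3 and 7 days after grafting
(DAG) under three treatments — interfamily grafting, self-grafting and
wounding — and the graft-specific part of the response is isolated,
compared across species, and tested for functional enrichment.  The
package operates on processed gene-level FPKM tables; read QC, alignment
and quantification are upstream of its scope, as is running the
translated homology search whose tabular output it consumes.

## Extraction rule and treatment-pattern classes

A gene is *upregulated* along a treatment series when, with pseudocount
c and fold threshold F (default 2),

    (x3 + c) > F * (x0 + c)   and   x7 > x3   and   max(x3, x7) > floor

with all inequalities strict: "more than twice" excludes exactly
two-fold, and a 7-DAG tie is not a rise.  x0 is the intact (time-0)
level shared by all treatments of a species.

* **Pseudocount** c = 1 FPKM by default.  The literal rule (c = 0) is
  undefined in spirit for genes silent in intact tissue, where any
  expression is an infinite fold change; one FPKM is a conventional
  noise-scale offset and c = 0 restores the literal rule exactly.
* **FPKM floor.**  The floor applies to the peak of the *interfamily*
  series only, where it is used to equalise extracted-set sizes between
  species (published values: 10 for *N. benthamiana*, 12 for *I. nil*,
  none for the focal species).  It deliberately does not enter the class
  predicate below.
* **Replicate aggregation** is the arithmetic mean of replicate FPKMs
  (median available).  It is permutation-invariant and unbiased; the
  upstream study pooled tissue from ten grafts per replicate, so heavy
  robustification is not needed at this stage.

Extracted genes are partitioned by evaluating the same rise predicate
(floor removed) on the self-graft and wounding series:

| class | self-graft | wounding | reading |
|-------|-----------|----------|---------|
| 1 | rising | not rising | graft-associated; wound response fades by 7 DAG |
| 2 | not rising | not rising | specific to the interfamily graft |
| 3 | rising | rising | generic wound/regeneration response |
| 4 | not rising | rising | all other patterns |

Reusing one predicate keeps a single definition of "rising" across
extraction and classification; because the published class descriptions
are qualitative, class counts on any real dataset are structural output
(they always partition the extracted set), not promised numbers.

## Profile analyses

* **Ratio profiles.**  Each non-intact condition is summarised per gene
  as log2((x_t + c)/(x0 + c)), c = 1.  The log scale makes up- and
  down-regulation symmetric under the Euclidean distances used below;
  raw ratios are available by taking 2^x.
* **Ward clustering** of condition vectors uses Euclidean distance with
  Ward's minimum-variance criterion (scipy linkage).  Merge heights are
  reported as the increase in total within-cluster sum of squares
  (scipy's sqrt(2·ΔSSE) heights are converted back), so identical points
  merge at exactly zero and heights are non-decreasing.  The test suite
  checks the heights against a brute-force implementation that
  recomputes cluster SSE from scratch at every step.
* **PCA** is computed by SVD of the per-feature mean-centred matrix with
  no per-gene scaling (the profiles are already on a common log-ratio
  scale).  Variance fractions are eigenvalue shares; an all-identical
  input yields zero fractions rather than an error.  Component signs
  follow the largest-absolute-loading-positive convention for
  deterministic reruns.
* **Self-organizing map.**  Batch training on a rectangular grid
  (default 4×4, 50 epochs): each epoch assigns profiles to their nearest
  codebook and replaces every codebook by the neighborhood-weighted mean
  of the data.  The neighborhood is a Gaussian in grid distance,
  *truncated at the current radius*, and the radius shrinks linearly
  from half the grid diagonal to 0.5; past the point where the radius
  drops below the grid spacing only the winning node is updated, so the
  final phase is exact k-means refinement and a 1×2 map on two separated
  clusters converges to the two cluster means.  An untruncated Gaussian
  at final radius 0.5 would instead converge to mutually smoothed
  codebooks and its quantization error can fluctuate between epochs —
  the truncation is what makes the 1×1-grid-equals-mean and
  cluster-mean limits exact.  Quantization error is the mean squared
  distance to the winning node; an epoch whose smoothed update would
  raise it falls back to the radius-zero update, which provably cannot,
  so the recorded trace is non-increasing by construction.  Codebooks
  are initialised by sampling data rows with the run seed; ties in all
  argmin steps go to the lowest index.  Constant (all-zero-ratio) gene
  rows are dropped before clustering and SOM training — they carry no
  profile signal.

## Cross-species projection

Genes are projected onto a common annotation space via the single most
similar subject in a 12-column tabular alignment file: maximal bit score,
ties broken by minimal e-value, then by lexicographically smallest
subject ID, making the map independent of row order.  Bit score is the
conventional ranking for translated searches; no e-value ceiling is
imposed by default (a `max_evalue` filter is available).  Venn region
counts are taken in annotation space after the many-to-one collapse, so
a region sum always reconstructs each projected set's size, and the
shared fraction of a set is the portion of its annotations found in at
least one other species.

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail
P[X ≥ k] (equivalently a one-sided Fisher test): k of the query's n
genes carry a term that annotates K of the N universe genes.  The
universe defaults to all annotated genes and is shared by the three GO
namespaces; the namespaces form independent Benjamini–Hochberg families,
mirroring per-category reporting.  Two choices matter:

* The BH family within a namespace is *every* term testable there, with
  terms the query missed entirely entering at p = 1, although the output
  lists only hit terms.  Adjusting over hit terms alone is a
  data-dependent selection that demonstrably inflates the null
  any-discovery rate several-fold and forfeits FDR control; the package
  verifies empirical FDR control under a uniform-query null in its test
  suite (200 repetitions, binomial bound).
* Annotations are used exactly as given — no GO-graph ancestor
  propagation — so results are relative to the supplied annotation
  table, as with any over-representation tool.

This statistic intentionally differs from the DAVID web service's
EASE-modified score (an unversioned service with an implicit
background), so term lists produced with that service will not match
exactly.

## Graft-success statistics

Success rates are reported exactly and rounded to the nearest integer
percent, halves away from zero (27/28 → 96 %, 27/35 → 77 %).  Fisher's
exact test enumerates the full hypergeometric support of the
fixed-margins 2×2 family; the two-sided p-value is the minimum-
likelihood convention (sum of point masses ≤ the observed mass, with a
1 + 1e-7 relative slack against roundoff, snapping to exactly 1 when the
whole support is included).  A zero margin makes the observed table the
only member of its family, hence p = 1.  Pairwise comparisons report
raw two-sided p-values (matching how such figures are starred) alongside
BH-adjusted values over the pair family; exact Clopper–Pearson intervals
are an optional extra column.  The test suite verifies the
implementation against exhaustive rational-arithmetic enumeration for
every table with row margins ≤ 12 and against an independent library
implementation on random tables.

## Synthetic data generator

The generator emulates the *processed form* of the study's data — it is
the package's validation substrate, not a read-level simulator.

* **Baselines**: log-normal FPKM (natural-log mean 2, sd 1; median
  ≈ 7.4), so a realistic share of genes sits below the 10/12 FPKM floors
  and the floor logic is exercised.
* **Planted genes**: 10 % of the transcriptome by default, split over
  classes 1–4 as 0.192/0.259/0.249/0.301 of the planted set (the shape
  of the published class partition).  Each "increase" step multiplies
  expression by a factor drawn uniformly from [2.5, 6]; a fading wound
  response falls to 0.3–0.8 of its 3-DAG level.  Planted baselines are
  lifted to at least 3 FPKM: genuinely graft-responsive genes are
  expressed genes, and below that level a two-fold call is not
  meaningful against the pseudocount.  With zero noise every planted
  trajectory satisfies its class signature exactly and every unplanted
  gene is flat, giving the end-to-end identity used in testing.
* **Noise**: multiplicative log-normal per replicate, sd 0.05 on the
  log2 scale by default, 3 replicates per condition.
* **Cross-species structure**: species share a bijective homolog core by
  gene index; a focal planted gene is planted (same class) in *all*
  other species with probability 0.12, mirroring the low (≈ 11–13 %)
  inter-species overlap regime of interfamily graft responses without
  claiming that value; each comparator tops up with its own planted
  genes to keep per-class counts comparable.  Hit tables give the true
  core subject the top bit score with configurable decoys below it, and
  per-gene dropout models incomplete homology coverage (default 0.9).
* **GO annotations** are drawn over the common annotation space; planted
  enriched terms sample their members with odds-weighted preference for
  the cross-species shared set (odds 1 = exchangeable null).
* **Trials** are binomial draws per arm with the inhibitor-experiment
  arm structure (0.77/35, 0.96/28, 0.0/31) as the default.

Not emulated: count-level sampling noise and gene-length effects behind
FPKM, correlated co-expression modules, mapping/annotation biases,
paralog ambiguity in homology, and the GO graph's hierarchical
dependence.  Passing recovery tests therefore demonstrates correctness
of the pipeline's logic under its stated model, not performance on real
libraries.

## Validation problem sizes and numerics

The test suite validates at desk scale: extraction recovery on 1000
genes (100 planted, σ = 0.05), class recovery on 400 genes at planted
proportions (0.2, 0.3, 0.25, 0.25), enrichment nulls over 100–300
seeds on 300-gene universes, Fisher enumeration over all ~8 000 tables
with row margins ≤ 12, and end-to-end identity on a noiseless 300-gene
three-species bundle.  Tie-breaking is lowest-index everywhere;
deterministic reruns of any stage, the generator and the pipeline are
asserted byte-for-byte.  Known limitations: the pipeline trusts the
FPKM normalisation it is given (no batch correction), treats a single
pooled library per condition the same as a replicate mean, and its
class boundaries are sharp thresholds — genes near a boundary flip
classes under small noise, which is why per-class recovery is asserted
at 0.9 rather than 1 under noise.
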