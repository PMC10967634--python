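# Methods

## Model and assumptions

The screen treats a disease as a transcriptomic phenotype: a set of genes
with a reproducible direction of dysregulation between a disease and a
control group. Candidate compounds are ranked by how many of those genes
their own perturbation transcriptome pushes in the *opposite* direction.
The pipeline makes three modelling commitments:

1. **Differential expression** is assessed gene-by-gene with Welch's
   unequal-variance *t*-test on log2 expression values, with
   Benjamini–Hochberg control of the FDR across all genes. This is
   deliberately assumption-light: the downstream screen consumes only
   directions and a gene ranking, not effect-size estimates, so a count
   model (negative binomial) would add machinery without changing what the
   screen sees. No fold-change cutoff is applied on top of the adjusted-p
   threshold.
2. **Enrichment** uses the weighted Kolmogorov–Smirnov running statistic on
   a preranked list. The ranking metric defaults to
   sign(log2FC)·−log10(max(p, 1e−300)); `log2fc` and `t_stat` are config
   alternatives, since different upstream pipelines rank differently. The
   p-floor only matters for p-values below ~1e−300 and exists to keep the
   metric finite.
3. **Scoring** is the integer ±1 matching rule. It generalises the
   original down-regulation-only formulation symmetrically: a disease-down
   gene that an ingredient up-regulates also counts +1 (reversal), and −1
   if pushed further down (aggravation). When every signature gene is
   disease-up the two formulations coincide.

## Enrichment details

For a set with hits H on a ranked list of N genes and weight w:

* P_hit(i) = Σ_{j ∈ H, j ≤ i} |m_j|^w / Σ_{j ∈ H} |m_j|^w, P_miss(i) =
  #{misses ≤ i}/(N − |H|); the ES is the profile value of maximum absolute
  deviation, with ties resolved to the **earliest** rank so the statistic
  is deterministic. With w = 0 each hit contributes 1/|H| and |ES| equals
  the classical two-sample KS deviation (verified against
  `scipy.stats.ks_2samp`).
* If every hit has zero metric (total hit weight 0), the profile falls
  back to the unweighted form rather than dividing by zero.
* The default null redraws random member sets of the same size
  (`gene_set` mode); with few samples per group a phenotype-label null is
  too coarse to be the default, but `phenotype` mode is provided and
  recomputes the full ranking per shuffle. An `exhaustive` flag enumerates
  all C(N, |H|) memberships and reports the exact same-sign null
  proportion (used for small-universe validation); sampled nulls use the
  (1 + extreme)/(1 + same-sign) pseudocount convention so p ∈ (0, 1].
* NES = ES / mean |same-sign null ES|; if ES = 0 or no same-sign
  permutations exist, NES = 0 and p = 1. A profile that is identically
  zero cannot arise for a non-empty proper subset, but the convention is
  implemented and unit-tested for robustness. Across multiple sets the
  permutation p-values are BH-adjusted — simpler than the NES-binned FDR
  of the original GSEA implementation, and a documented divergence from
  it.
* The leading edge is the set members at ranks ≤ the profile argmax
  (positive ES) or ≥ the argmin (negative ES), preserving ranked order; it
  is always a contiguous prefix/suffix of the set's hits.

## Screening details

* Gene symbols are matched case-insensitively (upper-cased), so
  mouse-style `Ripk1` matches human-style `RIPK1`; no orthology mapping is
  attempted.
* Ingredient perturbations carry a significance value in (0, 1]; it is
  **not** thresholded by default (`--ing-alpha` enables a cutoff), because
  the appropriate ingredient-side threshold depends on the database's own
  statistics.
* Ranking ties break by descending number of matched genes, then ascending
  ingredient identifier, giving a strict total order; determinism of the
  ranking matters more than the particular tie-break, which is a
  convention.
* The network keeps one node per gene even when several top ingredients
  share it; each edge records the direction the ingredient pushes that
  gene.

## Synthetic data: what it emulates, what it does not

`synthgen` produces the three inputs with known ground truth.

* **Expression**: per-gene baselines ~ N(8, 2²) on the log2 scale, i.i.d.
  Gaussian sample noise (sd 0.5), and planted genes shifted ±2 log2 units
  in the disease group. Defaults: 2000 genes, 4 samples per group, 5%
  planted DEGs with a 60/40 up/down split — a desk-scale caricature of a
  small two-arm RNA-seq contrast with the up-skew such contrasts typically
  show. It does **not** model counts, mean–variance coupling, library
  size, batch, or correlated genes; a pass here shows the pipeline's logic
  and calibration are right, not that the Welch test is optimal for any
  particular real protocol.
* **Gene sets**: 42 planted-up "signal" genes partitioned across three
  30-gene sets, padded with null genes — the size mirrors a realistic
  leading-edge union from two or three enriched pathways. An option plants
  the four named cell-death/interferon markers (Ripk1, Ripk3, Jak1,
  Ifitm1) among the signal genes so symbol-level behaviour is exercised
  with familiar names.
* **Ingredients**: 283 signatures of 200 genes drawn uniformly from the
  background with coin-flip directions; overlap with the signature is then
  hypergeometric, which makes the null score distribution symmetric about
  zero and provides the calibration baseline. One planted reverser covers
  round(reversal_fraction · |signature|) signature genes with the opposite
  direction (each flipped back with probability `direction_noise`), padded
  only with non-signature genes so its planted score is exactly the
  rounded product at zero noise. Real perturbation databases have
  correlated, pathway-structured signatures and heterogeneous sizes; none
  of that is modelled.

All generators are driven by `numpy.random.default_rng` with explicit
seeds; the pipeline and bundle generator spawn per-stage child seeds from
one root seed via `SeedSequence`, so a single integer makes a whole run
byte-reproducible.

## Numerical choices and degenerate inputs

* Genes with zero variance in **both** groups get stat 0, p 1, direction
  `ns`, and a logged warning — degenerate synthetic genes must not abort a
  run. Zero variance with unequal means yields an infinite t and p = 0,
  which is the correct limit.
* A significant gene with exactly zero fold change is called `ns` (no
  direction exists).
* BH adjustment delegates to `statsmodels` and is validated exactly
  against a brute-force step-up oracle.
* Gene-ranking ties break by descending log2FC then ascending symbol;
  ES-profile ties break to the earliest rank — every ordering in the
  pipeline is total.

## Problem sizes

Defaults were chosen as the smallest sizes at which every statistical
property of interest is comfortably testable: 2000-gene matrices, 1000
permutations per set (config-exposed; validation suites use 50–200),
20 null replicates for FDR calibration, 50 replicate databases for
reverser recovery, and 1000 null ingredients for score symmetry.

## Known limitations

* GSEA's desktop NES/FDR numerics are intentionally not reproduced
  (different FDR construction); ssGSEA and plotting beyond the running
  profile export are out of scope.
* The screen's output is a rank list, not an effect estimate; scores from
  signatures of different sizes are not comparable without the null
  calibration.
* Cross-species matching by upper-cased symbol will silently miss genes
  whose orthologs are not symbol-homonyms.
* Phenotype permutation with very small groups (the default 4 vs 4 has
  only 70 label splits) yields a coarse, conservative null; gene-set
  permutation is the default for exactly that reason.
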