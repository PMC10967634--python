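# transcriptoscreen

Transcriptotype-driven drug screening: rank candidate compounds by how well
their perturbation transcriptomes *reverse* a disease-associated expression
signature.

## The problem

Diseases without a well-defined molecular target — cholestatic liver
fibrosis is the motivating example — are hard to screen for with
single-target assays. An alternative is to characterise the disease as a
transcriptomic phenotype and search compound-perturbation databases (HERB,
ITCM, LINCS-style resources) for ingredients that push that phenotype back
toward normal. This package implements that screen as a tested, fully
reproducible pipeline, with a seeded synthetic-data module standing in for
the proprietary inputs so every stage can be verified offline.

## The method

1. **Differential expression.** Per-gene Welch *t*-tests on a two-group
   log2 expression matrix (disease vs control), Benjamini–Hochberg FDR
   across all genes, DEGs called at adjusted *p* < α (default 0.05).
2. **Ranking and enrichment.** Genes are ordered by a signed metric
   (default sign(log2FC) · −log10 *p*) and each gene set *S* is scored with
   the weighted Kolmogorov–Smirnov running statistic

   ES(S) = max-deviation over ranks *i* of  P_hit(i) − P_miss(i),

   where P_hit accumulates |metric|^w over members of *S* and P_miss the
   fraction of non-members. A permutation null (random member sets by
   default, or phenotype label shuffling) gives a permutation *p* and a
   normalised score NES = ES / mean |same-sign null ES|.
3. **Disease signature.** The *leading edge* of each enriched set — the
   members at or before (positive ES) / at or after (negative ES) the
   profile extremum — is extracted; their deduplicated union, each gene
   tagged with its disease direction, is the disease signature.
4. **Matching score.** Each database ingredient gets an integer score:
   **+1** for every signature gene it regulates *opposite* to the disease
   direction (reversal), **−1** for every gene it pushes the *same* way
   (aggravation); unmeasured genes contribute 0. Ingredients are ranked by
   score, and the top-*k* (default 5) are exported as a bipartite
   ingredient–target network (SIF + GraphML, Cytoscape-ready).

The synthetic-data module generates all inputs with known ground truth: a
matrix with planted up/down genes, gene sets carrying the planted signal,
and an ingredient database of direction-random signatures plus one planted
"reverser" — so the screen's ability to recover the right compound is a
testable property, not an anecdote.

## Worked example

```sh
transcriptoscreen simulate --outdir bundle --seed 7
# wrote bundle to bundle: 60 up, 40 down planted; reverser=ING0131

transcriptoscreen run --matrix bundle/matrix.tsv --groups bundle/groups.tsv \
    --gmt bundle/sets.gmt --db bundle/ingredients.tsv --outdir run --seed 7
# signature of 43 genes; top ingredient ING0131 (score +42)
```

The bundle plants 100 differential genes (60 up, 40 down) in a 2000-gene,
4-vs-4 matrix, spreads 42 of the up genes across three gene sets, and hides
one full reverser among 283 ingredients. The run recovers a 43-gene
signature from the GSEA leading edges (the 42 planted genes plus one
borderline null gene) and ranks the planted reverser first:

```
$ head -4 run/screen.tsv
rank    ingredient_id   score   n_matched
1       ING0131 42      42
2       ING0044 6       6
3       ING0202 6       6
```

A score of +42 means ING0131 down-regulates all 42 disease-up signature
genes it measures; the best direction-random ingredient only reaches +6 by
chance. `run/manifest.json` records every count (13 up / 13 down DEG calls
at q < 0.05 under these small group sizes, 3/3 gene sets enriched, 65
network edges), and `run/network.sif` holds the top-5 network.

Every stage is also scriptable from Python — see
`transcriptoscreen.differential_expression`, `enrichment_score`,
`leading_edge`, `match_score`, `rank_ingredients`, `build_network`.

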