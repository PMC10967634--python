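"""Weighted Kolmogorov-Smirnov gene-set enrichment on a preranked list.

Implements the running enrichment score (ES), a permutation null with
normalised score (NES), and leading-edge subset extraction. The ES of a set
S on a ranked list of N genes is the signed maximum deviation of

    P_hit(i) - P_miss(i),

where P_hit accumulates |metric|^weight over set members ("hits") up to rank
i, normalised by the total hit weight, and P_miss is the fraction of
non-members seen so far. With weight = 0 every hit contributes 1/n_hits and
the statistic reduces to the classical two-sample KS deviation between hit
and miss rank distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix, rank_genes, welch_arrays

__all__ = [
    "GeneSet",
    "GseaResult",
    "enrichment_score",
    "permutation_test",
    "leading_edge",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set '{self.name}' is empty")


@dataclass
class GseaResult:
    """Enrichment of one gene set on one ranked list.

    ``es`` is the signed maximum-magnitude value of ``running_profile``
    (ties resolved to the earliest rank). ``peak_index`` is that rank
    position (0-based). ``nes``/``p_perm`` are filled by
    :func:`permutation_test`; ``leading_edge`` by :func:`leading_edge`.
    """

    set_name: str
    es: float
    running_profile: np.ndarray = field(repr=False)
    peak_index: int
    nes: float | None = None
    p_perm: float | None = None
    n_perm: int = 0
    leading_edge: list[str] = field(default_factory=list)


def _hit_mask(ranked: pd.Series, members: frozenset[str]) -> np.ndarray:
    genes = ranked.index.to_numpy(dtype=object)
    mask = np.isin(genes, list(members))
    n = mask.sum()
    if n == 0:
        raise ValueError("empty set on this universe")
    if n == len(genes):
        raise ValueError("gene set covers the entire ranked universe")
    return mask


def _running_profile(weights: np.ndarray, hit: np.ndarray) -> np.ndarray:
    """P_hit - P_miss per rank, given per-gene hit weights (zero on misses)."""
    n = hit.size
    n_hits = int(hit.sum())
    denom = weights[hit].sum()
    if denom > 0:
        p_hit = np.cumsum(np.where(hit, weights, 0.0)) / denom
    else:
        # all hit weights zero (e.g. every hit metric is exactly 0):
        # fall back to unweighted hits so the profile stays defined
        p_hit = np.cumsum(hit) / n_hits
    p_miss = np.cumsum(~hit) / (n - n_hits)
    return p_hit - p_miss


def _es_of_profile(profile: np.ndarray) -> tuple[float, int]:
    peak = int(np.argmax(np.abs(profile)))  # earliest on ties
    return float(profile[peak]), peak


def _es_for_mask(weights: np.ndarray, hit: np.ndarray) -> float:
    es, _ = _es_of_profile(_running_profile(weights, hit))
    return es


def _weights(metric: np.ndarray, weight: float) -> np.ndarray:
    if weight < 0:
        raise ValueError("weight must be non-negative")
    if weight == 0:
        return np.ones_like(metric, dtype=float)
    return np.abs(metric.astype(float)) ** weight


def enrichment_score(ranked: pd.Series, gene_set: GeneSet, weight: float = 1.0) -> GseaResult:
    """ES and running profile of ``gene_set`` on the ranked list."""
    hit = _hit_mask(ranked, gene_set.members)
    profile = _running_profile(_weights(ranked.to_numpy(dtype=float), weight), hit)
    es, peak = _es_of_profile(profile)
    return GseaResult(set_name=gene_set.name, es=es, running_profile=profile, peak_index=peak)


def _normalize(es: float, perm_es: np.ndarray, exhaustive: bool) -> tuple[float, float, int]:
    """NES and permutation p from null ES values.

    p is one-sided on the observed sign with magnitude at least |es|. With a
    sampled null a +1 pseudocount keeps p in (0, 1]; under exhaustive
    enumeration p is the exact proportion among same-sign null values. NES
    divides es by the mean |ES| of same-sign permutations.
    """
    n_perm = int(perm_es.size)
    if es == 0:
        return 0.0, 1.0, n_perm
    same = perm_es * np.sign(es) > 0
    extreme = int((same & (np.abs(perm_es) >= abs(es))).sum())
    if exhaustive:
        p = extreme / max(int(same.sum()), 1)
    else:
        p = (1 + extreme) / (1 + int(same.sum()))
    mean_same = np.abs(perm_es[same]).mean() if same.any() else 0.0
    nes = es / mean_same if mean_same > 0 else 0.0
    return float(nes), float(p), n_perm


def permutation_test(
    ranked: pd.Series,
    gene_set: GeneSet,
    weight: float = 1.0,
    n_perm: int = 1000,
    mode: str = "gene_set",
    mat: ExpressionMatrix | None = None,
    seed: int | None = None,
    exhaustive: bool = False,
    metric: str = "signed_logp",
) -> GseaResult:
    """ES with a permutation null, normalised score and permutation p.

    ``gene_set`` mode (default) redraws random member sets of the observed
    hit count from the ranked universe; with ``exhaustive=True`` it
    enumerates every possible membership instead (small universes only) and
    reports the exact null proportion. ``phenotype`` mode shuffles the
    sample group labels of ``mat``, recomputes the Welch ranking with the
    given metric, and re-scores the set.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("gene_set", "phenotype"):
        raise ValueError("mode must be 'gene_set' or 'phenotype'")
    result = enrichment_score(ranked, gene_set, weight=weight)
    rng = np.random.default_rng(seed)
    metric_vals = ranked.to_numpy(dtype=float)
    w = _weights(metric_vals, weight)
    n = len(ranked)
    n_hits = int(_hit_mask(ranked, gene_set.members).sum())

    if mode == "gene_set":
        if exhaustive:
            perm_es = np.array(
                [
                    _es_for_mask(w, _indices_to_mask(idx, n))
                    for idx in combinations(range(n), n_hits)
                ]
            )
        else:
            perm_es = np.empty(n_perm)
            for i in range(n_perm):
                mask = _indices_to_mask(rng.choice(n, size=n_hits, replace=False), n)
                perm_es[i] = _es_for_mask(w, mask)
    else:
        if mat is None:
            raise ValueError("phenotype mode requires the expression matrix")
        perm_es = _phenotype_null(mat, gene_set, weight, n_perm, rng, metric)

    result.nes, result.p_perm, result.n_perm = _normalize(result.es, perm_es, exhaustive)
    return result


def _indices_to_mask(indices, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    mask[list(indices)] = True
    return mask


def _phenotype_null(
    mat: ExpressionMatrix,
    gene_set: GeneSet,
    weight: float,
    n_perm: int,
    rng: np.random.Generator,
    metric: str,
) -> np.ndarray:
    values = mat.values.to_numpy(dtype=float)
    labels = (mat.groups == "disease").to_numpy()
    n_d = int(labels.sum())
    if n_d < 2 or labels.size - n_d < 2:
        raise ValueError("phenotype permutation needs >= 2 samples per group")
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(labels.size)
        d_cols, c_cols = perm[:n_d], perm[n_d:]
        stat, p = welch_arrays(values[:, d_cols], values[:, c_cols])
        log2fc = values[:, d_cols].mean(axis=1) - values[:, c_cols].mean(axis=1)
        deg = pd.DataFrame({"log2fc": log2fc, "stat": stat, "p": p}, index=mat.genes)
        ranked = rank_genes(deg, metric=metric)
        hit = _hit_mask(ranked, gene_set.members)
        perm_es[i] = _es_for_mask(_weights(ranked.to_numpy(dtype=float), weight), hit)
    return perm_es


def leading_edge(result: GseaResult, ranked: pd.Series, gene_set: GeneSet) -> list[str]:
    """Set members driving the enrichment, in ranked-list order.

    Positive ES: members at ranks up to and including the profile maximum.
    Negative ES: members at ranks from the profile minimum onward. Zero ES
    yields an empty list.
    """
    if result.es == 0:
        return []
    hit = _hit_mask(ranked, gene_set.members)
    genes = ranked.index.to_numpy(dtype=object)
    profile = result.running_profile
    if result.es > 0:
        peak = int(np.argmax(profile))
        sel = hit & (np.arange(len(genes)) <= peak)
    else:
        peak = int(np.argmin(profile))
        sel = hit & (np.arange(len(genes)) >= peak)
    return [str(g) for g in genes[sel]]
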