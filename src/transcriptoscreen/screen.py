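"""Signature-reversal scoring of ingredient perturbation signatures.

The disease signature is the deduplicated union of GSEA leading-edge genes,
each carrying its disease direction (up/down from the differential
expression table). An ingredient's matching score sums +1 for every
signature gene whose perturbation direction opposes the disease direction
(reversal) and -1 for every gene it pushes the same way (aggravation);
genes the ingredient does not perturb contribute nothing. Ingredients are
ranked by score and the top-k feed a bipartite ingredient-target network.

Gene matching is case-insensitive (symbols are compared upper-cased), so
mouse-style symbols (Ripk1) match human-style ones (RIPK1) without an
orthology map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "DiseaseSignature",
    "IngredientSignature",
    "ScreenRecord",
    "build_disease_signature",
    "match_score",
    "rank_ingredients",
    "build_network",
]

UP = "up"
DOWN = "down"


@dataclass
class DiseaseSignature:
    """Deduplicated signature genes with disease direction and provenance.

    ``entries`` maps gene symbol to ``"up"`` or ``"down"``; ``provenance``
    maps gene symbol to the names of the gene sets whose leading edges
    contributed it.
    """

    entries: dict[str, str]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.entries.items() if d not in (UP, DOWN)}
        if bad:
            raise ValueError(f"invalid disease directions: {bad}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class IngredientSignature:
    """One ingredient's perturbation: gene -> (direction, significance)."""

    ingredient_id: str
    ingredient_name: str
    perturbations: dict[str, tuple[str, float]]

    def __post_init__(self) -> None:
        for gene, (direction, sig) in self.perturbations.items():
            if direction not in (UP, DOWN):
                raise ValueError(f"{self.ingredient_id}/{gene}: bad direction {direction!r}")
            if not 0 < sig <= 1:
                raise ValueError(f"{self.ingredient_id}/{gene}: significance must be in (0, 1]")


@dataclass
class ScreenRecord:
    ingredient_id: str
    score: int
    n_matched: int
    contributions: dict[str, int]  # signature gene -> +1 (reversal) | -1 (aggravation)
    rank: int | None = None


def build_disease_signature(results, deg: pd.DataFrame) -> DiseaseSignature:
    """Union of all leading-edge genes with directions from the DEG table.

    A gene's disease direction is up when its log2 fold change is positive,
    down otherwise; duplicates across leading edges collapse to one entry
    whose provenance lists every contributing set.
    """
    entries: dict[str, str] = {}
    provenance: dict[str, list[str]] = {}
    for res in results:
        for gene in res.leading_edge:
            if gene not in entries:
                entries[gene] = UP if deg.loc[gene, "log2fc"] > 0 else DOWN
                provenance[gene] = []
            if res.set_name not in provenance[gene]:
                provenance[gene].append(res.set_name)
    if not entries:
        raise ValueError("empty signature: no leading-edge genes")
    return DiseaseSignature(entries=entries, provenance=provenance)


def match_score(
    signature: DiseaseSignature,
    ing: IngredientSignature,
    ing_alpha: float | None = None,
) -> ScreenRecord:
    """The +/-1 matching score of one ingredient against the signature.

    ``ing_alpha``, if given, drops ingredient perturbations with
    significance above it before scoring. The returned record has ``rank``
    unset.
    """
    if len(signature) == 0:
        raise ValueError("signature is empty")
    perturb = {
        gene.upper(): direction
        for gene, (direction, sig) in ing.perturbations.items()
        if ing_alpha is None or sig <= ing_alpha
    }
    contributions: dict[str, int] = {}
    for gene, disease_dir in signature.entries.items():
        ing_dir = perturb.get(gene.upper())
        if ing_dir is None:
            continue
        contributions[gene] = 1 if ing_dir != disease_dir else -1
    score = sum(contributions.values())
    return ScreenRecord(
        ingredient_id=ing.ingredient_id,
        score=score,
        n_matched=len(contributions),
        contributions=contributions,
    )


def rank_ingredients(
    db: list[IngredientSignature],
    signature: DiseaseSignature,
    ing_alpha: float | None = None,
) -> list[ScreenRecord]:
    """Score every ingredient and rank by descending matching score.

    Ties break by descending n_matched then ascending ingredient_id, so
    ranks are a strict 1-based total order.
    """
    if not db:
        raise ValueError("ingredient database is empty")
    records = [match_score(signature, ing, ing_alpha=ing_alpha) for ing in db]
    records.sort(key=lambda r: (-r.score, -r.n_matched, r.ingredient_id))
    for i, rec in enumerate(records, start=1):
        rec.rank = i
    return records


def build_network(
    records: list[ScreenRecord],
    signature: DiseaseSignature,
    k: int = 5,
) -> nx.Graph:
    """Bipartite ingredient-target network of the top-k ranked ingredients.

    Nodes are the k best-ranked ingredients plus every signature gene they
    matched; each edge carries ``regulation`` — the direction the
    ingredient pushes that gene (opposite the disease direction for a +1
    contribution). The paper's convention of k = 5 is the default.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(records):
        raise ValueError(f"k = {k} exceeds the {len(records)} ranked ingredients")
    top = sorted(records, key=lambda r: r.rank)[:k]
    net = nx.Graph()
    for rec in top:
        net.add_node(rec.ingredient_id, kind="ingredient", score=rec.score, rank=rec.rank)
        for gene, contrib in rec.contributions.items():
            disease_dir = signature.entries[gene]
            if contrib == 1:  # reversal: ingredient pushes opposite the disease
                regulation = DOWN if disease_dir == UP else UP
            else:
                regulation = disease_dir
            net.add_node(gene, kind="gene", disease_direction=disease_dir)
            net.add_edge(rec.ingredient_id, gene, regulation=regulation)
    return net
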