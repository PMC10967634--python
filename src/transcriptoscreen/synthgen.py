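"""Seeded synthetic inputs with the statistical structure the screen assumes.

Three generators cover the pipeline's inputs end to end:

* a two-group log2 expression matrix with planted up/down-regulated genes
  at a stated effect size over Gaussian noise,
* gene-set collections that overlap the planted genes (so enrichment and
  leading edges are recoverable),
* an ingredient perturbation database of direction-random signatures plus
  one planted "reverser" that pushes a stated fraction of the disease
  signature in the opposite direction.

Every generator is driven by an explicit seed and is bit-reproducible.
Expression is simulated directly on the log2 scale (not as counts): the
downstream Welch test operates on log2 values, so a Gaussian model is the
matching desk-scale choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import CONTROL, DISEASE, ExpressionMatrix
from .gsea import GeneSet
from .screen import DOWN, UP, DiseaseSignature, IngredientSignature

__all__ = [
    "SimExpressionConfig",
    "SimIngredientConfig",
    "SimGeneSetConfig",
    "SimTruth",
    "MARKER_GENES",
    "simulate_expression",
    "simulate_gene_sets",
    "simulate_ingredient_db",
]

#: disease-up marker genes named in cholestatic-fibrosis work (PANoptosis /
#: type-I IFN members); injected into the planted up set on request so
#: symbol-level behaviour can be exercised with familiar names.
MARKER_GENES = ("Ripk1", "Ripk3", "Jak1", "Ifitm1")


@dataclass
class SimExpressionConfig:
    """Conditions for the two-group expression simulation.

    ``effect_size`` is the planted |log2 fold change|; ``noise_sd`` the
    per-sample Gaussian sd of log2 expression; ``up_down_balance`` the
    fraction of planted genes shifted up in disease.
    """

    n_genes: int = 2000
    n_per_group: int = 4
    de_fraction: float = 0.05
    effect_size: float = 2.0
    noise_sd: float = 0.5
    up_down_balance: float = 0.6
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    include_marker_genes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (variance undefined below)")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if not 0 <= self.up_down_balance <= 1:
            raise ValueError("up_down_balance must lie in [0, 1]")
        if self.effect_size <= 0 or self.noise_sd <= 0:
            raise ValueError("effect_size and noise_sd must be positive")


@dataclass
class SimGeneSetConfig:
    """Gene-set collection overlapping the planted disease-up genes.

    ``n_signal_genes`` planted-up genes are split across ``n_sets`` sets
    (every signal gene lands in exactly one set); the remainder of each set
    is filled with random background genes.
    """

    n_sets: int = 3
    set_size: int = 30
    n_signal_genes: int = 42
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sets < 1 or self.set_size < 1:
            raise ValueError("n_sets and set_size must be positive")
        if self.n_signal_genes < 0:
            raise ValueError("n_signal_genes must be non-negative")


@dataclass
class SimIngredientConfig:
    """Conditions for the ingredient perturbation database.

    One reverser is planted whenever ``reversal_fraction > 0``; it carries
    ``round(reversal_fraction * |signature|)`` signature genes assigned the
    direction opposite to disease, each independently flipped back with
    probability ``direction_noise``. All other ingredients draw genes
    uniformly from the background with random directions, so their overlap
    with the signature is hypergeometric — the natural score null.
    """

    n_ingredients: int = 283
    genes_per_signature: int = 200
    background_genes: tuple[str, ...] = ()
    reversal_fraction: float = 1.0
    direction_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ingredients < 1:
            raise ValueError("n_ingredients must be positive")
        if self.genes_per_signature < 1:
            raise ValueError("genes_per_signature must be positive")
        if not 0 <= self.reversal_fraction <= 1:
            raise ValueError("reversal_fraction must lie in [0, 1]")
        if not 0 <= self.direction_noise <= 1:
            raise ValueError("direction_noise must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of a simulation: planted genes and the planted reverser."""

    de_genes_up: set[str] = field(default_factory=set)
    de_genes_down: set[str] = field(default_factory=set)
    reverser_id: str | None = None
    reversal_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.de_genes_up & self.de_genes_down:
            raise ValueError("a gene cannot be planted both up and down")


def _gene_symbols(n: int) -> list[str]:
    return [f"G{i + 1:06d}" for i in range(n)]


def simulate_expression(cfg: SimExpressionConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Two-group log2 expression matrix with planted differential genes.

    Each gene gets a baseline drawn once from N(baseline_mean,
    baseline_sd^2); every sample adds N(0, noise_sd^2) noise. The first
    ``round(n_genes * de_fraction)`` genes are shifted by +/-effect_size in
    the disease group (up/down split by ``up_down_balance``); planting them
    at fixed positions keeps the truth transparent while the Welch test is
    position-blind.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_symbols(cfg.n_genes)
    n_de = round(cfg.n_genes * cfg.de_fraction)
    n_up = round(n_de * cfg.up_down_balance)
    if cfg.include_marker_genes:
        for i, name in enumerate(MARKER_GENES[: min(n_up, len(MARKER_GENES))]):
            genes[i] = name
    up = set(genes[:n_up])
    down = set(genes[n_up:n_de])

    n_samples = 2 * cfg.n_per_group
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    values = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_samples))
    shift = np.zeros(cfg.n_genes)
    shift[:n_up] = cfg.effect_size
    shift[n_up:n_de] = -cfg.effect_size
    values[:, : cfg.n_per_group] += shift[:, None]

    samples = [f"disease_{i + 1}" for i in range(cfg.n_per_group)] + [
        f"control_{i + 1}" for i in range(cfg.n_per_group)
    ]
    groups = pd.Series(
        [DISEASE] * cfg.n_per_group + [CONTROL] * cfg.n_per_group,
        index=pd.Index(samples, name="sample"),
        name="group",
    )
    mat = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        groups=groups,
    )
    return mat, SimTruth(de_genes_up=up, de_genes_down=down)


def simulate_gene_sets(
    cfg: SimGeneSetConfig, truth: SimTruth, background: list[str]
) -> list[GeneSet]:
    """Gene sets whose signal members are planted disease-up genes.

    Signal genes are drawn (deterministically per seed) from
    ``truth.de_genes_up``, partitioned across the sets; background filler
    comes from genes outside the planted sets, so each collection is
    enriched for the planted up-regulation and nothing else.
    """
    rng = np.random.default_rng(cfg.seed)
    up_pool = sorted(truth.de_genes_up)
    n_signal = min(cfg.n_signal_genes, len(up_pool))
    signal = list(rng.choice(up_pool, size=n_signal, replace=False)) if n_signal else []
    null_pool = sorted(set(background) - truth.de_genes_up - truth.de_genes_down)
    chunks = np.array_split(np.asarray(signal, dtype=object), cfg.n_sets)
    sets = []
    for i, chunk in enumerate(chunks):
        members = list(chunk)
        n_fill = max(cfg.set_size - len(members), 0)
        if n_fill > len(null_pool):
            raise ValueError("background too small to fill gene sets")
        members += list(rng.choice(null_pool, size=n_fill, replace=False))
        sets.append(
            GeneSet(
                name=f"SET_{i + 1:02d}",
                description=f"synthetic set with {len(chunk)} planted signal genes",
                members=frozenset(members),
            )
        )
    return sets


def simulate_ingredient_db(
    cfg: SimIngredientConfig, signature: DiseaseSignature | None = None
) -> tuple[list[IngredientSignature], SimTruth]:
    """Ingredient database of random signatures plus one planted reverser.

    The reverser (required: a non-empty ``signature`` when
    ``reversal_fraction > 0``) covers ``round(reversal_fraction *
    |signature|)`` signature genes with the direction opposite to disease
    (individually flipped with probability ``direction_noise``), padded to
    ``genes_per_signature`` with random background genes. Every perturbed
    gene carries a significance drawn uniformly from (0, 1).
    """
    background = list(cfg.background_genes)
    if cfg.genes_per_signature > len(background):
        raise ValueError("genes_per_signature exceeds the background gene universe")
    plant = cfg.reversal_fraction > 0
    if plant and (signature is None or len(signature) == 0):
        raise ValueError("a non-empty signature is required to plant a reverser")

    rng = np.random.default_rng(cfg.seed)
    reverser_idx = int(rng.integers(cfg.n_ingredients)) if plant else -1
    db: list[IngredientSignature] = []
    truth = SimTruth(reversal_fraction=cfg.reversal_fraction if plant else 0.0)

    for i in range(cfg.n_ingredients):
        ing_id = f"ING{i + 1:04d}"
        perturbations: dict[str, tuple[str, float]] = {}
        if i == reverser_idx:
            sig_genes = sorted(signature.entries)
            n_rev = round(cfg.reversal_fraction * len(sig_genes))
            chosen = list(rng.choice(sig_genes, size=n_rev, replace=False))
            for gene in chosen:
                opposite = DOWN if signature.entries[gene] == UP else UP
                if cfg.direction_noise > 0 and rng.random() < cfg.direction_noise:
                    opposite = UP if opposite == DOWN else DOWN
                perturbations[gene] = (opposite, _significance(rng))
            # pad only with non-signature genes so the planted score is
            # exactly round(reversal_fraction * |signature|) at zero noise
            pad_pool = sorted(set(background) - set(sig_genes))
            n_pad = min(cfg.genes_per_signature - len(chosen), len(pad_pool))
            if n_pad > 0:
                for gene in rng.choice(pad_pool, size=n_pad, replace=False):
                    perturbations[str(gene)] = (_direction(rng), _significance(rng))
            truth.reverser_id = ing_id
        else:
            for gene in rng.choice(background, size=cfg.genes_per_signature, replace=False):
                perturbations[str(gene)] = (_direction(rng), _significance(rng))
        db.append(
            IngredientSignature(
                ingredient_id=ing_id,
                ingredient_name=f"ingredient {i + 1}",
                perturbations=perturbations,
            )
        )
    return db, truth


def _direction(rng: np.random.Generator) -> str:
    return UP if rng.random() < 0.5 else DOWN


def _significance(rng: np.random.Generator) -> float:
    # uniform on (0, 1): nudge 0 away so the open-interval contract holds
    return float(max(rng.random(), np.finfo(float).tiny))
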