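"""End-to-end orchestration: configuration, staging, manifest and logging.

The pipeline wires the modules together in the screening order:
differential expression -> gene ranking -> per-set enrichment with a
permutation null -> leading-edge extraction -> disease signature ->
ingredient scoring and ranking -> top-k ingredient-target network. Every
intermediate table is written to the run directory, and a JSON manifest
records the configuration, seed and headline counts. One root seed drives
every stochastic stage through spawned child seeds, so a single integer
fixes the whole run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from .diffexpr import bh_adjust, differential_expression, rank_genes
from .gsea import leading_edge, permutation_test
from .screen import (
    UP,
    DiseaseSignature,
    build_disease_signature,
    build_network,
    rank_ingredients,
)
from .synthgen import (
    SimExpressionConfig,
    SimGeneSetConfig,
    SimIngredientConfig,
    simulate_expression,
    simulate_gene_sets,
    simulate_ingredient_db,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Parameter surface of one screening run.

    Thresholds follow the source conventions: DEGs at BH-adjusted p <
    ``alpha`` (default 0.05), enriched sets kept at BH-adjusted permutation
    p < ``gsea_alpha``, and the network built from the ``top_k`` (default
    5) ranked ingredients.
    """

    matrix: str = ""
    groups: str = ""
    gmt: str = ""
    ingredient_db: str = ""
    outdir: str = "run"
    alpha: float = 0.05
    gsea_alpha: float = 0.25
    weight: float = 1.0
    n_perm: int = 1000
    permutation_mode: str = "gene_set"
    metric: str = "signed_logp"
    top_k: int = 5
    ing_alpha: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "gsea_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie strictly between 0 and 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _child_seeds(seed: int, n: int) -> list[int]:
    # independent, reproducible child streams below 2**31
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full screen; returns the manifest dict.

    Writes into ``cfg.outdir``: the DEG table, ranked list, per-set GSEA
    results and leading edges, disease signature, ranked screen table, the
    top-k network (SIF + GraphML) and ``manifest.json``. A failing stage
    raises :class:`StageError` naming the stage; files already written are
    kept for inspection.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _log_to(outdir / "run.log")
    logger.info("run_pipeline seed=%d outdir=%s", cfg.seed, outdir)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            raise StageError(f"stage '{name}' failed: {exc}") from exc

    mat = stage("load_inputs", io.read_expression, cfg.matrix, cfg.groups)
    gene_sets = stage("load_inputs", io.read_gmt, cfg.gmt)
    db = stage("load_inputs", io.read_ingredient_db, cfg.ingredient_db)

    deg = stage("differential_expression", differential_expression, mat, cfg.alpha)
    io.write_deg_table(deg, outdir / "deg.tsv")
    ranked = stage("rank_genes", rank_genes, deg, cfg.metric)
    io.write_rnk(ranked, outdir / "ranked.rnk")

    seeds = _child_seeds(cfg.seed, len(gene_sets))
    results = []
    for gs, gs_seed in zip(gene_sets, seeds):
        res = stage(
            f"gsea[{gs.name}]",
            permutation_test,
            ranked,
            gs,
            weight=cfg.weight,
            n_perm=cfg.n_perm,
            mode=cfg.permutation_mode,
            mat=mat,
            seed=gs_seed,
            metric=cfg.metric,
        )
        res.leading_edge = stage(f"leading_edge[{gs.name}]", leading_edge, res, ranked, gs)
        results.append(res)
    q = list(bh_adjust([r.p_perm for r in results]))
    io.write_gsea_results(results, q, outdir / "gsea_results.tsv")
    io.write_leading_edges(results, outdir / "leading_edges.gmt")

    selected = [r for r, qv in zip(results, q) if qv < cfg.gsea_alpha and r.leading_edge]
    logger.info("gene sets kept at q < %g: %d/%d", cfg.gsea_alpha, len(selected), len(results))
    signature = stage("build_disease_signature", build_disease_signature, selected, deg)
    io.write_signature(signature, outdir / "signature.tsv")

    records = stage("rank_ingredients", rank_ingredients, db, signature, cfg.ing_alpha)
    io.write_screen_records(records, outdir / "screen.tsv")

    k = min(cfg.top_k, len(records))
    net = stage("build_network", build_network, records, signature, k)
    io.write_sif(net, outdir / "network.sif")
    io.write_graphml(net, outdir / "network.graphml")

    n_dir = deg["direction"].value_counts()
    manifest = {
        "config": dataclasses.asdict(cfg),
        "version": __version__,
        "counts": {
            "n_genes": int(len(deg)),
            "n_deg_up": int(n_dir.get("up", 0)),
            "n_deg_down": int(n_dir.get("down", 0)),
            "n_deg_ns": int(n_dir.get("ns", 0)),
            "n_gene_sets": len(gene_sets),
            "n_sets_selected": len(selected),
            "signature_size": len(signature),
            "n_ingredients": len(db),
            "network_nodes": net.number_of_nodes(),
            "network_edges": net.number_of_edges(),
        },
        "top_ingredients": [
            {"rank": r.rank, "ingredient_id": r.ingredient_id, "score": r.score, "n_matched": r.n_matched}
            for r in records[:k]
        ],
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest


@dataclass
class SimulateConfig:
    """Bundle generator conditions: expression, gene sets, ingredients."""

    expression: SimExpressionConfig = field(default_factory=SimExpressionConfig)
    gene_sets: SimGeneSetConfig = field(default_factory=SimGeneSetConfig)
    ingredients: SimIngredientConfig = field(default_factory=SimIngredientConfig)

    @classmethod
    def from_yaml(cls, path) -> "SimulateConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {"expression", "gene_sets", "ingredients"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(
            expression=SimExpressionConfig(**raw.get("expression", {})),
            gene_sets=SimGeneSetConfig(**raw.get("gene_sets", {})),
            ingredients=SimIngredientConfig(**raw.get("ingredients", {})),
        )


def simulate_bundle(cfg: SimulateConfig, outdir, seed: int | None = None) -> dict:
    """Generate and write a complete synthetic input bundle.

    The planted disease signature handed to the ingredient generator is the
    set of planted-up genes placed into the gene sets — exactly the genes
    an ideal leading-edge analysis would recover — so the planted reverser
    is the ground-truth best ingredient. ``seed``, when given, overrides
    every section seed through spawned child seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        s_expr, s_sets, s_ing = _child_seeds(seed, 3)
        cfg = SimulateConfig(
            expression=dataclasses.replace(cfg.expression, seed=s_expr),
            gene_sets=dataclasses.replace(cfg.gene_sets, seed=s_sets),
            ingredients=dataclasses.replace(cfg.ingredients, seed=s_ing),
        )

    mat, truth = simulate_expression(cfg.expression)
    io.write_expression(mat, outdir / "matrix.tsv", outdir / "groups.tsv")

    sets = simulate_gene_sets(cfg.gene_sets, truth, list(mat.genes))
    io.write_gmt(sets, outdir / "sets.gmt")

    planted = sorted(set().union(*(s.members for s in sets)) & truth.de_genes_up)
    planted_sig = DiseaseSignature(
        entries={g: UP for g in planted},
        provenance={g: ["planted"] for g in planted},
    )
    ing_cfg = dataclasses.replace(cfg.ingredients, background_genes=tuple(mat.genes))
    db, ing_truth = simulate_ingredient_db(ing_cfg, planted_sig if planted else None)
    io.write_ingredient_db(db, outdir / "ingredients.tsv")

    truth_doc = {
        "de_genes_up": sorted(truth.de_genes_up),
        "de_genes_down": sorted(truth.de_genes_down),
        "planted_signature": planted,
        "reverser_id": ing_truth.reverser_id,
        "reversal_fraction": ing_truth.reversal_fraction,
    }
    io.write_json(truth_doc, outdir / "truth.json")
    return truth_doc


def _log_to(path) -> None:
    root = logging.getLogger("transcriptoscreen")
    root.setLevel(logging.INFO)
    if not any(
        isinstance(h, logging.FileHandler) and h.baseFilename == str(Path(path).resolve())
        for h in root.handlers
    ):
        handler = logging.FileHandler(path)
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root.addHandler(handler)
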