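"""Readers and writers for the pipeline's plain-text formats.

Formats: expression TSV (genes x samples) plus a sample-to-group TSV, GMT
gene-set collections, two-column .rnk ranked lists, DEG tables, disease
signature TSV, ingredient databases (TSV or JSON), screen result TSV, SIF
and GraphML networks, and JSON manifests. All writers emit deterministic
byte-stable text; all readers validate and report malformed content with
file and line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .gsea import GeneSet, GseaResult
from .screen import DiseaseSignature, IngredientSignature, ScreenRecord

#: float format shared by every table writer; 12 significant digits
#: round-trips doubles produced here while keeping files byte-stable
FLOAT_FMT = "%.12g"


class FormatError(ValueError):
    """Malformed input file; message carries the file and 1-based line."""

    def __init__(self, path, line: int | None, message: str):
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {message}")
        self.path = str(path)
        self.line = line


# ---------------------------------------------------------------- expression

def write_expression(mat: ExpressionMatrix, matrix_path, groups_path) -> None:
    df = mat.values.copy()
    df.index.name = "gene"
    df.to_csv(matrix_path, sep="\t", float_format=FLOAT_FMT)
    grp = mat.groups.rename("group")
    grp.index.name = "sample"
    grp.to_csv(groups_path, sep="\t")


def read_expression(matrix_path, groups_path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise FormatError(matrix_path, None, f"duplicate gene symbol {dup!r}")
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise FormatError(matrix_path, None, f"non-numeric expression value ({exc})") from exc
    groups = pd.read_csv(groups_path, sep="\t", index_col=0)
    if groups.shape[1] != 1:
        raise FormatError(groups_path, 1, "expected exactly two columns: sample, group")
    try:
        return ExpressionMatrix(values=values, groups=groups.iloc[:, 0])
    except ValueError as exc:
        raise FormatError(matrix_path, None, str(exc)) from exc


# ----------------------------------------------------------------------- GMT

def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def read_gmt(path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(path, lineno, "GMT line needs name, description and >=1 gene")
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in seen:
                raise FormatError(path, lineno, f"duplicate gene set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name=name, description=desc, members=frozenset(genes)))
    return sets


# ----------------------------------------------------------------------- rnk

def write_rnk(ranked: pd.Series, path) -> None:
    df = ranked.rename("metric")
    df.index.name = "gene"
    df.to_csv(path, sep="\t", header=False, float_format=FLOAT_FMT)


def read_rnk(path) -> pd.Series:
    genes: list[str] = []
    metrics: list[float] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(path, lineno, "expected two columns: gene, metric")
            gene, raw = fields
            if gene in seen:
                raise FormatError(path, lineno, f"duplicate gene {gene!r}")
            seen.add(gene)
            try:
                metric = float(raw)
            except ValueError:
                raise FormatError(path, lineno, f"non-numeric metric {raw!r}") from None
            genes.append(gene)
            metrics.append(metric)
    if not genes:
        raise FormatError(path, None, "empty ranked list")
    return pd.Series(metrics, index=pd.Index(genes, name="gene"), name="metric")


# ----------------------------------------------------------------- DEG table

def write_deg_table(deg: pd.DataFrame, path) -> None:
    out = deg.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_deg_table(path) -> pd.DataFrame:
    deg = pd.read_csv(path, sep="\t", index_col=0)
    expected = ["log2fc", "stat", "p", "q", "direction"]
    if list(deg.columns) != expected:
        raise FormatError(path, 1, f"expected columns {expected}, got {list(deg.columns)}")
    if deg.index.has_duplicates:
        dup = deg.index[deg.index.duplicated()][0]
        raise FormatError(path, None, f"duplicate gene {dup!r}")
    return deg


# ---------------------------------------------------------------- GSEA table

def write_gsea_results(results: list[GseaResult], q: list[float] | None, path) -> None:
    rows = []
    for i, res in enumerate(results):
        rows.append(
            {
                "set": res.set_name,
                "es": res.es,
                "nes": res.nes if res.nes is not None else np.nan,
                "p_perm": res.p_perm if res.p_perm is not None else np.nan,
                "q": q[i] if q is not None else np.nan,
                "n_perm": res.n_perm,
                "n_leading_edge": len(res.leading_edge),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_leading_edges(results: list[GseaResult], path) -> None:
    """One GMT-style line per set: name, description, leading-edge genes."""
    with open(path, "w") as fh:
        for res in results:
            fh.write("\t".join([res.set_name, "leading_edge", *res.leading_edge]) + "\n")


# ----------------------------------------------------------------- signature

def write_signature(sig: DiseaseSignature, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tdirection\tprovenance\n")
        for gene in sorted(sig.entries):
            prov = ";".join(sig.provenance.get(gene, []))
            fh.write(f"{gene}\t{sig.entries[gene]}\t{prov}\n")


def read_signature(path) -> DiseaseSignature:
    entries: dict[str, str] = {}
    provenance: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != ["gene", "direction", "provenance"]:
            raise FormatError(path, 1, "expected header: gene, direction, provenance")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(path, lineno, "expected three columns")
            gene, direction, prov = fields
            if gene in entries:
                raise FormatError(path, lineno, f"duplicate gene {gene!r}")
            if direction not in ("up", "down"):
                raise FormatError(path, lineno, f"direction must be up|down, got {direction!r}")
            entries[gene] = direction
            provenance[gene] = [p for p in prov.split(";") if p]
    if not entries:
        raise FormatError(path, None, "empty signature")
    return DiseaseSignature(entries=entries, provenance=provenance)


# -------------------------------------------------------------- ingredients

_ING_COLUMNS = ["ingredient_id", "ingredient_name", "gene", "direction", "significance"]


def write_ingredient_db(db: list[IngredientSignature], path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        payload = [
            {
                "ingredient_id": ing.ingredient_id,
                "ingredient_name": ing.ingredient_name,
                "perturbations": {
                    g: {"direction": d, "significance": s}
                    for g, (d, s) in sorted(ing.perturbations.items())
                },
            }
            for ing in db
        ]
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    with open(path, "w") as fh:
        fh.write("\t".join(_ING_COLUMNS) + "\n")
        for ing in db:
            for gene in sorted(ing.perturbations):
                direction, sig = ing.perturbations[gene]
                fh.write(
                    f"{ing.ingredient_id}\t{ing.ingredient_name}\t{gene}"
                    f"\t{direction}\t{FLOAT_FMT % sig}\n"
                )


def read_ingredient_db(path) -> list[IngredientSignature]:
    path = Path(path)
    if path.suffix == ".json":
        return _read_ingredient_json(path)
    order: list[str] = []
    names: dict[str, str] = {}
    perturbations: dict[str, dict[str, tuple[str, float]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != _ING_COLUMNS:
            raise FormatError(path, 1, f"expected header {_ING_COLUMNS}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(path, lineno, "expected five columns")
            ing_id, name, gene, direction, raw_sig = fields
            if direction not in ("up", "down"):
                raise FormatError(path, lineno, f"direction must be up|down, got {direction!r}")
            try:
                sig = float(raw_sig)
            except ValueError:
                raise FormatError(path, lineno, f"non-numeric significance {raw_sig!r}") from None
            if ing_id not in perturbations:
                order.append(ing_id)
                names[ing_id] = name
                perturbations[ing_id] = {}
            if gene in perturbations[ing_id]:
                raise FormatError(path, lineno, f"duplicate gene {gene!r} for {ing_id}")
            perturbations[ing_id][gene] = (direction, sig)
    if not order:
        raise FormatError(path, None, "empty ingredient database")
    try:
        return [
            IngredientSignature(ingredient_id=i, ingredient_name=names[i], perturbations=perturbations[i])
            for i in order
        ]
    except ValueError as exc:
        raise FormatError(path, None, str(exc)) from exc


def _read_ingredient_json(path: Path) -> list[IngredientSignature]:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(path, exc.lineno, f"invalid JSON: {exc.msg}") from exc
    if not isinstance(payload, list) or not payload:
        raise FormatError(path, None, "expected a non-empty JSON array of ingredients")
    db = []
    for entry in payload:
        try:
            db.append(
                IngredientSignature(
                    ingredient_id=entry["ingredient_id"],
                    ingredient_name=entry.get("ingredient_name", ""),
                    perturbations={
                        g: (v["direction"], float(v["significance"]))
                        for g, v in entry["perturbations"].items()
                    },
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(path, None, f"malformed ingredient entry: {exc}") from exc
    return db


# -------------------------------------------------------------- screen table

def write_screen_records(records: list[ScreenRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tingredient_id\tscore\tn_matched\n")
        for rec in sorted(records, key=lambda r: r.rank):
            fh.write(f"{rec.rank}\t{rec.ingredient_id}\t{rec.score}\t{rec.n_matched}\n")


# ------------------------------------------------------------------ networks

def write_sif(net: nx.Graph, path) -> None:
    """SIF edge list: ingredient TAB regulation TAB gene, sorted."""
    lines = []
    for u, v, data in net.edges(data=True):
        ing, gene = (u, v) if net.nodes[u].get("kind") == "ingredient" else (v, u)
        lines.append(f"{ing}\t{data['regulation']}\t{gene}")
    with open(path, "w") as fh:
        fh.write("\n".join(sorted(lines)) + ("\n" if lines else ""))


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path, named_key_ids=True)


# ---------------------------------------------------------------------- JSON

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
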