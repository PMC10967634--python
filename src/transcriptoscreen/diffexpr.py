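"""Two-group differential expression on log2 expression values.

Per-gene Welch t-tests (unequal variances), Benjamini-Hochberg adjustment
across all genes, direction calls at an adjusted-p threshold, and
construction of the signed ranking metric consumed by gene-set enrichment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DISEASE = "disease"
CONTROL = "control"

#: valid choices for the GSEA ranking metric
RANK_METRICS = ("signed_logp", "log2fc", "t_stat")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with a two-class sample grouping.

    Parameters
    ----------
    values
        DataFrame of finite log2 expression values, indexed by unique gene
        symbols, with unique sample IDs as columns.
    groups
        Series mapping every sample ID to ``"disease"`` or ``"control"``;
        each group must contain at least two samples.
    """

    values: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols: {list(dupes[:5])}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = self.values.columns[self.groups.isna()]
            raise ValueError(f"samples without group label: {list(missing[:5])}")
        bad = set(self.groups.unique()) - {DISEASE, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        counts = self.groups.value_counts()
        for grp in (DISEASE, CONTROL):
            if counts.get(grp, 0) < 2:
                raise ValueError(f"group '{grp}' needs >= 2 samples")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, group: str) -> pd.Index:
        return self.groups.index[self.groups == group]


def welch_arrays(d: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t over rows of two (genes x samples) arrays.

    Genes with zero variance in both groups get ``stat = 0`` and ``p = 1``:
    the statistic is undefined there and the convention keeps degenerate
    synthetic genes from aborting a run.
    """
    with warnings.catch_warnings():
        # near-constant genes trigger a precision warning; the flat case is
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(d, c, axis=1, equal_var=False)
    stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    flat = (d.var(axis=1, ddof=1) == 0) & (c.var(axis=1, ddof=1) == 0)
    if flat.any():
        logger.warning("%d gene(s) with zero variance in both groups; p set to 1", int(flat.sum()))
        stat[flat] = 0.0
        p[flat] = 1.0
    return stat, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(mat: ExpressionMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene Welch test of disease vs control on log2 values.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (disease
    minus control group-mean difference), ``stat`` (Welch t), ``p`` (two
    sided), ``q`` (BH over all genes) and ``direction`` in
    ``{"up", "down", "ns"}`` where up/down require ``q < alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    d = mat.values[mat.group_samples(DISEASE)].to_numpy(dtype=float)
    c = mat.values[mat.group_samples(CONTROL)].to_numpy(dtype=float)
    stat, p = welch_arrays(d, c)
    log2fc = d.mean(axis=1) - c.mean(axis=1)
    q = bh_adjust(p)
    direction = np.where(q < alpha, np.where(log2fc > 0, "up", "down"), "ns")
    # a significant gene with exactly zero fold change has no direction
    direction[(q < alpha) & (log2fc == 0)] = "ns"
    return pd.DataFrame(
        {"log2fc": log2fc, "stat": stat, "p": p, "q": q, "direction": direction},
        index=mat.genes,
    )


def rank_genes(
    deg: pd.DataFrame, metric: str = "signed_logp", p_floor: float = 1e-300
) -> pd.Series:
    """Order genes by a descending signed ranking metric for GSEA.

    ``signed_logp`` (default) is sign(log2fc) * -log10(max(p, p_floor));
    ``log2fc`` and ``t_stat`` use those columns directly. Ties are broken
    by descending log2fc, then ascending gene symbol, so the order is
    deterministic. Returns the metric as a Series indexed by gene, in rank
    order.
    """
    if metric not in RANK_METRICS:
        raise ValueError(f"metric must be one of {RANK_METRICS}")
    if metric == "signed_logp":
        vals = np.sign(deg["log2fc"].to_numpy()) * -np.log10(
            np.maximum(deg["p"].to_numpy(dtype=float), p_floor)
        )
    elif metric == "log2fc":
        vals = deg["log2fc"].to_numpy(dtype=float)
    else:
        vals = deg["stat"].to_numpy(dtype=float)
    order = pd.DataFrame(
        {"metric": vals, "log2fc": deg["log2fc"].to_numpy(), "gene": deg.index}
    ).sort_values(
        ["metric", "log2fc", "gene"], ascending=[False, False, True], kind="mergesort"
    )
    return pd.Series(order["metric"].to_numpy(), index=pd.Index(order["gene"], name="gene"), name="metric")
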