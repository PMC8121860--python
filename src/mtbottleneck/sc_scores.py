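"""Single-cell expression QC, normalization, gene-list scores and DEG tests.

The pipeline mirrors standard single-cell preprocessing: cells with fewer
than 200 detected genes are removed, then genes detected in fewer than 3
cells; counts are depth-normalized to 10,000 per cell and log(1 + x)
transformed.  Per-cell metabolic activity is scored per curated gene list
(OXPHOS, glycolysis, mtDNA replication, autophagy, lysosomal) as the number
of list genes expressed in the cell — "expressed" meaning count > 0 —
divided by the number of list genes present in the matrix, giving a score
in [0, 1].  Differential expression between two conditions uses per-gene
two-sided Wilcoxon rank-sum tests on the log-normalized values with
Benjamini-Hochberg correction across genes.
"""

from __future__ import annotations

import warnings
from importlib import resources

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .bottleneck_sim import GeneList
from .hetstats import bh_adjust

__all__ = [
    "GeneList",
    "read_gene_list",
    "load_default_gene_lists",
    "qc_filter",
    "normalize_log",
    "gene_list_score",
    "wilcoxon_deg",
    "score_compare",
]

DEFAULT_MIN_GENES = 200
DEFAULT_MIN_CELLS = 3
DEFAULT_TARGET = 10_000.0


def read_gene_list(path, name: str | None = None) -> GeneList:
    """Read a one-symbol-per-line gene list; '#' lines may name the list."""
    genes: list[str] = []
    list_name = name
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if list_name is None and line.lstrip("# ").strip():
                    list_name = line.lstrip("# ").split()[0]
                continue
            genes.append(line.split()[0])
    if list_name is None:
        import os

        list_name = os.path.splitext(os.path.basename(str(path)))[0]
    return GeneList(name=list_name, genes=tuple(genes))


def load_default_gene_lists() -> dict[str, GeneList]:
    """Packaged curated gene lists keyed by name (oxphos, glycolysis, ...)."""
    lists = {}
    root = resources.files("mtbottleneck").joinpath("data/gene_lists")
    for entry in sorted(root.iterdir()):
        if entry.name.endswith(".txt"):
            gl = read_gene_list(entry, name=entry.name.removesuffix(".txt"))
            lists[gl.name] = gl
    return lists


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def qc_filter(
    adata: ad.AnnData,
    min_genes: int = DEFAULT_MIN_GENES,
    min_cells: int = DEFAULT_MIN_CELLS,
    order: str = "cells_first",
) -> ad.AnnData:
    """Remove low-coverage cells, then rarely detected genes.

    Both thresholds are strict ("fewer than"): a cell is kept when it detects
    at least ``min_genes`` genes, a gene when it is detected (count > 0) in at
    least ``min_cells`` cells.  ``order`` controls whether cells or genes are
    filtered first (cells first by default; the alternative order can change
    the result and is exposed deliberately).  Removal counts are stored in
    ``.uns['qc']``.
    """
    if order not in ("cells_first", "genes_first"):
        raise ValueError(f"unknown qc order {order!r}")
    X = _dense(adata.X)
    out = adata.copy()

    def keep_cells(a):
        detected = (_dense(a.X) > 0).sum(axis=1)
        return a[detected >= min_genes].copy()

    def keep_genes(a):
        detected_in = (_dense(a.X) > 0).sum(axis=0)
        return a[:, detected_in >= min_cells].copy()

    if order == "cells_first":
        out = keep_genes(keep_cells(out))
    else:
        out = keep_cells(keep_genes(out))
    if out.n_obs == 0 or out.n_vars == 0:
        raise ValueError(
            f"QC removed everything: {adata.n_obs - out.n_obs} cells and "
            f"{adata.n_vars - out.n_vars} genes dropped"
        )
    out.uns["qc"] = {
        "cells_removed": int(adata.n_obs - out.n_obs),
        "genes_removed": int(adata.n_vars - out.n_vars),
        "min_genes": int(min_genes),
        "min_cells": int(min_cells),
        "order": order,
    }
    del X
    return out


def normalize_log(adata: ad.AnnData, target: float = DEFAULT_TARGET) -> ad.AnnData:
    """Scale each cell to ``target`` total counts, then log(1 + x).

    Raw counts are preserved in ``layers['counts']``.  A zero-total cell is an
    error (impossible after QC).
    """
    X = _dense(adata.X).astype(float)
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts; run QC first")
    out = adata.copy()
    out.layers["counts"] = X.copy()
    out.X = np.log1p(X * (target / totals[:, None]))
    out.uns["normalization"] = {"target": float(target), "log": "ln(1+x)"}
    return out


def _match_list_genes(adata: ad.AnnData, gene_list: GeneList) -> list[str]:
    """List genes present in the matrix, matched case-insensitively."""
    lower_index: dict[str, str] = {}
    for name in adata.var_names:
        key = name.lower()
        if key in lower_index:
            warnings.warn(f"case collision between genes {lower_index[key]!r} and {name!r}")
        else:
            lower_index[key] = name
    present = [lower_index[g.lower()] for g in gene_list.genes if g.lower() in lower_index]
    if not present:
        raise ValueError(
            f"gene list {gene_list.name!r} shares no genes with the matrix"
        )
    return present


def gene_list_score(adata: ad.AnnData, gene_list: GeneList) -> pd.DataFrame:
    """Per-cell raw count and normalized score of expressed list genes.

    Uses raw counts when available (``layers['counts']``); a gene is expressed
    in a cell when its count > 0 (normalization preserves zeros, so the score
    is identical before and after ``normalize_log``).  The normalized score
    divides by the number of list genes present in the matrix, so it lies in
    [0, 1] and equals 1 only when every matched list gene is detected.
    """
    present = _match_list_genes(adata, gene_list)
    view = adata[:, present]
    sub = _dense(view.layers["counts"] if "counts" in adata.layers else view.X)
    raw = (sub > 0).sum(axis=1).astype(int)
    return pd.DataFrame(
        {
            "cell_id": adata.obs_names,
            "list": gene_list.name,
            "raw_count": raw,
            "n_list_genes_present": len(present),
            "score": raw / len(present),
        }
    ).set_index("cell_id")


def wilcoxon_deg(
    adata: ad.AnnData,
    group_labels,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum DEG test between two groups.

    Applied to the log-normalized values; exact null distribution for small
    tie-free samples and the tie-corrected normal approximation otherwise
    (scipy's policy).  BH adjustment across genes; ``significant`` flags
    adjusted p < alpha, ``direction`` is the sign of the group-A minus
    group-B mean difference.  Constant genes get p = 1 and are kept.
    """
    labels = np.asarray(group_labels)
    if labels.shape[0] != adata.n_obs:
        raise ValueError("one label per cell required")
    groups = sorted(pd.unique(labels))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {list(groups)}")
    ga, gb = groups  # deterministic order: 'up' = higher in the first group
    X = _dense(adata.X).astype(float)
    xa, xb = X[labels == ga], X[labels == gb]
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("each group needs at least 3 cells")

    constant = np.all(X == X[0], axis=0)
    pvals = np.ones(adata.n_vars)
    stats_u = np.full(adata.n_vars, np.nan)
    if np.any(~constant):
        res = stats.mannwhitneyu(
            xa[:, ~constant], xb[:, ~constant], alternative="two-sided", axis=0
        )
        pvals[~constant] = res.pvalue
        stats_u[~constant] = res.statistic
    reject, p_adj = bh_adjust(pvals, q=alpha)
    diff = xa.mean(axis=0) - xb.mean(axis=0)
    return pd.DataFrame(
        {
            "gene": adata.var_names,
            "statistic": stats_u,
            "p_value": pvals,
            "p_adjusted": p_adj,
            "direction": np.where(diff >= 0, "up", "down"),
            "mean_diff": diff,
            "significant": reject,
        }
    ).set_index("gene")


def score_compare(scores_a, scores_b, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum p-value comparing per-cell list scores between groups."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 cells")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative=alternative).pvalue)
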