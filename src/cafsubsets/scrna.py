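"""Marker-based CAF-S1/CAF-S5 filtering of scRNA data and differential expression.

Fibroblast count matrices are filtered to the two FAP+/PDPN+ subsets by
presence/absence of marker transcripts: cells expressing CD29 (ITGB1),
PDGFRb, PDPN and FAP but not FSP1 (S100A4) are retained, and split into
CAF-S1 (aSMA/ACTA2 detected) versus CAF-S5 (ACTA2 undetected).
"Expressed" means raw count > 0.

Differential expression between the groups uses a two-sided Wilcoxon
rank-sum test on library-size-normalised log counts (CPM, log1p) with
Benjamini-Hochberg correction — an assumption-light engine whose
acceptance surface is effect direction, not exact p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .profiles import SchemaError

__all__ = [
    "DEFAULT_ALIASES",
    "filter_caf_s1_s5",
    "differential_expression",
    "top_genes",
]

#: Protein-name to gene-symbol aliases used by the filter.
DEFAULT_ALIASES: dict[str, str] = {
    "CD29": "ITGB1",
    "PDGFRb": "PDGFRB",
    "PDPN": "PDPN",
    "FAP": "FAP",
    "FSP1": "S100A4",
    "aSMA": "ACTA2",
}


def _counts_matrix(adata) -> np.ndarray:
    X = adata.X
    if sparse.issparse(X):
        X = X.toarray()
    return np.asarray(X)


def _gene_counts(adata, symbol: str) -> np.ndarray:
    j = adata.var_names.get_loc(symbol)
    X = adata.X
    col = X[:, j]
    if sparse.issparse(col):
        col = col.toarray().ravel()
    return np.asarray(col).ravel()


def filter_caf_s1_s5(adata, aliases: dict[str, str] | None = None) -> pd.Series:
    """Label each cell CAF-S1, CAF-S5 or excluded by marker criteria.

    Included cells have ITGB1, PDGFRB, PDPN and FAP counts > 0 and
    S100A4 = 0; included cells are CAF-S1 when ACTA2 > 0, else CAF-S5.
    Raises a schema error listing any required gene symbol absent from
    the matrix (after alias resolution).
    """
    aliases = {**DEFAULT_ALIASES, **(aliases or {})}
    needed = [aliases[p] for p in ("CD29", "PDGFRb", "PDPN", "FAP", "FSP1", "aSMA")]
    missing = [g for g in needed if g not in adata.var_names]
    if missing:
        raise SchemaError(f"matrix missing required genes: {missing}")

    inc = np.ones(adata.n_obs, dtype=bool)
    for p in ("CD29", "PDGFRb", "PDPN", "FAP"):
        inc &= _gene_counts(adata, aliases[p]) > 0
    inc &= _gene_counts(adata, aliases["FSP1"]) == 0

    asma = _gene_counts(adata, aliases["aSMA"]) > 0
    labels = np.where(~inc, "excluded", np.where(asma, "CAF-S1", "CAF-S5"))
    return pd.Series(labels, index=adata.obs_names, name="subset")


def differential_expression(
    adata,
    labels: pd.Series,
    group: str = "CAF-S5",
    reference: str = "CAF-S1",
    min_cells: int = 3,
) -> pd.DataFrame:
    """Two-group DE: Wilcoxon rank-sum on CPM-log1p values.

    Positive log2 fold-change means up in ``group`` (CAF-S5 by
    default).  Genes detected in fewer than ``min_cells`` cells overall
    are excluded from testing; genes with no variation get p = 1.
    Returns a gene-indexed frame with ``lfc``, ``p``, ``q`` and the
    per-group mean CPM.
    """
    labels = labels.reindex(adata.obs_names)
    in_g = (labels == group).to_numpy()
    in_r = (labels == reference).to_numpy()
    if in_g.sum() < min_cells or in_r.sum() < min_cells:
        raise ValueError(
            f"need >= {min_cells} cells per group "
            f"(got {int(in_g.sum())} vs {int(in_r.sum())})")

    X = _counts_matrix(adata)[in_g | in_r]
    grp = in_g[in_g | in_r]
    lib = X.sum(axis=1, keepdims=True).astype(float)
    lib[lib == 0] = 1.0
    cpm = X / lib * 1e6
    logcpm = np.log1p(cpm)

    detected = (X > 0).sum(axis=0) >= min_cells
    genes = adata.var_names[detected]
    A = logcpm[grp][:, detected]
    B = logcpm[~grp][:, detected]

    p = np.ones(A.shape[1])
    varying = ~(np.all(A == A[0:1], axis=0) & np.all(B == B[0:1], axis=0)
                & (A[0] == B[0]))
    if varying.any():
        res = stats.mannwhitneyu(
            A[:, varying], B[:, varying], alternative="two-sided", axis=0)
        p[varying] = res.pvalue
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = multipletests(p, method="fdr_bh")[1]

    mean_g = cpm[grp][:, detected].mean(axis=0)
    mean_r = cpm[~grp][:, detected].mean(axis=0)
    lfc = np.log2((mean_g + 1.0) / (mean_r + 1.0))

    return pd.DataFrame(
        {
            "lfc": lfc,
            "p": p,
            "q": q,
            f"mean_{group}": mean_g,
            f"mean_{reference}": mean_r,
        },
        index=pd.Index(genes, name="gene"),
    )


def top_genes(de: pd.DataFrame, n: int = 50) -> list[str]:
    """The ``n`` most significant genes.

    Ordered by ascending q, ties broken by descending absolute fold
    change, then gene symbol.
    """
    if len(de) == 0:
        raise ValueError("empty DE result")
    tmp = de.reset_index()
    gene_col = tmp.columns[0]
    tmp["_negabs"] = -tmp["lfc"].abs()
    tmp = tmp.sort_values(["q", "_negabs", gene_col], kind="mergesort")
    return list(tmp[gene_col].iloc[:n])
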