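"""Top-regulator selection, hierarchical clustering and gene correlations.

For each of the seven outcome patterns the best-supported promoting and
inhibiting genes are selected by gene-level p-value; their combined log2
fold-change profiles across all patterns form an effect matrix that is
row-standardized, clustered with average linkage, and summarized as a
gene-gene Pearson correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .patterns import EDITED_PATTERNS

__all__ = ["EffectMatrix", "select_top_genes", "hcluster_profiles", "pearson_matrix"]

DEFAULT_N_TOP = 50


@dataclass
class EffectMatrix:
    """Genes x patterns matrix of combined log2 fold changes."""

    values: pd.DataFrame  # rows: genes, cols: patterns
    standardized: bool = False
    constant_rows: list[str] = field(default_factory=list)

    def standardize(self) -> "EffectMatrix":
        """Per-row z-scores across patterns; constant rows become all-zero."""
        X = self.values.to_numpy(dtype=float)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        constant = (sd.ravel() == 0) | ~np.isfinite(sd.ravel())
        sd = np.where(sd > 0, sd, 1.0)
        Z = (X - mu) / sd
        Z[constant] = 0.0
        return EffectMatrix(
            values=pd.DataFrame(Z, index=self.values.index,
                                columns=self.values.columns),
            standardized=True,
            constant_rows=list(self.values.index[constant]),
        )


def select_top_genes(
    gene_scores: pd.DataFrame,
    n_top: int = DEFAULT_N_TOP,
    p_col: str = "p_combined",
    lfc_col: str = "combined_log2fc",
) -> tuple[pd.DataFrame, EffectMatrix]:
    """Select the top promoting and inhibiting genes per pattern.

    ``gene_scores`` holds one row per gene x pattern x direction with a
    gene-level p-value.  Per pattern and direction the ``n_top`` smallest
    p-values are taken (ties broken by rra score if present, then gene
    name, so the selection is invariant to input row order).  The selection
    list keeps duplicates across patterns (7 patterns x 2 directions x
    n_top slots); matrix rows are the deduplicated genes with their effect
    profile across all patterns.
    """
    sort_cols = [p_col] + (["rra_rho"] if "rra_rho" in gene_scores else []) + ["gene"]
    picks = []
    patterns = [p for p in EDITED_PATTERNS if p in set(gene_scores["pattern"])]
    for pattern in patterns:
        for direction in ("promoting", "inhibiting"):
            block = gene_scores[
                (gene_scores["pattern"] == pattern)
                & (gene_scores["direction"] == direction)
            ].sort_values(sort_cols, kind="mergesort")
            if len(block) < n_top:
                import warnings
                warnings.warn(
                    f"only {len(block)} candidates for {pattern}/{direction}; "
                    f"taking all", stacklevel=2,
                )
            picks.append(block.head(n_top))
    selection = pd.concat(picks, ignore_index=True)

    genes = sorted(selection["gene"].unique())
    # Effect profile: per gene x pattern combined log2fc.  A gene appears in
    # both directions of a pattern's score table with the same effect size;
    # deduplicate on (gene, pattern).
    profile = (
        gene_scores.drop_duplicates(["gene", "pattern"])
        .pivot(index="gene", columns="pattern", values=lfc_col)
        .reindex(index=genes, columns=patterns)
    )
    return selection, EffectMatrix(values=profile)


def hcluster_profiles(
    matrix: EffectMatrix,
    axis: str = "rows",
    metric: str = "euclidean",
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering of effect profiles.

    Standardizes the matrix first if it is not already.  Returns the scipy
    linkage matrix (merge table: left, right, height, size) and the leaf
    labels in dendrogram order.  Ties merge lower original indices first
    (scipy's deterministic order).

    Raises
    ------
    ValueError
        If the matrix contains NaNs (offending genes are listed).
    """
    m = matrix if matrix.standardized else matrix.standardize()
    df = m.values if axis == "rows" else m.values.T
    if len(df) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    X = df.to_numpy(dtype=float)
    bad = df.index[np.isnan(X).any(axis=1)]
    if len(bad):
        raise ValueError(f"NaN effect values for: {list(bad)}")
    if metric == "correlation":
        dist = pdist(X, metric="correlation")
    else:
        dist = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(Z)
    return Z, [df.index[i] for i in order]


def pearson_matrix(matrix: EffectMatrix) -> pd.DataFrame:
    """Gene-gene Pearson correlations of effect profiles.

    Symmetric with unit diagonal; rows with zero variance produce NaN
    entries (flagged in ``matrix.constant_rows`` after standardization).
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=matrix.values.index, columns=matrix.values.index)
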