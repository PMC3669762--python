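"""Functional-category abundance profiling.

Builds category x site abundance matrices from long-format annotation
tables, converts to relative abundance, row-standardizes across sites,
and runs PCA (delegating to :mod:`matbin.ordination`) and two-way
hierarchical clustering with either the Pearson/average or the
Euclidean/complete recipe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from matbin.ordination import OrdinationResult, pca

__all__ = [
    "FunctionalMatrix",
    "DendrogramResult",
    "read_functional_table",
    "relative_abundance",
    "standardize_rows",
    "hcluster",
    "profile_pca",
]

_LINKAGES = ("average", "complete")
_DISTANCES = ("euclidean", "pearson")


@dataclass
class FunctionalMatrix:
    """Category x site abundance matrix with its normalization state."""

    data: pd.DataFrame  # categories (rows) x sites (columns)
    normalization: str = "raw"  # raw | relative | row-standardized

    @property
    def categories(self) -> list[str]:
        return list(self.data.index)

    @property
    def sites(self) -> list[str]:
        return list(self.data.columns)


def read_functional_table(
    path: str | Path, mapping: Mapping[str, str] | str | Path | None = None
) -> FunctionalMatrix:
    """Aggregate a long-format table (family, category, site, count).

    With ``mapping`` (family -> category; a two-column TSV path is
    accepted) the category column may be absent and is derived from the
    family id. Counts for the same (category, site) are summed.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if isinstance(mapping, (str, Path)):
        mdf = pd.read_csv(mapping, sep="\t", comment="#", dtype=str, header=None)
        mapping = dict(zip(mdf.iloc[:, 0], mdf.iloc[:, 1]))
    if mapping is not None:
        fam_col = cols.get("family") or cols.get("protein_family") or cols.get("id")
        if fam_col is None:
            raise ValueError(f"{path}: no family column to apply mapping to")
        df["category"] = df[fam_col].map(lambda f: mapping.get(str(f), "unmapped"))
        cols["category"] = "category"
    for needed in ("category", "site", "count"):
        if needed not in cols:
            raise ValueError(f"{path}: missing column {needed!r}; found {list(df.columns)}")
    wide = (
        df.pivot_table(
            index=cols["category"], columns=cols["site"], values=cols["count"],
            aggfunc="sum", fill_value=0,
        )
        .astype(float)
    )
    wide.index.name, wide.columns.name = "category", "site"
    if (wide.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return FunctionalMatrix(data=wide, normalization="raw")


def relative_abundance(matrix: FunctionalMatrix) -> FunctionalMatrix:
    """Divide each site column by its total; zero-total sites are an error."""
    totals = matrix.data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"site(s) with zero total abundance: {list(zero.index)}")
    return FunctionalMatrix(data=matrix.data / totals, normalization="relative")


def standardize_rows(matrix: FunctionalMatrix) -> FunctionalMatrix:
    """Per-category z-scores across sites; constant rows dropped with a notice."""
    X = matrix.data
    sd = X.std(axis=1, ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index
    if len(constant):
        warnings.warn(
            f"dropping {len(constant)} constant categor{'y' if len(constant) == 1 else 'ies'}: "
            f"{list(constant)[:5]}{'...' if len(constant) > 5 else ''}",
            stacklevel=2,
        )
        X = X.drop(index=constant)
        sd = sd.drop(index=constant)
    Z = X.sub(X.mean(axis=1), axis=0).div(sd, axis=0)
    return FunctionalMatrix(data=Z, normalization="row-standardized")


@dataclass
class DendrogramResult:
    """Agglomerative merge tree over items (sites or categories)."""

    items: list[str]
    merge_tree: np.ndarray  # scipy linkage matrix
    linkage: str
    distance: str
    cophenetic: np.ndarray  # condensed cophenetic distances

    def cut(self, n_clusters: int) -> dict[str, int]:
        """item -> cluster label (1..n_clusters) at the flat cut."""
        flat = fcluster(self.merge_tree, n_clusters, criterion="maxclust")
        return dict(zip(self.items, (int(c) for c in flat)))

    def heights(self) -> np.ndarray:
        return self.merge_tree[:, 2]

    def to_newick(self) -> str:
        tree = to_tree(self.merge_tree)

        def walk(node) -> str:
            if node.is_leaf():
                return self.items[node.id]
            left, right = walk(node.left), walk(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"


def hcluster(matrix, distance: str = "euclidean", linkage_method: str = "complete") -> DendrogramResult:
    """Hierarchical clustering of rows of ``matrix``.

    ``distance`` is ``"euclidean"`` or ``"pearson"`` (1 - r);
    ``linkage_method`` is ``"average"`` or ``"complete"`` (both monotone,
    so merge heights never decrease). To cluster sites of a
    :class:`FunctionalMatrix`, pass ``fm.data.T``.
    """
    if isinstance(matrix, FunctionalMatrix):
        matrix = matrix.data
    if isinstance(matrix, pd.DataFrame):
        items = [str(i) for i in matrix.index]
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        items = [str(i) for i in range(X.shape[0])]
    if distance not in _DISTANCES:
        raise ValueError(f"distance must be one of {_DISTANCES}")
    if linkage_method not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 items")
    if np.isnan(X).any():
        raise ValueError("matrix contains NaN")
    if distance == "pearson":
        if X.shape[1] < 2:
            raise ValueError("pearson distance needs >= 2 variables per item")
        dvec = pdist(X, metric="correlation")  # 1 - r
        if np.isnan(dvec).any():
            raise ValueError("pearson distance undefined for constant items")
        dvec = np.clip(dvec, 0.0, None)
    else:
        dvec = pdist(X, metric="euclidean")
    Z = linkage(dvec, method=linkage_method)
    coph = cophenet(Z)
    return DendrogramResult(
        items=items, merge_tree=Z, linkage=linkage_method,
        distance=distance, cophenetic=coph,
    )


def profile_pca(matrix: FunctionalMatrix, n_axes: int = 3, scale: bool = False) -> OrdinationResult:
    """PCA across sites (sites are observations, categories variables)."""
    return pca(matrix.data.T, n_axes=n_axes, scale=scale)
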