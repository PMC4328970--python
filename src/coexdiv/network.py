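"""Weighted gene coexpression network construction and module detection.

The network is built from the expression profiles of a filtered gene set:
Pearson correlations are raised (in absolute value) to a soft-threshold
power ``beta`` to give the weighted adjacency, the topological overlap
matrix (TOM) converts adjacency into a neighborhood-sharing similarity, and
average-linkage (UPGMA) hierarchical clustering on the TOM dissimilarity
``1 - TOM`` groups genes into modules by cutting the dendrogram at a fixed
height.  Clusters smaller than a minimum size stay unassigned.

The unsigned TOM for genes i != j is

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity ``k_i = sum_{u != i} a_iu``; the diagonal is 1.

Each module is summarized by its eigengene: the first right-singular vector
of the per-gene standardized module expression matrix (the module's first
principal component across samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CoexpressionModules",
    "ModuleSet",
    "Eigengene",
    "correlation_matrix",
    "adjacency_from_correlation",
    "topological_overlap",
    "average_linkage_dendrogram",
    "cut_modules",
    "module_eigengene",
    "kruskal_wallis",
    "linkage_to_newick",
    "MODULE_COLORS",
]

# WGCNA-convention color sequence: module labels in decreasing size order.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)

UNASSIGNED = "unassigned"


def correlation_matrix(expression: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Pearson correlation between all gene pairs across samples.

    ``expression`` has genes as rows and samples as columns (>=3 samples).
    Constant-expression genes have undefined correlation and must be removed
    beforehand; they raise here.
    """
    X = np.asarray(expression, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("need a genes x samples matrix with >=3 samples")
    sd = X.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        if isinstance(expression, pd.DataFrame):
            names = [str(expression.index[i]) for i in flat[:10]]
        else:
            names = [f"row {i}" for i in flat[:10]]
        raise ValueError(f"constant-expression gene(s): {', '.join(names)}")
    cor = np.corrcoef(X)
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    if isinstance(expression, pd.DataFrame):
        return pd.DataFrame(cor, index=expression.index, columns=expression.index)
    return cor


def adjacency_from_correlation(cor, beta: float = 10.0):
    """Soft-threshold power adjacency ``a_ij = |cor_ij|^beta``, diagonal 1."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    C = np.asarray(cor, dtype=float)
    A = np.abs(C) ** beta
    np.fill_diagonal(A, 1.0)
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(A, index=cor.index, columns=cor.columns)
    return A


def topological_overlap(adjacency):
    """Unsigned topological overlap matrix of a weighted adjacency.

    Vectorized via one matrix product over the zero-diagonal adjacency.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    shared = A0 @ A0  # sum_u a_iu a_uj, u ranging over all, incl. i and j (both zeroed)
    k = A0.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + A0) / (kmin + 1.0 - A0)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


def average_linkage_dendrogram(dissimilarity) -> np.ndarray:
    """UPGMA merge tree (scipy linkage matrix) of a square dissimilarity."""
    D = np.asarray(dissimilarity, dtype=float)
    if np.isnan(D).any():
        raise ValueError("dissimilarity contains NaN")
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(np.diag(D), 0.0, atol=1e-9):
        raise ValueError("dissimilarity diagonal must be zero")
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return linkage(squareform(D, checks=False), method="average")


@dataclass
class Eigengene:
    """First-principal-component summary of one module's expression."""

    module: str
    v1: pd.Series  # per-sample values, unit norm
    variance_explained: float
    kw_statistic: float | None = None
    kw_p: float | None = None


@dataclass
class ModuleSet:
    """Gene-to-module assignment from cutting a coexpression dendrogram."""

    assignment: pd.Series  # gene -> module label ("unassigned" for none)
    dendrogram: np.ndarray | None = None
    cut_height: float = 0.995
    min_module_size: int = 30
    eigengenes: dict[str, Eigengene] = field(default_factory=dict)

    @property
    def modules(self) -> list[str]:
        sizes = self.assignment[self.assignment != UNASSIGNED].value_counts()
        return list(sizes.index)

    def genes_in(self, module: str) -> list[str]:
        return list(self.assignment.index[self.assignment == module])

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def to_tsv(self, path: str | Path) -> None:
        self.assignment.rename("module_label").rename_axis("gene").to_csv(path, sep="\t")


def cut_modules(
    dendrogram: np.ndarray,
    genes,
    cut_height: float = 0.995,
    min_module_size: int = 30,
) -> ModuleSet:
    """Form modules by removing dendrogram merges above ``cut_height``.

    Clusters smaller than ``min_module_size`` are labeled ``unassigned``;
    surviving modules are labeled by decreasing size with the conventional
    color sequence (largest = turquoise).
    """
    genes = pd.Index(genes)
    heights = dendrogram[:, 2]
    max_h = float(heights.max()) if len(heights) else 0.0
    if cut_height < 0 or cut_height > max(max_h, 1.0):
        raise ValueError(f"cut_height {cut_height} outside [0, {max(max_h, 1.0)}]")
    if len(genes) == 1:
        flat = np.array([1])
    else:
        flat = fcluster(dendrogram, t=cut_height, criterion="distance")
    sizes = pd.Series(flat).value_counts()
    surviving = sizes[sizes >= min_module_size].index
    # order by size desc, ties by cluster id for determinism
    surviving = sorted(surviving, key=lambda c: (-sizes[c], c))
    label_of = {}
    for rank, c in enumerate(surviving):
        if rank < len(MODULE_COLORS):
            label_of[c] = MODULE_COLORS[rank]
        else:
            label_of[c] = f"module{rank + 1}"
    assignment = pd.Series(
        [label_of.get(c, UNASSIGNED) for c in flat], index=genes, name="module_label"
    )
    return ModuleSet(assignment, dendrogram, cut_height, min_module_size)


def module_eigengene(expression: pd.DataFrame, module_genes, label: str = "") -> Eigengene:
    """Eigengene of a module: first right-singular vector of the per-gene
    standardized (zero-mean, unit-variance across samples) expression.

    The sign is fixed so the eigengene correlates positively with the
    module's mean standardized profile (ties broken toward the first gene).
    """
    module_genes = list(module_genes)
    if len(module_genes) < 2:
        raise ValueError("module must have >=2 genes")
    X = expression.loc[module_genes].to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant-expression gene in module")
    Z = (X - mu) / sd
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    v1 = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    mean_profile = Z.mean(axis=0)
    orient = float(np.dot(v1, mean_profile))
    if orient == 0.0:
        orient = float(np.dot(v1, Z[0]))
    if orient < 0:
        v1 = -v1
    return Eigengene(
        module=label,
        v1=pd.Series(v1, index=expression.columns, name=label),
        variance_explained=var_explained,
    )


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test of ``values`` against group labels.

    Returns ``(H, p)`` with the tie-corrected statistic and the chi-squared
    approximation.  All-identical values give ``(0.0, 1.0)`` by convention.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >=2 groups")
    parts = [values[groups == g] for g in labels]
    if any(len(p) == 0 for p in parts):
        raise ValueError("empty group")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*parts)
    return float(h), float(p)


def linkage_to_newick(dendrogram: np.ndarray, genes) -> str:
    """Serialize a scipy linkage matrix to a Newick string with heights."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(dendrogram, list(genes))
    return str(tree).strip()


class CoexpressionModules(BaseEstimator, ClusterMixin):
    """Detect coexpression modules in a weighted gene network.

    A scikit-learn style clusterer over genes: ``fit(X)`` takes a matrix
    whose *rows are genes* and columns are samples (each gene is one
    observation described by its expression profile), builds the Pearson
    correlation, the ``|cor|^beta`` adjacency and the topological overlap
    matrix, clusters genes by UPGMA on ``1 - TOM`` and cuts the dendrogram
    at a fixed height, discarding clusters below ``min_module_size``.

    Parameters
    ----------
    beta : float, default 10
        Soft-threshold power of the adjacency.
    cut_height : float, default 0.995
        Static dendrogram cut height on the TOM dissimilarity scale.
    min_module_size : int, default 30
        Smallest cluster retained as a module; smaller clusters are
        left unassigned (label ``-1``).

    Attributes
    ----------
    labels_ : ndarray of int
        Module index per gene, ``-1`` for unassigned.
    module_labels_ : ndarray of str
        Conventional color label per gene (``"unassigned"`` for -1).
    correlation_, adjacency_, tom_ : ndarray
        The three gene-by-gene network matrices.
    linkage_ : ndarray
        scipy linkage matrix of the UPGMA dendrogram.
    module_set_ : ModuleSet
        Label-based view of the assignment.
    """

    def __init__(self, beta: float = 10.0, cut_height: float = 0.995, min_module_size: int = 30):
        self.beta = beta
        self.cut_height = cut_height
        self.min_module_size = min_module_size

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            genes = X.index
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            genes = pd.RangeIndex(values.shape[0]).astype(str)
        if values.ndim != 2:
            raise ValueError("X must be 2-D (genes x samples)")
        sd = values.std(axis=1)
        keep = sd > 0
        if not keep.all():
            dropped = [str(g) for g, k in zip(genes, keep) if not k]
            warnings.warn(
                f"excluding {len(dropped)} constant-expression gene(s): "
                + ", ".join(dropped[:5]),
                stacklevel=2,
            )
        self.dropped_genes_ = [str(g) for g, k in zip(genes, keep) if not k]
        kept_genes = pd.Index([g for g, k in zip(genes, keep) if k])
        V = values[keep]

        self.correlation_ = correlation_matrix(V)
        self.adjacency_ = adjacency_from_correlation(self.correlation_, self.beta)
        self.tom_ = topological_overlap(self.adjacency_)
        self.linkage_ = average_linkage_dendrogram(1.0 - self.tom_)
        module_set = cut_modules(
            self.linkage_, kept_genes, self.cut_height, self.min_module_size
        )
        self.genes_ = kept_genes
        self.module_set_ = module_set

        order = module_set.modules  # size-ranked labels
        index_of = {m: i for i, m in enumerate(order)}
        kept_idx = np.array(
            [index_of.get(m, -1) for m in module_set.assignment.to_numpy()], dtype=int
        )
        # map back onto the full input gene list (dropped genes -> -1)
        full_idx = np.full(len(genes), -1, dtype=int)
        full_idx[np.flatnonzero(keep)] = kept_idx
        self.labels_ = full_idx
        full_lab = np.array([UNASSIGNED] * len(genes), dtype=object)
        full_lab[np.flatnonzero(keep)] = module_set.assignment.to_numpy()
        self.module_labels_ = full_lab
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def eigengenes(self, expression: pd.DataFrame) -> dict[str, Eigengene]:
        """Compute eigengenes of every fitted module from ``expression``
        (genes x samples; must contain the fitted genes)."""
        check_is_fitted(self, "module_set_")
        out = {}
        for m in self.module_set_.modules:
            out[m] = module_eigengene(expression, self.module_set_.genes_in(m), m)
        self.module_set_.eigengenes = out
        return out
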