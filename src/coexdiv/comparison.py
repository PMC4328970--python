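"""Cross-network module preservation and hub-gene extraction.

Two coexpression networks built independently (e.g. one per breed) are
compared module-by-module on their shared gene universe.  For every pair of
modules the number of shared genes, the overlap fraction on each side and a
hypergeometric upper-tail p-value are computed.  A module pair is called
preserved when the larger of its two overlap fractions exceeds 50% and the
overlap is significant (p < 0.001); modules participating in no preserved
pair are condition-specific.  Within a module, the strongest intra-module
edges (top 300 by topological overlap) form the module backbone, and genes
with at least 15 backbone connections are its hub genes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import UNASSIGNED

__all__ = [
    "PreservationResult",
    "overlap_table",
    "overlap_fractions",
    "hypergeometric_overlap_p",
    "classify_preservation",
    "compare_module_sets",
    "module_backbone",
    "hub_genes",
]


@dataclass
class PreservationResult:
    """Overlap statistics for one pair of modules from two networks."""

    module_a: str
    module_b: str
    overlap: int
    size_a: int
    size_b: int
    fraction_a: float
    fraction_b: float
    p_value: float
    preserved: bool = False


def _assigned(assignment: pd.Series) -> pd.Series:
    return assignment[assignment != UNASSIGNED]


def overlap_table(assignment_a: pd.Series, assignment_b: pd.Series) -> pd.DataFrame:
    """Contingency table of gene counts over module-label pairs.

    Both assignments are restricted to their shared gene universe (genes
    assigned to a module in both networks are counted; unassigned genes are
    excluded).  Cell (a, b) counts genes in module a of network A and module
    b of network B.
    """
    a = _assigned(assignment_a)
    b = _assigned(assignment_b)
    shared = a.index.intersection(b.index)
    missing = len(assignment_a.index.symmetric_difference(assignment_b.index))
    if missing:
        warnings.warn(f"{missing} gene(s) absent from one of the two networks", stacklevel=2)
    if len(shared) == 0:
        raise ValueError("empty shared gene universe")
    return pd.crosstab(
        a.reindex(shared).rename("module_a"), b.reindex(shared).rename("module_b")
    )


def overlap_fractions(overlap: int, size_a: int, size_b: int) -> tuple[float, float, int, int]:
    """Overlap fractions and rounded percentages on each side of a pair."""
    if size_a <= 0 or size_b <= 0:
        raise ValueError("module sizes must be positive")
    if overlap > min(size_a, size_b):
        raise ValueError("overlap cannot exceed the smaller module")
    fa, fb = overlap / size_a, overlap / size_b
    return fa, fb, round(fa * 100), round(fb * 100)


def hypergeometric_overlap_p(overlap: int, size_a: int, size_b: int, universe: int) -> float:
    """Upper-tail hypergeometric p-value ``P(X >= overlap)`` for the number
    of shared genes between a module of ``size_a`` and one of ``size_b``
    drawn from ``universe`` genes."""
    if overlap > min(size_a, size_b) or size_a > universe or size_b > universe:
        raise ValueError("inconsistent counts")
    if overlap < 0 or size_a < 0 or size_b < 0 or universe < 0:
        raise ValueError("counts must be nonnegative")
    return float(stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))


def classify_preservation(
    results: list[PreservationResult],
    fraction_threshold: float = 0.5,
    p_threshold: float = 0.001,
) -> tuple[list[PreservationResult], list[str], list[str]]:
    """Call preserved module pairs and condition-specific modules.

    A pair qualifies when ``max(fraction_a, fraction_b) > fraction_threshold``
    and ``p < p_threshold``.  Qualifying pairs are matched one-to-one
    greedily by ascending p-value (ties broken by labels), so each module
    appears in at most one preserved pair.  Modules of either network in no
    preserved pair are condition-specific.

    Returns ``(preserved_pairs, specific_a, specific_b)``.
    """
    for r in results:
        r.preserved = False
    candidates = [
        r
        for r in results
        if max(r.fraction_a, r.fraction_b) > fraction_threshold and r.p_value < p_threshold
    ]
    candidates.sort(key=lambda r: (r.p_value, r.module_a, r.module_b))
    used_a: set[str] = set()
    used_b: set[str] = set()
    preserved = []
    for r in candidates:
        if r.module_a in used_a or r.module_b in used_b:
            continue
        r.preserved = True
        preserved.append(r)
        used_a.add(r.module_a)
        used_b.add(r.module_b)
    all_a = sorted({r.module_a for r in results})
    all_b = sorted({r.module_b for r in results})
    specific_a = [m for m in all_a if m not in used_a]
    specific_b = [m for m in all_b if m not in used_b]
    return preserved, specific_a, specific_b


def compare_module_sets(
    assignment_a: pd.Series,
    assignment_b: pd.Series,
    fraction_threshold: float = 0.5,
    p_threshold: float = 0.001,
) -> pd.DataFrame:
    """Full pairwise preservation analysis of two module assignments.

    Module sizes and overlap fractions use the full module memberships (as
    the printed percentages do); the hypergeometric universe is the union
    of all module genes of both networks.  Every module pair appears, with
    overlap 0 when the memberships are disjoint.  Returns one row per pair
    with overlap counts, fractions, p-value and the preserved flag.
    """
    a = _assigned(assignment_a)
    b = _assigned(assignment_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("a network has no assigned module genes")
    universe = len(a.index.union(b.index))
    modules_a = a.value_counts()
    modules_b = b.value_counts()
    results = []
    for ma, mb in itertools.product(modules_a.index, modules_b.index):
        genes_a = set(a.index[a == ma])
        genes_b = set(b.index[b == mb])
        ov = len(genes_a & genes_b)
        sa, sb = int(modules_a[ma]), int(modules_b[mb])
        fa, fb, _, _ = overlap_fractions(ov, sa, sb)
        p = hypergeometric_overlap_p(ov, sa, sb, universe)
        results.append(PreservationResult(str(ma), str(mb), ov, sa, sb, fa, fb, p))
    classify_preservation(results, fraction_threshold, p_threshold)
    return pd.DataFrame(
        {
            "module_a": [r.module_a for r in results],
            "module_b": [r.module_b for r in results],
            "overlap": [r.overlap for r in results],
            "size_a": [r.size_a for r in results],
            "size_b": [r.size_b for r in results],
            "fraction_a": [r.fraction_a for r in results],
            "fraction_b": [r.fraction_b for r in results],
            "p_value": [r.p_value for r in results],
            "preserved": [r.preserved for r in results],
        }
    )


def module_backbone(tom: pd.DataFrame, module_genes, k: int = 300) -> pd.DataFrame:
    """Top-``k`` strongest intra-module edges by topological overlap.

    Ties are broken by lexicographic gene-pair order for determinism.
    Returns a DataFrame with columns ``gene_i, gene_j, weight``.
    """
    module_genes = sorted(str(g) for g in module_genes)
    if not module_genes:
        raise ValueError("empty module")
    missing = [g for g in module_genes if g not in tom.index]
    if missing:
        raise ValueError(f"module genes absent from network: {missing[:5]}")
    sub = tom.loc[module_genes, module_genes].to_numpy()
    n = len(module_genes)
    iu, ju = np.triu_indices(n, k=1)
    weights = sub[iu, ju]
    pairs = sorted(
        zip(weights, (module_genes[i] for i in iu), (module_genes[j] for j in ju)),
        key=lambda t: (-t[0], t[1], t[2]),
    )[:k]
    return pd.DataFrame(pairs, columns=["weight", "gene_i", "gene_j"])[
        ["gene_i", "gene_j", "weight"]
    ]


def hub_genes(backbone: pd.DataFrame, min_connections: int = 15) -> pd.DataFrame:
    """Genes with backbone degree >= ``min_connections``, sorted by degree
    descending (ties by gene id).  Returns columns ``gene, degree``."""
    degrees = pd.concat([backbone["gene_i"], backbone["gene_j"]]).value_counts()
    hubs = degrees[degrees >= min_connections]
    out = hubs.rename("degree").rename_axis("gene").reset_index()
    return out.sort_values(["degree", "gene"], ascending=[False, True], ignore_index=True)
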