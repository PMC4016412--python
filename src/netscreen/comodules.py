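"""Co-expression module detection.

Pipeline per network representation: soft-power adjacency from |r|,
topological overlap dissimilarity, average-linkage hierarchical clustering,
a deterministic tree-style dynamic cut, and optional merging of modules
whose eigengenes are highly correlated.  Power-1 partitions are used
unmerged; power-6 partitions are eigengene-merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .expr_io import CorrelationMatrix, ExpressionMatrix, pearson_correlation

UNASSIGNED = "unassigned"

__all__ = [
    "UNASSIGNED",
    "ModulePartition",
    "soft_adjacency",
    "topological_overlap",
    "cut_modules",
    "module_eigengene",
    "merge_by_eigengene",
    "build_representations",
]


@dataclass
class ModulePartition:
    """Assignment of genes to co-expression modules for one representation."""

    representation_id: str
    assignment: dict[str, str]
    power: int = 1
    min_module_size: int = 30
    merge_height: float = 0.15
    merged: bool = False

    def __post_init__(self) -> None:
        for label, genes in self.modules().items():
            if len(genes) < self.min_module_size:
                raise ValueError(
                    f"module {label!r} has {len(genes)} genes "
                    f"(< min_module_size={self.min_module_size})"
                )

    def modules(self) -> dict[str, list[str]]:
        """Mapping module label -> member genes, excluding the unassigned pool."""
        out: dict[str, list[str]] = {}
        for g, m in self.assignment.items():
            if m != UNASSIGNED:
                out.setdefault(m, []).append(g)
        return out

    @property
    def n_modules(self) -> int:
        return len(self.modules())

    def assigned_genes(self) -> list[str]:
        return [g for g, m in self.assignment.items() if m != UNASSIGNED]


def soft_adjacency(c: CorrelationMatrix, power: int) -> np.ndarray:
    """Soft-threshold adjacency a_ij = |r_ij|^power, zero diagonal."""
    if int(power) != power or power < 1:
        raise ValueError(f"power must be an integer >= 1, got {power}")
    a = c.abs_r() ** int(power)
    np.fill_diagonal(a, 0.0)
    return a


def topological_overlap(a: np.ndarray) -> np.ndarray:
    """Topological overlap dissimilarity of a soft adjacency matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k_i = sum_u a_iu; returns 1 - TOM with zero diagonal.  A pair whose
    denominator vanishes (two fully isolated nodes) gets dissimilarity 1.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=0)
    shared = a @ a
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    tom = np.clip(tom, 0.0, 1.0)
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    return d


def _static_cut_roots(node, h0):
    """Maximal subtrees merged at height <= h0 (the static cut forest)."""
    if node.is_leaf() or node.dist <= h0:
        return [node]
    return _static_cut_roots(node.left, h0) + _static_cut_roots(node.right, h0)


def _refine(node, min_size):
    """Recursively split a branch while both children can stand alone."""
    if node.is_leaf():
        return [node]
    left, right = node.left, node.right
    if left.count >= min_size and right.count >= min_size:
        return _refine(left, min_size) + _refine(right, min_size)
    return [node]


def cut_modules(
    d: np.ndarray,
    gene_ids: list[str],
    min_size: int = 30,
    *,
    representation_id: str = "rep",
    power: int = 1,
    cut_fraction: float = 0.99,
) -> ModulePartition:
    """Average-linkage clustering with a deterministic tree-style dynamic cut.

    The dendrogram is cut at ``cut_fraction`` of the maximum merge height;
    each resulting branch is then recursively split wherever both
    sub-branches hold at least ``min_size`` leaves.  Final clusters smaller
    than ``min_size`` fall into the unassigned pool.  Ties are broken by the
    input gene order (scipy linkage is deterministic for a fixed input).
    """
    d = np.asarray(d, dtype=float)
    n = len(gene_ids)
    if d.shape != (n, n):
        raise ValueError("dissimilarity shape does not match gene_ids")
    if n < min_size:
        warnings.warn(
            f"{n} genes < min_size={min_size}: all genes unassigned", stacklevel=2
        )
        return ModulePartition(
            representation_id, {g: UNASSIGNED for g in gene_ids}, power, min_size
        )
    z = linkage(squareform(d, checks=False), method="average")
    root = to_tree(z)
    h0 = cut_fraction * root.dist
    clusters = []
    for branch in _static_cut_roots(root, h0):
        clusters.extend(_refine(branch, min_size))
    assignment = {g: UNASSIGNED for g in gene_ids}
    label_no = 0
    # order modules by their smallest leaf index for stable labels
    for node in sorted(clusters, key=lambda nd: min(nd.pre_order())):
        leaves = node.pre_order()
        if len(leaves) < min_size:
            continue
        label_no += 1
        for i in leaves:
            assignment[gene_ids[i]] = f"M{label_no}"
    return ModulePartition(representation_id, assignment, power, min_size)


def module_eigengene(x: ExpressionMatrix, genes: list[str]) -> np.ndarray:
    """First principal component score vector of a module (length = replicates).

    Gene rows are standardized; missing cells are imputed with the gene
    mean.  The eigengene is sign-oriented to correlate positively with the
    mean module expression profile.
    """
    idx = [x.gene_ids.index(g) for g in genes]
    m = x.values[idx, :].copy()
    row_mean = np.nanmean(m, axis=1, keepdims=True)
    nan_mask = np.isnan(m)
    m[nan_mask] = np.broadcast_to(row_mean, m.shape)[nan_mask]
    m -= m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    m /= sd
    _, _, vt = np.linalg.svd(m, full_matrices=False)
    eig = vt[0]
    mean_profile = m.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return eig


def merge_by_eigengene(
    p: ModulePartition, x: ExpressionMatrix, height: float = 0.15
) -> ModulePartition:
    """Iteratively merge modules whose eigengene dissimilarity 1 - r < height.

    The closest pair is merged first and eigengenes are recomputed after
    each merge, until no pair is below the cutoff.  Modules with fewer than
    two genes are excluded from merging.  ``height = 0`` is a no-op.
    """
    if not 0 <= height < 1:
        raise ValueError("height must lie in [0, 1)")
    modules = p.modules()
    if height == 0 or len(modules) < 2:
        return ModulePartition(
            p.representation_id, dict(p.assignment), p.power, p.min_module_size,
            height, merged=True,
        )
    groups = {label: list(genes) for label, genes in sorted(modules.items())}
    while len(groups) > 1:
        labels = [lb for lb in sorted(groups) if len(groups[lb]) >= 2]
        if len(labels) < 2:
            break
        eigs = {lb: module_eigengene(x, groups[lb]) for lb in labels}
        best = None
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                r = float(np.corrcoef(eigs[la], eigs[lb])[0, 1])
                diss = 1.0 - r
                if diss < height and (best is None or diss < best[0]):
                    best = (diss, la, lb)
        if best is None:
            break
        _, la, lb = best
        groups[la] = groups[la] + groups[lb]
        del groups[lb]
    assignment = {g: UNASSIGNED for g in p.assignment}
    for label, genes in groups.items():
        for g in genes:
            assignment[g] = label
    return ModulePartition(
        p.representation_id, assignment, p.power, p.min_module_size, height, merged=True
    )


def build_representations(
    expr_by_period: dict[str, ExpressionMatrix],
    powers: tuple[int, ...] = (1, 6),
    *,
    min_module_size: int = 30,
    merge_height: float = 0.15,
    merge_powers: tuple[int, ...] = (6,),
    correlations: dict[str, CorrelationMatrix] | None = None,
) -> dict[str, ModulePartition]:
    """Build one ModulePartition per (period, power) representation.

    Partitions for powers listed in ``merge_powers`` are eigengene-merged;
    the rest are returned unmerged.  Precomputed correlation matrices may be
    passed via ``correlations`` (keyed by period).
    """
    out: dict[str, ModulePartition] = {}
    for period, x in expr_by_period.items():
        c = (correlations or {}).get(period) or pearson_correlation(x)
        for power in powers:
            rep_id = f"{period}_p{power}"
            a = soft_adjacency(c, power)
            d = topological_overlap(a)
            part = cut_modules(
                d, c.gene_ids, min_module_size,
                representation_id=rep_id, power=power,
            )
            if power in merge_powers and part.n_modules > 1:
                part = merge_by_eigengene(part, x, merge_height)
            out[rep_id] = part
    return out
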