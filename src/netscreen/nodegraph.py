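"""Collapse tightly correlated genes into nodes and build the thresholded network.

Within each module, genes with average-linkage |r| above the multi-gene cut
(default 0.75) are collapsed into one node.  Nodes — single- or multi-gene —
are then connected whenever the average absolute correlation between their
member genes strictly exceeds the edge threshold (default 0.7).  Edges may
cross module boundaries: the adjacency is defined on correlation alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .comodules import ModulePartition
from .expr_io import CorrelationMatrix

__all__ = ["NodeGraph", "collapse_multinodes", "build_adjacency"]


@dataclass
class NodeGraph:
    """Single-/multi-gene nodes with a binary thresholded adjacency.

    ``nodes[i]`` is the sorted tuple of member genes of node i; ``adjacency``
    is a symmetric boolean matrix with no self-edges (None until
    :func:`build_adjacency` runs).
    """

    nodes: list[tuple[str, ...]]
    representation_id: str = "rep"
    adjacency: np.ndarray | None = None
    edge_threshold: float | None = None
    node_of_gene: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.node_of_gene = {}
        for i, members in enumerate(self.nodes):
            for g in members:
                if g in self.node_of_gene:
                    raise ValueError(f"gene {g!r} appears in more than one node")
                self.node_of_gene[g] = i
        if self.adjacency is not None:
            adj = np.asarray(self.adjacency, dtype=bool)
            n = len(self.nodes)
            if adj.shape != (n, n):
                raise ValueError("adjacency shape does not match node count")
            if not np.array_equal(adj, adj.T):
                raise ValueError("adjacency must be symmetric")
            if adj.diagonal().any():
                raise ValueError("self-edges are not allowed")
            self.adjacency = adj

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        if self.adjacency is None:
            return 0
        return int(self.adjacency.sum()) // 2

    def genes(self) -> list[str]:
        return [g for members in self.nodes for g in members]

    def multi_gene_nodes(self, min_genes: int = 2) -> list[int]:
        return [i for i, m in enumerate(self.nodes) if len(m) >= min_genes]

    def neighbor_counts(self, labels: np.ndarray) -> np.ndarray:
        """Per-node count of neighbors with label 1."""
        if self.adjacency is None:
            raise ValueError("adjacency not built")
        return self.adjacency.astype(float) @ np.asarray(labels, dtype=float)


def collapse_multinodes(
    c: CorrelationMatrix,
    p: ModulePartition,
    cut: float = 0.75,
) -> NodeGraph:
    """Cluster each module at average-linkage |r| = ``cut`` into nodes.

    Within a module, average-linkage clustering on dissimilarity 1 - |r| is
    cut at height 1 - cut; clusters of two or more genes become multi-gene
    nodes, the rest stay single-gene nodes.  Unassigned genes carry no
    module neighborhood and are excluded.  ``cut`` must exceed the 0.7 edge
    threshold so that within-node cohesion is stronger than between-node
    edges.
    """
    if cut <= 0.7:
        raise ValueError(f"multi-gene cut must be > 0.7, got {cut}")
    abs_r = c.abs_r()
    nodes: list[tuple[str, ...]] = []
    for _, genes in sorted(p.modules().items()):
        genes = sorted(genes)
        if len(genes) == 1:
            nodes.append((genes[0],))
            continue
        idx = [c.index_of(g) for g in genes]
        sub = abs_r[np.ix_(idx, idx)]
        d = 1.0 - sub
        np.fill_diagonal(d, 0.0)
        z = linkage(squareform(d, checks=False), method="average")
        memberships = fcluster(z, t=1.0 - cut, criterion="distance")
        clusters: dict[int, list[str]] = {}
        for g, m in zip(genes, memberships):
            clusters.setdefault(int(m), []).append(g)
        for _, cluster_genes in sorted(
            clusters.items(), key=lambda kv: min(kv[1])
        ):
            nodes.append(tuple(sorted(cluster_genes)))
    return NodeGraph(nodes, representation_id=p.representation_id)


def build_adjacency(
    g: NodeGraph, c: CorrelationMatrix, threshold: float = 0.7
) -> NodeGraph:
    """Connect nodes whose between-node average |r| strictly exceeds ``threshold``.

    For single-gene nodes this reduces to |r_ij| > threshold.  Missing
    correlations contribute 0 to the average (absent evidence is not an
    edge).
    """
    abs_r = c.abs_r()
    n = g.n_nodes
    # membership indicator, rows normalized -> block means via two matmuls
    member = np.zeros((n, c.n_genes))
    for i, genes in enumerate(g.nodes):
        for gene in genes:
            member[i, c.index_of(gene)] = 1.0 / len(genes)
    avg = member @ abs_r @ member.T
    adj = avg > threshold
    np.fill_diagonal(adj, False)
    adj &= adj.T
    return NodeGraph(
        list(g.nodes),
        representation_id=g.representation_id,
        adjacency=adj,
        edge_threshold=threshold,
    )
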