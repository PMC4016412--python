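"""Synthetic expression and genetic-score generators.

Expression blocks follow a one-factor model,
x = sqrt(rho) * f_block + sqrt(1 - rho) * eps, so the expected within-block
correlation is exactly rho and each block has a well-defined leading factor.
Genetic signal is planted either inside correlation blocks (clustered risk)
or scattered uniformly — the contrast the dilution experiments exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .expr_io import ExpressionMatrix
from .nodegraph import NodeGraph

__all__ = [
    "SyntheticTruth",
    "generate_expression",
    "plant_genetic_signal",
    "desk_scenario",
    "node_level_scenario",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset, recorded for recovery tests."""

    risk_genes: set[str] = field(default_factory=set)
    module_assignment: dict[str, int] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def generate_expression(
    n_genes: int,
    blocks: list[tuple[int, float]],
    n_replicates: int,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Block-correlated expression from one latent factor per block.

    ``blocks`` is a list of (size, rho) pairs; block sizes must sum to at
    most ``n_genes`` and rho must lie in [0, 1).  Genes outside all blocks
    are independent noise (block id -1 in the truth record).
    """
    sizes = [s for s, _ in blocks]
    if sum(sizes) > n_genes:
        raise ValueError("block sizes exceed n_genes")
    for _, rho in blocks:
        if not 0 <= rho < 1:
            raise ValueError(f"rho must lie in [0, 1), got {rho}")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    values = rng.standard_normal((n_genes, n_replicates))
    assignment = {g: -1 for g in genes}
    pos = 0
    for bi, (size, rho) in enumerate(blocks):
        factor = rng.standard_normal(n_replicates)
        sl = slice(pos, pos + size)
        values[sl] = np.sqrt(rho) * factor + np.sqrt(1 - rho) * values[sl]
        for g in genes[sl]:
            assignment[g] = bi
        pos += size
    truth = SyntheticTruth(
        module_assignment=assignment,
        params={
            "n_genes": n_genes, "blocks": list(blocks),
            "n_replicates": n_replicates, "seed": seed,
        },
    )
    return ExpressionMatrix(genes, values, [f"S{j + 1}" for j in range(n_replicates)]), truth


def plant_genetic_signal(
    truth: SyntheticTruth,
    frac_risk: float,
    mu_true: float,
    clustering: str = "within-block",
    seed: int = 0,
    *,
    dnlof_gene_fraction: float = 0.25,
) -> pd.DataFrame:
    """Plant risk genes and draw their association scores.

    Risk genes get z ~ N(mu_true, 1), null genes z ~ N(0, 1); P = 1 - Phi(z).
    ``clustering`` places risk genes inside correlation blocks (filling
    blocks one by one) or scattered uniformly.  De novo LoF counts are drawn
    so that about half the genes carrying a simulated dnLoF are true risk
    genes.  Returns a score DataFrame (gene, p, z, dnlof, risk) and updates
    ``truth.risk_genes``.
    """
    if not 0 < frac_risk < 1:
        raise ValueError("frac_risk must lie in (0, 1)")
    if mu_true < 0:
        raise ValueError("mu_true must be non-negative")
    if clustering not in {"within-block", "scattered"}:
        raise ValueError(f"unknown clustering mode: {clustering!r}")
    rng = np.random.default_rng(seed)
    genes = list(truth.module_assignment)
    n_risk = max(1, round(frac_risk * len(genes)))
    if clustering == "within-block":
        in_blocks = [g for g in genes if truth.module_assignment[g] >= 0]
        ordered = sorted(in_blocks, key=lambda g: (truth.module_assignment[g], g))
        risk = ordered[:n_risk]
        if len(risk) < n_risk:  # blocks exhausted; spill over to leftovers
            rest = [g for g in genes if g not in set(risk)]
            risk += list(rng.choice(rest, size=n_risk - len(risk), replace=False))
    else:
        risk = list(rng.choice(genes, size=n_risk, replace=False))
    risk_set = set(risk)
    is_risk = np.array([g in risk_set for g in genes])
    z = rng.standard_normal(len(genes))
    z[is_risk] += mu_true
    p = norm.sf(z)
    # dnLoF carriers: half sampled from risk genes, half from null genes
    k = max(1, round(dnlof_gene_fraction * n_risk))
    dnlof = np.zeros(len(genes), dtype=int)
    risk_idx = np.nonzero(is_risk)[0]
    null_idx = np.nonzero(~is_risk)[0]
    hit_risk = rng.choice(risk_idx, size=min(k, risk_idx.size), replace=False)
    hit_null = rng.choice(null_idx, size=min(k, null_idx.size), replace=False)
    for idx in (hit_risk, hit_null):
        dnlof[idx] = 1
    # a few recurrent genes among the risk carriers
    if hit_risk.size >= 4:
        dnlof[rng.choice(hit_risk, size=hit_risk.size // 4, replace=False)] = 2
    truth.risk_genes = risk_set
    truth.params.update({
        "frac_risk": frac_risk, "mu_true": mu_true, "clustering": clustering,
    })
    return pd.DataFrame(
        {"gene": genes, "p": p, "z": z, "dnlof": dnlof, "risk": is_risk}
    )


def node_level_scenario(
    seed: int = 0,
    *,
    n_communities: int = 10,
    community_size: int = 30,
    p_in: float = 0.25,
    p_out: float = 0.005,
    n_risk_communities: int = 2,
    mu_true: float = 2.2,
    n_dnlof: int = 12,
) -> tuple[NodeGraph, pd.DataFrame, np.ndarray]:
    """Node-level benchmark: community graph with risk planted in whole communities.

    Returns a single-gene-per-node :class:`~netscreen.nodegraph.NodeGraph`
    over a planted-partition graph, a score table where the first
    ``n_risk_communities`` communities carry z ~ N(mu_true, 1) (null
    elsewhere), and the boolean risk mask.  dnLoF carriers are split evenly
    between risk and null genes.  This is the test bed for the dilution
    experiments, which operate at the node level.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    n = n_communities * community_size
    graph = nx.planted_partition_graph(n_communities, community_size, p_in, p_out,
                                       seed=seed)
    adj = nx.to_numpy_array(graph).astype(bool)
    genes = [f"N{i:04d}" for i in range(n)]
    risk = np.zeros(n, dtype=bool)
    risk[: n_risk_communities * community_size] = True
    z = rng.standard_normal(n)
    z[risk] += mu_true
    dnlof = np.zeros(n, dtype=int)
    half = n_dnlof // 2
    dnlof[rng.choice(np.nonzero(risk)[0], size=half, replace=False)] = 1
    dnlof[rng.choice(np.nonzero(~risk)[0], size=n_dnlof - half, replace=False)] = 1
    scores = pd.DataFrame(
        {"gene": genes, "p": norm.sf(z), "z": z, "dnlof": dnlof, "risk": risk}
    )
    g = NodeGraph([(x,) for x in genes], representation_id=f"nodes_seed{seed}",
                  adjacency=adj, edge_threshold=None)
    return g, scores, risk


def desk_scenario(
    seed: int = 0,
    *,
    n_genes: int = 1000,
    n_replicates: int = 120,
    n_blocks: int = 8,
    block_size: int = 60,
    rho: float = 0.72,
    frac_risk: float = 0.05,
    mu_true: float = 3.0,
    clustering: str = "within-block",
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Default desk-scale scenario: expression, scores and ground truth."""
    blocks = [(block_size, rho)] * n_blocks
    x, truth = generate_expression(n_genes, blocks, n_replicates, seed=seed)
    scores = plant_genetic_signal(
        truth, frac_risk, mu_true, clustering, seed=seed + 1
    )
    return x, scores, truth
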