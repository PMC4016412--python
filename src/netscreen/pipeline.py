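"""End-to-end orchestration: representations -> screen -> clean -> combine.

One *representation* is a (period, soft power) version of the co-expression
network.  The pipeline builds each representation's module partition and
node graph, screens with the HMRF, cleans with the stratified mixture FDR,
and combines calls across representations by minimum q.  Network scores are
computed per period and summarized by their maximum.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .comodules import build_representations
from .expr_io import CorrelationMatrix, ExpressionMatrix, pearson_correlation
from .fdr_clean import combine_representations, stratified_q
from .genetics import score_nodes
from .hmrf_screen import HMRFFit, ScreenResult, call_nasd, fit_hmrf
from .netstat import network_scores
from .nodegraph import NodeGraph, build_adjacency, collapse_multinodes

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RepresentationResult", "PipelineResult",
           "screen_clean_representation", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline constants, defaulting to the published thresholds."""

    powers: tuple[int, ...] = (1, 6)
    edge_threshold: float = 0.7
    multinode_cut: float = 0.75
    posterior_threshold: float = 0.5
    q_threshold: float = 0.05
    min_module_size: int = 30
    merge_height: float = 0.15
    score_r_min: float = 0.7
    score_z_min: float = 1.2
    init_p_threshold: float = 0.05
    validation_threshold: float = 0.9
    seed: int = 0
    max_iter: int = 50

    def __post_init__(self) -> None:
        if self.multinode_cut <= self.edge_threshold:
            raise ValueError("multinode cut must exceed the edge threshold")
        for name in ("posterior_threshold", "q_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RepresentationResult:
    representation_id: str
    graph: NodeGraph
    node_scores: pd.DataFrame
    fit: HMRFFit
    screen: ScreenResult
    q_table: pd.DataFrame


@dataclass
class PipelineResult:
    config: RunConfig
    representations: dict[str, RepresentationResult]
    final: pd.DataFrame
    network_scores: pd.Series
    config_hash: str = field(default="")

    def risk_genes(self) -> list[str]:
        return sorted(self.final.loc[self.final["risk"], "gene"])

    def screened_genes(self) -> list[str]:
        out: set[str] = set()
        for rep in self.representations.values():
            out.update(rep.screen.nasd_genes)
        return sorted(out)


def screen_clean_representation(
    graph: NodeGraph,
    scores: pd.DataFrame,
    config: RunConfig,
    seed: int | None = None,
) -> RepresentationResult:
    """Screen (HMRF) then clean (stratified mixture FDR) one representation."""
    seed = config.seed if seed is None else seed
    node_scores = score_nodes(graph, scores)
    fit = fit_hmrf(
        graph, node_scores, seed=seed, max_iter=config.max_iter,
        init_p_threshold=config.init_p_threshold,
    )
    screen = call_nasd(fit, graph, config.posterior_threshold)
    q_table = stratified_q(screen, graph, scores, seed=seed)
    return RepresentationResult(
        graph.representation_id, graph, node_scores, fit, screen, q_table
    )


def build_graphs(
    expr_by_period: dict[str, ExpressionMatrix],
    config: RunConfig,
    correlations: dict[str, CorrelationMatrix] | None = None,
) -> tuple[dict[str, NodeGraph], dict[str, CorrelationMatrix]]:
    """Module partitions and node graphs for every (period, power) representation."""
    corr = dict(correlations or {})
    for period, x in expr_by_period.items():
        if period not in corr:
            corr[period] = pearson_correlation(x)
    partitions = build_representations(
        expr_by_period, config.powers,
        min_module_size=config.min_module_size,
        merge_height=config.merge_height,
        correlations=corr,
    )
    graphs: dict[str, NodeGraph] = {}
    for rep_id, part in partitions.items():
        period = rep_id.rsplit("_p", 1)[0]
        g = collapse_multinodes(corr[period], part, config.multinode_cut)
        graphs[rep_id] = build_adjacency(g, corr[period], config.edge_threshold)
        logger.info("representation %s: %d nodes, %d edges",
                    rep_id, graphs[rep_id].n_nodes, graphs[rep_id].n_edges)
    return graphs, corr


def run_pipeline(
    expr_by_period: dict[str, ExpressionMatrix],
    scores: pd.DataFrame,
    config: RunConfig | None = None,
    validation_scores: pd.DataFrame | None = None,
) -> PipelineResult:
    """Full screen-and-clean run over all representations.

    ``expr_by_period`` maps a period label to its expression matrix;
    ``scores`` is the gene score table (columns gene, p, z, dnlof).
    Deterministic for a fixed config seed.
    """
    config = config or RunConfig()
    graphs, corr = build_graphs(expr_by_period, config)
    reps = {
        rep_id: screen_clean_representation(graph, scores, config)
        for rep_id, graph in graphs.items()
    }
    final = combine_representations(
        {rep_id: r.q_table for rep_id, r in reps.items()},
        validation_scores,
        q_threshold=config.q_threshold,
        validation_threshold=config.validation_threshold,
    )
    per_period = [
        network_scores(cm, scores, config.score_r_min, config.score_z_min)
        for cm in corr.values()
    ]
    ns = pd.concat(per_period, axis=1).max(axis=1)
    ns.name = "network_score"
    final["network_score"] = final["gene"].map(ns)
    dn = scores.set_index("gene")["dnlof"] if "dnlof" in scores.columns else None
    if dn is not None:
        final["dnlof"] = final["gene"].map(dn).fillna(0).astype(int)
    return PipelineResult(config, reps, final, ns, config.hash())
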