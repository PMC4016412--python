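"""Robustness validation: signal-removal cross-validation and dilution experiments.

Two probes of how the screen-and-clean calls depend on the genetic signal:

* validation scores — repeatedly null out the signal of a random 10% of the
  initially called genes, re-run screening and cleaning, and record how
  often each gene (when its own signal was retained) survives; genes
  surviving fewer than 90% of iterations are flagged non-robust.
* dilution experiments — at the node level, swap P values (mode I) or whole
  nodes (mode II) between a fraction l of signal nodes (P <= 0.1) and null
  nodes, re-fit the HMRF, and record how the number of detected
  dnLoF-carrying genes and the fitted clustering parameter c decay with l.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .fdr_clean import combine_representations
from .genetics import p_to_z, score_nodes
from .hmrf_screen import fit_hmrf
from .nodegraph import NodeGraph
from .pipeline import RunConfig, screen_clean_representation

__all__ = ["validation_scores", "dilution_experiment", "DILUTION_LEVELS"]

DILUTION_LEVELS = (0.2, 0.4, 0.6, 0.8, 1.0)


def _rerun(graphs: dict[str, NodeGraph], scores: pd.DataFrame, config: RunConfig) -> set[str]:
    """Screen + clean + combine; return the q <= threshold gene set."""
    tables = {
        rep_id: screen_clean_representation(graph, scores, config).q_table
        for rep_id, graph in graphs.items()
    }
    combined = combine_representations(tables, q_threshold=config.q_threshold)
    return set(combined.loc[combined["risk"], "gene"])


def validation_scores(
    graphs: dict[str, NodeGraph],
    scores: pd.DataFrame,
    config: RunConfig | None = None,
    *,
    frac_removed: float = 0.10,
    n_iter: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Fraction of signal-removal iterations in which each called gene survives.

    Per iteration a random ``frac_removed`` of the initially called genes
    has its P value replaced by a fresh Uniform(0,1) draw (the network is
    untouched) and the screen/clean stages are re-run.  A gene is scored
    only over iterations in which its own signal was retained.  Returns
    columns gene, score, n_retained, n_iter, robust (score >= 0.9).
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    if n_iter < 10:
        warnings.warn("n_iter < 10: validation scores will be unstable", stacklevel=2)
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    initial = sorted(_rerun(graphs, scores, config))
    if not initial:
        return pd.DataFrame(columns=["gene", "score", "n_retained", "n_iter", "robust"])
    present = {g: 0 for g in initial}
    retained_count = {g: 0 for g in initial}
    n_remove = max(1, round(frac_removed * len(initial)))
    base = scores.set_index("gene")
    for _ in range(n_iter):
        removed = set(rng.choice(initial, size=min(n_remove, len(initial)), replace=False))
        perturbed = base.copy()
        new_p = rng.uniform(size=len(removed))
        idx = sorted(removed)
        perturbed.loc[idx, "p"] = new_p
        perturbed.loc[idx, "z"] = p_to_z(new_p)
        updated = _rerun(graphs, perturbed.reset_index(), config)
        for g in initial:
            if g not in removed:
                retained_count[g] += 1
                if g in updated:
                    present[g] += 1
    rows = []
    for g in initial:
        n_ret = retained_count[g]
        score = present[g] / n_ret if n_ret else np.nan
        rows.append((g, score, n_ret, n_iter, bool(score >= 0.9) if n_ret else False))
    return pd.DataFrame(rows, columns=["gene", "score", "n_retained", "n_iter", "robust"])


def _diluted_node_table(
    node_scores: pd.DataFrame,
    graph: NodeGraph,
    mode: str,
    l: float,
    rng: np.random.Generator,
    p_split: float = 0.1,
) -> tuple[pd.DataFrame, list[tuple[str, ...]]]:
    """Swap node P values (mode I) or whole nodes (mode II) at dilution l."""
    p = node_scores["p_min"].to_numpy(dtype=float)
    signal = np.nonzero(np.nan_to_num(p, nan=1.0) <= p_split)[0]
    null = np.nonzero(np.nan_to_num(p, nan=1.0) > p_split)[0]
    n_swap = round(l * signal.size)
    if n_swap == 0:
        return node_scores.copy(), list(graph.nodes)
    if signal.size == 0:
        raise ValueError(f"no node with P <= {p_split} to dilute")
    if null.size < n_swap:
        raise ValueError(
            f"need {n_swap} nodes with P > {p_split} but only {null.size} available"
        )
    pick_sig = rng.choice(signal, size=n_swap, replace=False)
    pick_null = rng.choice(null, size=n_swap, replace=False)
    out = node_scores.copy()
    cols = ["p_min", "z", "scored"]
    tmp = out.loc[pick_sig, cols].to_numpy()
    out.loc[pick_sig, cols] = out.loc[pick_null, cols].to_numpy()
    out.loc[pick_null, cols] = tmp
    members = list(graph.nodes)
    if mode == "II":
        for a, b in zip(pick_sig, pick_null):
            members[a], members[b] = members[b], members[a]
    return out, members


def dilution_experiment(
    graph: NodeGraph,
    scores: pd.DataFrame,
    mode: str = "I",
    levels: tuple[float, ...] = DILUTION_LEVELS,
    n_rep: int = 20,
    seed: int = 0,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Node-level signal dilution followed by HMRF re-fitting.

    Mode "I" swaps P values between a fraction ``l`` of signal nodes
    (P <= 0.1) and an equal number of null nodes, separating small P values
    from their genes.  Mode "II" swaps the entire node (P value together
    with gene membership), destroying the co-location of signal in the
    network.  Each (l, replicate) records the number of screened-in genes
    carrying at least one dnLoF mutation and the fitted interaction
    parameter c.  ``l = 0`` reproduces the undiluted run exactly.

    Returns a long table (mode, l, rep, n_nasd, n_dnlof_detected, c_hat).
    """
    if mode not in {"I", "II"}:
        raise ValueError(f"mode must be 'I' or 'II', got {mode!r}")
    config = config or RunConfig()
    node_scores = score_nodes(graph, scores)
    dn = dict(zip(scores["gene"], scores.get("dnlof", pd.Series(dtype=int))))
    rng = np.random.default_rng(seed)
    rows = []
    for l in levels:
        if not 0 <= l <= 1:
            raise ValueError(f"dilution level must lie in [0, 1], got {l}")
        for rep in range(n_rep):
            diluted, members = _diluted_node_table(node_scores, graph, mode, l, rng)
            fit = fit_hmrf(
                graph, diluted, seed=seed, max_iter=config.max_iter,
                init_p_threshold=config.init_p_threshold,
            )
            called = [i for i, pp in enumerate(fit.posteriors)
                      if pp >= config.posterior_threshold]
            genes = {g for i in called for g in members[i]}
            n_dn = sum(1 for g in genes if dn.get(g, 0) >= 1)
            rows.append((mode, l, rep, len(genes), n_dn, fit.c))
    return pd.DataFrame(
        rows, columns=["mode", "l", "rep", "n_nasd", "n_dnlof_detected", "c_hat"]
    )
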