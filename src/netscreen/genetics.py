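"""Gene-level association scores: P -> Z conversion and node scoring.

The genetic input is a per-gene table of association P values (plus a
de novo loss-of-function count).  P values are mapped to Z-scores through
the standard normal quantile, Z = Phi^-1(1 - P), so null genes are N(0, 1)
and risk genes shift to positive mean.  A node inherits the minimum P over
its scored member genes.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .nodegraph import NodeGraph

logger = logging.getLogger(__name__)

#: smallest admissible P value; smaller inputs are clamped with a warning
P_FLOOR = 1e-16

__all__ = ["P_FLOOR", "p_to_z", "load_gene_scores", "save_gene_scores", "score_nodes"]


def p_to_z(p):
    """Z = Phi^-1(1 - P) for scalar or array P in (0, 1].

    P values below ``P_FLOOR`` are clamped to the floor (with a warning);
    P = 1 maps to Phi^-1(0) evaluated at the floor's complement, i.e. a
    large negative value rather than -inf.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("P values must lie in (0, 1]")
    if np.any(arr < P_FLOOR):
        warnings.warn(
            f"P value(s) below {P_FLOOR:g} clamped to the floor", stacklevel=2
        )
        arr = np.maximum(arr, P_FLOOR)
    arr = np.minimum(arr, 1.0 - 1e-16)
    z = norm.isf(arr)
    return float(z) if np.isscalar(p) or np.ndim(p) == 0 else z


def load_gene_scores(path: str) -> pd.DataFrame:
    """Read a gene score TSV with columns gene, tada_p, dnlof.

    Returns a DataFrame with columns ``gene``, ``p``, ``z``, ``dnlof``.
    Missing dnlof counts default to 0.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    gene_col = cols.get("gene")
    p_col = cols.get("tada_p") or cols.get("p") or cols.get("p_value")
    if gene_col is None or p_col is None:
        raise ValueError("score table needs 'gene' and 'tada_p' (or 'p') columns")
    out = pd.DataFrame({"gene": df[gene_col].astype(str), "p": df[p_col].astype(float)})
    if out["gene"].duplicated().any():
        dup = out.loc[out["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene in score table: {dup!r}")
    dn_col = cols.get("dnlof")
    out["dnlof"] = df[dn_col].fillna(0).astype(int) if dn_col else 0
    out["z"] = p_to_z(out["p"].to_numpy())
    return out


def save_gene_scores(scores: pd.DataFrame, path: str) -> None:
    scores.loc[:, ["gene", "p", "z", "dnlof"]].rename(
        columns={"p": "tada_p"}
    ).to_csv(path, sep="\t", index=False)


def score_nodes(g: NodeGraph, scores: pd.DataFrame) -> pd.DataFrame:
    """Per-node minimum P and corresponding Z-score.

    Genes absent from the score table are ignored in the minimum.  Nodes
    with no scored member at all stay in the network as null vertices
    (z = 0, ``scored`` False) so graph topology is preserved, but they
    carry no evidence of their own; each such node is logged.

    Returns a DataFrame indexed by node id with columns ``p_min``, ``z``,
    ``scored``, ``n_genes``.
    """
    p_of = dict(zip(scores["gene"], scores["p"]))
    rows = []
    for i, members in enumerate(g.nodes):
        ps = [p_of[m] for m in members if m in p_of]
        if ps:
            p_min = float(min(ps))
            rows.append((i, p_min, float(p_to_z(p_min)), True, len(members)))
        else:
            logger.info("node %d (%s) has no scored genes; treated as null", i, members)
            rows.append((i, np.nan, 0.0, False, len(members)))
    return pd.DataFrame(
        rows, columns=["node", "p_min", "z", "scored", "n_genes"]
    ).set_index("node")
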