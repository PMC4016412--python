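"""Cleaning stage: stratified Gaussian-mixture FDR over screened genes.

Screened genes are stratified: each large multi-gene node (more than ten
genes) forms its own stratum, everything else pools.  Within a stratum a
two-component mixture f(z) = pi0 * N(0,1) + pi1 * N(mu1, sigma1^2) is fit by
EM with the null component fixed, the local false discovery rate
lfdr(z) = pi0 * phi(z) / f(z) is evaluated, and the q-value is the
tail-averaged lfdr.  Final calls take the minimum q over the network
representations, optionally filtered by a robustness validation score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genetics import p_to_z
from .hmrf_screen import ScreenResult
from .nodegraph import NodeGraph

__all__ = [
    "MixtureFit",
    "fit_mixture",
    "local_fdr",
    "tail_q",
    "stratified_q",
    "combine_representations",
]

POOLED_STRATUM = "pooled"


@dataclass
class MixtureFit:
    """Two-group mixture with the null fixed at N(0, 1)."""

    pi0: float
    mu1: float
    sigma1: float
    loglik: float
    n: int
    degenerate: bool = False

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi0

    def density(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self.pi0 * norm.pdf(z) + self.pi1 * norm.pdf(z, self.mu1, self.sigma1)


def _em(z: np.ndarray, pi0: float, mu1: float, sigma1: float,
        mu_min: float, sigma_floor: float, tol: float, max_iter: int,
        ) -> tuple[float, float, float, float]:
    ll_prev = -np.inf
    for _ in range(max_iter):
        f0 = pi0 * norm.pdf(z)
        f1 = (1.0 - pi0) * norm.pdf(z, mu1, sigma1)
        total = f0 + f1
        total[total <= 0] = np.finfo(float).tiny
        ll = float(np.sum(np.log(total)))
        w1 = f1 / total
        w1sum = w1.sum()
        if w1sum < 1e-10:
            pi0 = 1.0
            break
        pi0 = float(np.clip(1.0 - w1sum / z.size, 1e-6, 1.0 - 1e-6))
        mu1 = max(float(np.sum(w1 * z) / w1sum), mu_min)
        var1 = float(np.sum(w1 * (z - mu1) ** 2) / w1sum)
        sigma1 = max(np.sqrt(max(var1, 0.0)), sigma_floor)
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            ll_prev = ll
            break
        ll_prev = ll
    return pi0, mu1, sigma1, ll_prev


def fit_mixture(
    z,
    seed: int = 0,
    n_restarts: int = 10,
    *,
    mu_min: float = 1.0,
    sigma_floor: float = 0.25,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureFit:
    """EM fit of pi0*N(0,1) + pi1*N(mu1, sigma1^2), multi-start and seeded.

    The alternative mean is constrained to ``mu_min`` or above: the
    alternative component models genuine positive signal, and without the
    constraint it drifts into the bulk of the null on signal-free data,
    deflating pi0.  Requires at least five scores.  A degenerate sample
    (all values equal) returns pi0 = 1 with a warning.
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 5:
        raise ValueError(f"need at least 5 scores to fit the mixture, got {z.size}")
    if np.ptp(z) == 0:
        warnings.warn("all z identical; returning degenerate pi0=1 fit", stacklevel=2)
        return MixtureFit(1.0, 1.0, 1.0, float("nan"), z.size, degenerate=True)
    rng = np.random.default_rng(seed)
    best: tuple[float, float, float, float] | None = None
    hi = max(z.max(), 0.5)
    for _ in range(n_restarts):
        pi0 = rng.uniform(0.3, 0.95)
        mu1 = rng.uniform(mu_min, max(hi, mu_min + 0.5))
        sigma1 = rng.uniform(0.5, 2.0)
        fit = _em(z, pi0, mu1, sigma1, mu_min, sigma_floor, tol, max_iter)
        if best is None or fit[3] > best[3]:
            best = fit
    pi0, mu1, sigma1, ll = best
    return MixtureFit(pi0, mu1, sigma1, ll, z.size)


def local_fdr(z, fit: MixtureFit) -> np.ndarray:
    """lfdr(z) = pi0 * phi(z) / f(z), clipped to [0, 1]."""
    z = np.asarray(z, dtype=float)
    if fit.degenerate or fit.pi0 >= 1.0:
        return np.ones_like(z)
    return np.clip(fit.pi0 * norm.pdf(z) / fit.density(z), 0.0, 1.0)


def tail_q(z: np.ndarray, lfdr: np.ndarray) -> np.ndarray:
    """Tail-averaged lfdr: q_i = mean lfdr over j in the stratum with z_j >= z_i."""
    z = np.asarray(z, dtype=float)
    lfdr = np.asarray(lfdr, dtype=float)
    order = np.argsort(-z, kind="stable")  # descending z
    csum = np.cumsum(lfdr[order])
    q_sorted = csum / np.arange(1, z.size + 1)
    # ties: every tied z gets the average over the full tied tail
    q = np.empty_like(q_sorted)
    zs = z[order]
    i = 0
    while i < zs.size:
        j = i
        while j + 1 < zs.size and zs[j + 1] == zs[i]:
            j += 1
        q[i : j + 1] = q_sorted[j]
        i = j + 1
    out = np.empty_like(q)
    out[order] = q
    return out


def stratified_q(
    screen: ScreenResult,
    g: NodeGraph,
    scores: pd.DataFrame,
    seed: int = 0,
    *,
    large_node_min_genes: int = 11,
) -> pd.DataFrame:
    """Per-gene q-values for one representation's screened gene set.

    Each screened multi-gene node with at least ``large_node_min_genes``
    members is its own stratum; remaining screened genes (singletons and
    small multi-gene nodes) share the pooled stratum.  Genes without a
    score are not assessable and are omitted.  A stratum whose mixture fit
    is unavailable (too few scores) falls back to the pooled fit.

    Returns columns ``gene``, ``node``, ``stratum``, ``z``, ``lfdr``, ``q``.
    """
    score_of = scores.set_index("gene")
    rows: list[tuple[str, int, str]] = []
    for node_id in screen.nasd_nodes:
        members = g.nodes[node_id]
        big = len(members) >= large_node_min_genes
        stratum = f"node{node_id}" if big else POOLED_STRATUM
        for gene in members:
            if gene in score_of.index:
                rows.append((gene, node_id, stratum))
    if not rows:
        return pd.DataFrame(columns=["gene", "node", "stratum", "z", "lfdr", "q"])
    df = pd.DataFrame(rows, columns=["gene", "node", "stratum"])
    df["z"] = score_of.loc[df["gene"], "z"].to_numpy(dtype=float)

    pooled_z = df.loc[df["stratum"] == POOLED_STRATUM, "z"].to_numpy()
    if pooled_z.size < 5:
        pooled_z = df["z"].to_numpy()
    try:
        pooled_fit = fit_mixture(pooled_z, seed=seed)
    except ValueError:
        pooled_fit = MixtureFit(1.0, 1.0, 1.0, float("nan"), pooled_z.size, True)

    df["lfdr"] = np.nan
    df["q"] = np.nan
    for stratum, sub in df.groupby("stratum"):
        zs = sub["z"].to_numpy()
        if stratum == POOLED_STRATUM:
            fit = pooled_fit
        else:
            try:
                fit = fit_mixture(zs, seed=seed)
            except ValueError:
                fit = pooled_fit
        lf = local_fdr(zs, fit)
        df.loc[sub.index, "lfdr"] = lf
        df.loc[sub.index, "q"] = tail_q(zs, lf)
    return df.reset_index(drop=True)


def combine_representations(
    tables: dict[str, pd.DataFrame],
    validation_scores: pd.DataFrame | None = None,
    *,
    q_threshold: float = 0.05,
    validation_threshold: float = 0.9,
) -> pd.DataFrame:
    """Minimum-q consensus across representations, with optional robustness filter.

    A gene's q_min is the smallest q over the representations in which it
    was screened.  It is a final risk call when q_min <= ``q_threshold``
    and, if ``validation_scores`` (columns gene, score) are supplied, its
    validation score is at least ``validation_threshold``; genes never
    scored by the validation procedure pass the filter unexamined.
    """
    if not tables:
        raise ValueError("need at least one representation table")
    per_rep = {}
    for rep, tab in tables.items():
        if len(tab):
            per_rep[rep] = tab.groupby("gene")["q"].min()
        else:
            per_rep[rep] = pd.Series(dtype=float)
    wide = pd.DataFrame(per_rep)
    wide.columns = [f"q_{rep}" for rep in tables]
    out = wide.reset_index().rename(columns={"index": "gene"})
    qcols = [c for c in out.columns if c.startswith("q_")]
    out["q_min"] = out[qcols].min(axis=1)
    out["risk"] = out["q_min"] <= q_threshold
    if validation_scores is not None and len(validation_scores):
        vs = validation_scores.set_index("gene")["score"]
        fails = out["gene"].map(vs).lt(validation_threshold).fillna(False)
        out["validation_score"] = out["gene"].map(vs)
        out.loc[fails, "risk"] = False
    return out.sort_values("q_min", kind="stable").reset_index(drop=True)
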