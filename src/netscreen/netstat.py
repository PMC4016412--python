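"""Network and enrichment statistics.

Contains the per-gene network score, the mutability-matched connectivity
permutation test, exact hypergeometric and Fisher tests (with the
conditional-MLE odds ratio), and the de novo occupancy extrapolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import nchypergeom_fisher

from .expr_io import CorrelationMatrix

__all__ = [
    "network_scores",
    "network_score",
    "connectivity_test",
    "hypergeom_tail",
    "fisher_exact",
    "DeNovoModel",
    "extrapolate_denovo",
    "prior_hit_probability",
]


# ---------------------------------------------------------------- network score

def network_scores(
    c: CorrelationMatrix,
    scores: pd.DataFrame,
    r_min: float = 0.7,
    z_min: float = 1.2,
) -> pd.Series:
    """S_i = sum_{j != i} |r_ij| * z_j with hard thresholds on both factors.

    A neighbor contributes only when |r_ij| >= ``r_min`` and z_j >= ``z_min``;
    otherwise its term is zero.  Genes without a score count as z below
    threshold.  Returns a Series indexed by gene.
    """
    z_of = dict(zip(scores["gene"], scores["z"]))
    zvec = np.array([z_of.get(g, 0.0) for g in c.gene_ids], dtype=float)
    zvec = np.where(zvec >= z_min, zvec, 0.0)
    a = c.abs_r()
    a = np.where(a >= r_min, a, 0.0)
    np.fill_diagonal(a, 0.0)
    return pd.Series(a @ zvec, index=c.gene_ids, name="network_score")


def network_score(gene: str, c: CorrelationMatrix, scores: pd.DataFrame,
                  r_min: float = 0.7, z_min: float = 1.2) -> float:
    """Network score for a single gene (see :func:`network_scores`)."""
    return float(network_scores(c, scores, r_min, z_min)[gene])


# ------------------------------------------------------------ connectivity test

def _within_list_connectivity(idx: np.ndarray, abs_r: np.ndarray, threshold: float) -> float:
    sub = abs_r[np.ix_(idx, idx)]
    partners = (sub > threshold).sum(axis=1) - (np.diag(sub) > threshold).astype(int)
    return float(partners.mean())


def connectivity_test(
    target: list[str],
    pool: pd.DataFrame,
    c: CorrelationMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    r_threshold: float = 0.7,
    n_bins: int = 10,
) -> dict:
    """Permutation P value for within-list co-expression connectivity.

    The statistic is the mean, over target genes, of the number of other
    target genes correlated at |r| > ``r_threshold``.  Null lists of the
    same size are drawn from ``pool`` (columns gene, mutability) matched on
    the target's mutability composition by quantile bins, so mutability
    cannot masquerade as connectivity.  P = (1 + #{null >= observed}) /
    (n_perm + 1).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    pool = pool.drop_duplicates("gene").reset_index(drop=True)
    missing = set(target) - set(pool["gene"])
    if missing:
        raise ValueError(f"target genes absent from pool: {sorted(missing)[:5]}")
    gene_idx = {g: i for i, g in enumerate(c.gene_ids)}
    if set(pool["gene"]) - set(gene_idx):
        raise ValueError("pool contains genes absent from the correlation matrix")
    bins = pd.qcut(pool["mutability"].rank(method="first"), n_bins, labels=False)
    pool = pool.assign(_bin=bins)
    bin_of = dict(zip(pool["gene"], pool["_bin"]))
    target_bins = pd.Series([bin_of[g] for g in target]).value_counts()
    by_bin = {b: sub["gene"].to_numpy() for b, sub in pool.groupby("_bin")}
    for b, need in target_bins.items():
        if len(by_bin[b]) < need:
            raise ValueError(f"mutability bin {b} too small for matched sampling")
    abs_r = c.abs_r()
    obs_idx = np.array([gene_idx[g] for g in target])
    observed = _within_list_connectivity(obs_idx, abs_r, r_threshold)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        draw: list[str] = []
        for b, need in target_bins.items():
            draw.extend(rng.choice(by_bin[b], size=need, replace=False))
        idx = np.array([gene_idx[g] for g in draw])
        null[k] = _within_list_connectivity(idx, abs_r, r_threshold)
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return {"observed": observed, "null_mean": float(null.mean()), "p": float(p),
            "n_perm": n_perm}


# ------------------------------------------------------------------ exact tests

def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeometric(N, K, n).

    Evaluated in rational arithmetic (sum of binomial products over the
    support) and returned as a float.
    """
    for name, v in [("N", N), ("K", K), ("n", n), ("k", k)]:
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if K > N or n > N or k > min(n, K):
        raise ValueError(f"inconsistent counts: N={N}, K={K}, n={n}, k={k}")
    total = math.comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(n, K) + 1):
        if n - x > N - K:
            continue
        acc += Fraction(math.comb(K, x) * math.comb(N - K, n - x), total)
    return float(acc)


def _conditional_mle_or(a: int, b: int, c: int, d: int) -> float:
    """Odds ratio maximizing the noncentral hypergeometric likelihood of cell a."""
    if b == 0 or c == 0:
        return math.inf
    if a == 0 or d == 0:
        return 0.0
    N, K, n = a + b + c + d, a + b, a + c

    def negll(log_or: float) -> float:
        return -float(nchypergeom_fisher.logpmf(a, N, K, n, math.exp(log_or)))

    res = minimize_scalar(negll, bounds=(-30.0, 30.0), method="bounded",
                          options={"xatol": 1e-10})
    return float(math.exp(res.x))


def fisher_exact(table, alternative: str = "greater") -> tuple[float, float]:
    """One-sided Fisher exact test with conditional-MLE odds ratio.

    ``table`` = [[a, b], [c, d]].  The P value is the exact hypergeometric
    upper tail on the fixed margins (alternative "greater": association in
    the direction of cell a).  The odds ratio is the conditional maximum
    likelihood estimate under the Fisher noncentral hypergeometric model —
    infinite (zero) when a zero off-diagonal (diagonal) cell forces it.
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    if a + b + c + d == 0:
        raise ValueError("contingency table is all zero")
    if alternative != "greater":
        raise ValueError("only the one-sided 'greater' alternative is supported")
    p = hypergeom_tail(a + b + c + d, a + b, a + c, a)
    return p, _conditional_mle_or(a, b, c, d)


# ------------------------------------------------------- de novo extrapolation

@dataclass
class DeNovoModel:
    """Observed de novo LoF occupancy in a trio cohort."""

    trios_obs: int
    events_obs: int
    unique_obs: int
    multi_obs: int
    single_obs: int

    def __post_init__(self) -> None:
        if self.single_obs + self.multi_obs != self.unique_obs:
            raise ValueError("single + multi must equal unique")
        if self.events_obs < self.unique_obs:
            raise ValueError("events must be >= unique genes hit")
        if min(self.trios_obs, self.events_obs) <= 0:
            raise ValueError("observed counts must be positive")


def _occupancy_curves(G: float, alpha: float, t: np.ndarray):
    """E[unique], E[multi] for t total events over G genes, gamma dispersion alpha."""
    m = t / G
    p0 = (alpha / (alpha + m)) ** alpha
    p1 = p0 * alpha * m / (alpha + m)
    return G * (1.0 - p0), G * (1.0 - p0 - p1)


def extrapolate_denovo(m: DeNovoModel, trios_target: int) -> dict:
    """Expected events / unique / multi / single genes at ``trios_target`` trios.

    Events scale linearly with trios.  Two gene-count estimators are
    returned: ``linear`` scales every observed count proportionally;
    ``occupancy`` fits a gamma-heterogeneous Poisson occupancy model
    (pool size and dispersion chosen by least squares against the observed
    unique/multi split, then anchored so the model passes exactly through
    the observed counts at the observed event total) and evaluates it at
    the scaled total.
    """
    if trios_target <= 0:
        raise ValueError("trios_target must be positive")
    ratio = trios_target / m.trios_obs
    events = m.events_obs * ratio
    linear = {
        "events": events,
        "unique": m.unique_obs * ratio,
        "multi": m.multi_obs * ratio,
        "single": m.single_obs * ratio,
    }

    t_obs = float(m.events_obs)

    # For each candidate dispersion, the pool size solving
    # E[unique](t_obs) = unique_obs is unique (E[unique] increases in G);
    # pick the dispersion whose implied multi count is closest to the
    # observed one.  Gamma mixing can only overdisperse, so when the data
    # are underdispersed the grid settles at the (near-)Poisson end.
    def g_for_alpha(alpha: float) -> float:
        def f(log_g: float) -> float:
            u, _ = _occupancy_curves(math.exp(log_g), alpha, np.array([t_obs]))
            return u[0] - m.unique_obs
        lo, hi = math.log(m.unique_obs), 25.0
        if f(lo) > 0:
            return m.unique_obs
        return math.exp(brentq(f, lo, hi, xtol=1e-12))

    best: tuple[float, float, float] | None = None
    for alpha in np.logspace(-2, 6, 81):
        G = g_for_alpha(alpha)
        _, ml = _occupancy_curves(G, alpha, np.array([t_obs]))
        err = abs(ml[0] - m.multi_obs)
        if best is None or err < best[0]:
            best = (err, G, alpha)
    _, G, alpha = best
    u_curve, m_curve = _occupancy_curves(G, alpha, np.array([t_obs, events]))
    # anchor: pass exactly through the observed split at t_obs
    unique = m.unique_obs * u_curve[1] / u_curve[0]
    multi = m.multi_obs * (m_curve[1] / m_curve[0] if m_curve[0] > 0 else ratio)
    unique = min(unique, events)
    multi = min(multi, unique)
    occupancy = {
        "events": events,
        "unique": unique,
        "multi": multi,
        "single": unique - multi,
    }
    if trios_target == m.trios_obs:
        occupancy = {
            "events": float(m.events_obs), "unique": float(m.unique_obs),
            "multi": float(m.multi_obs), "single": float(m.single_obs),
        }
    return {"trios_target": trios_target, "linear": linear, "occupancy": occupancy,
            "pool_size": float(G), "dispersion": float(alpha)}


def prior_hit_probability(true_gene_hits: int, n_true_genes: int) -> float:
    """A priori chance a true risk gene is hit: hits / pool size."""
    if n_true_genes <= 0:
        raise ValueError("n_true_genes must be positive")
    if true_gene_hits < 0 or true_gene_hits > n_true_genes:
        raise ValueError("true_gene_hits must lie in [0, n_true_genes]")
    return true_gene_hits / n_true_genes
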