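import numpy as np
import pandas as pd
import pytest

from netscreen.fdr_clean import (
    MixtureFit,
    combine_representations,
    fit_mixture,
    local_fdr,
    stratified_q,
    tail_q,
)
from netscreen.genetics import p_to_z
from netscreen.hmrf_screen import ScreenResult
from netscreen.nodegraph import NodeGraph


class TestFitMixture:
    def test_null_pi0_high(self):
        for seed in range(20):
            z = np.random.default_rng(seed).standard_normal(10_000)
            assert fit_mixture(z, seed=seed).pi0 >= 0.95

    def test_known_mixture_recovery(self):
        rng = np.random.default_rng(42)
        z = np.concatenate([rng.standard_normal(7000), rng.normal(3, 1, 3000)])
        fit = fit_mixture(z, seed=1)
        assert 0.65 <= fit.pi0 <= 0.75
        assert 2.8 <= fit.mu1 <= 3.2

    def test_degenerate_identical(self):
        with pytest.warns(UserWarning, match="identical"):
            fit = fit_mixture(np.full(10, 1.3))
        assert fit.pi0 == 1.0 and fit.degenerate

    def test_too_few_scores(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_mixture([1.0, 2.0, 3.0])

    def test_seeded_determinism(self):
        z = np.random.default_rng(3).standard_normal(500)
        f1, f2 = fit_mixture(z, seed=9), fit_mixture(z, seed=9)
        assert (f1.pi0, f1.mu1, f1.sigma1) == (f2.pi0, f2.mu1, f2.sigma1)


class TestLocalFdrAndTailQ:
    def test_lfdr_bounds_and_monotone(self):
        fit = MixtureFit(0.7, 3.0, 1.0, 0.0, 100)
        z = np.linspace(-2, 6, 50)
        lf = local_fdr(z, fit)
        assert lf.min() >= 0 and lf.max() <= 1
        assert np.all(np.diff(lf[25:]) <= 1e-12)  # decreasing in the right tail

    def test_tail_q_is_tail_mean(self):
        z = np.array([3.0, 1.0, 2.0])
        lf = np.array([0.1, 0.9, 0.5])
        q = tail_q(z, lf)
        assert q[0] == pytest.approx(0.1)
        assert q[2] == pytest.approx((0.1 + 0.5) / 2)
        assert q[1] == pytest.approx((0.1 + 0.5 + 0.9) / 3)

    def test_q_monotone_in_z(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=200)
        fit = MixtureFit(0.8, 2.5, 1.0, 0.0, 200)
        q = tail_q(z, local_fdr(z, fit))
        order = np.argsort(z)
        assert np.all(np.diff(q[order]) <= 1e-12)


def build_screen(node_defs, p_of):
    """node_defs: list of gene tuples; all nodes screened in."""
    g = NodeGraph([tuple(nd) for nd in node_defs])
    genes = [gene for nd in node_defs for gene in nd]
    p = np.array([p_of[gene] for gene in genes])
    scores = pd.DataFrame({"gene": genes, "p": p, "z": p_to_z(p), "dnlof": 0})
    screen = ScreenResult(list(range(len(node_defs))), genes)
    return g, scores, screen


class TestStratifiedQ:
    def test_null_stratum_no_calls(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(30)]
        p_of = {g: p for g, p in zip(genes, rng.uniform(0.3, 1.0, 30))}
        g, scores, screen = build_screen([tuple(genes)], p_of)
        q = stratified_q(screen, g, scores, seed=0)
        assert (q["q"] > 0.05).all()

    def test_dense_signal_stratum_called(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(20)]
        p_of = {}
        for i, gene in enumerate(genes):
            if i < 10:
                p_of[gene] = float(np.clip(1 - __import__("scipy.stats", fromlist=["norm"]).norm.cdf(rng.normal(4, 0.5)), 1e-12, 1))
            else:
                p_of[gene] = float(rng.uniform(0.2, 1.0))
        g, scores, screen = build_screen([tuple(genes)], p_of)
        q = stratified_q(screen, g, scores, seed=0)
        strong = q[q["gene"].isin(genes[:10])]
        assert (strong["q"] <= 0.05).all()

    def test_gene_not_screened_absent(self):
        p_of = {"a": 0.01, "b": 0.02, "c": 0.5, "d": 0.6, "e": 0.7, "f": 0.01}
        g, scores, _ = build_screen([("a",), ("b",), ("c",), ("d",), ("e",), ("f",)], p_of)
        screen = ScreenResult([0, 1, 2, 3, 4], ["a", "b", "c", "d", "e"])
        q = stratified_q(screen, g, scores, seed=0)
        assert "f" not in set(q["gene"])

    def test_small_node_goes_to_pooled_stratum(self):
        rng = np.random.default_rng(3)
        small = [f"s{i}" for i in range(5)]
        singles = [f"x{i}" for i in range(10)]
        p_of = {g: rng.uniform(0.01, 1) for g in small + singles}
        g, scores, screen = build_screen([tuple(small)] + [(s,) for s in singles], p_of)
        q = stratified_q(screen, g, scores, seed=0)
        assert set(q.loc[q["gene"].isin(small), "stratum"]) == {"pooled"}

    def test_large_node_is_own_stratum(self):
        rng = np.random.default_rng(4)
        big = [f"b{i}" for i in range(12)]
        singles = [f"x{i}" for i in range(8)]
        p_of = {g: rng.uniform(0.01, 1) for g in big + singles}
        g, scores, screen = build_screen([tuple(big)] + [(s,) for s in singles], p_of)
        q = stratified_q(screen, g, scores, seed=0)
        strata = set(q.loc[q["gene"].isin(big), "stratum"])
        assert strata == {"node0"}

    def test_stratification_gains_power(self):
        # one dense-signal large node + diffuse null background:
        # stratified calling recovers at least as many planted genes as a
        # pooled-only analysis (paired over seeds)
        from scipy.stats import norm

        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            hot = [f"h{i}" for i in range(15)]
            cold = [f"c{i}" for i in range(60)]
            p_of = {}
            for i, gene in enumerate(hot):
                p_of[gene] = float(np.clip(norm.sf(rng.normal(3.0, 1.0)), 1e-12, 1)) if i < 10 \
                    else float(rng.uniform())
            for gene in cold:
                p_of[gene] = float(rng.uniform())
            g, scores, screen = build_screen(
                [tuple(hot)] + [(c,) for c in cold], p_of)
            q_strat = stratified_q(screen, g, scores, seed=seed)
            planted = set(hot[:10])
            n_strat = int(((q_strat["q"] <= 0.05) & q_strat["gene"].isin(planted)).sum())
            # pooled-only: collapse the big node into singletons
            g2, scores2, screen2 = build_screen(
                [(h,) for h in hot] + [(c,) for c in cold], p_of)
            q_pool = stratified_q(screen2, g2, scores2, seed=seed)
            n_pool = int(((q_pool["q"] <= 0.05) & q_pool["gene"].isin(planted)).sum())
            wins += n_strat >= n_pool
        assert wins >= 15  # stratification at least as powerful in most runs


class TestCombineRepresentations:
    def test_min_q(self):
        tabs = {
            f"r{i}": pd.DataFrame({"gene": ["A"], "q": [qv], "z": [1.0],
                                   "node": [0], "stratum": ["pooled"], "lfdr": [qv]})
            for i, qv in enumerate([0.2, 0.04, 0.8, 0.6])
        }
        out = combine_representations(tabs)
        assert out.loc[0, "q_min"] == pytest.approx(0.04)
        assert bool(out.loc[0, "risk"])

    def test_validation_filter_excludes(self):
        tabs = {"r0": pd.DataFrame({"gene": ["A", "B"], "q": [0.04, 0.03],
                                    "z": [2.0, 2.1], "node": [0, 1],
                                    "stratum": ["pooled"] * 2, "lfdr": [0.0, 0.0]})}
        vs = pd.DataFrame({"gene": ["A"], "score": [0.5]})
        out = combine_representations(tabs, validation_scores=vs).set_index("gene")
        assert not bool(out.loc["A", "risk"])  # non-robust
        assert bool(out.loc["B", "risk"])      # never scored -> passes

    def test_absent_gene_absent(self):
        tabs = {"r0": pd.DataFrame({"gene": ["A"], "q": [0.04], "z": [2.0],
                                    "node": [0], "stratum": ["pooled"], "lfdr": [0.0]})}
        out = combine_representations(tabs)
        assert set(out["gene"]) == {"A"}

    def test_empty_tables_rejected(self):
        with pytest.raises(ValueError):
            combine_representations({})
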