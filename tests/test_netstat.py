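import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom, kstest

from netscreen.netstat import (
    DeNovoModel,
    connectivity_test,
    extrapolate_denovo,
    fisher_exact,
    hypergeom_tail,
    network_score,
    network_scores,
    prior_hit_probability,
)


def brute_hypergeom_tail(N, K, n, k):
    """Oracle: direct rational sum over the support."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(n, K) + 1):
        if 0 <= n - x <= N - K:
            acc += Fraction(math.comb(K, x) * math.comb(N - K, n - x), total)
    return acc


class TestNetworkScore:
    def test_three_neighbor_example(self, corr_from_matrix, gene_scores):
        r = np.eye(4)
        r[0, 1] = r[1, 0] = 0.9
        r[0, 2] = r[2, 0] = 0.5
        r[0, 3] = r[3, 0] = 0.8
        c = corr_from_matrix(r, ["i", "a", "b", "d"])
        from netscreen.genetics import p_to_z
        from scipy.stats import norm

        z_of = {"a": 2.0, "b": 5.0, "d": 1.0, "i": 0.0}
        scores = pd.DataFrame({
            "gene": list(z_of), "z": list(z_of.values()),
            "p": [float(norm.sf(v)) for v in z_of.values()], "dnlof": 0,
        })
        # only 'a' passes both thresholds: S = 0.9 * 2.0
        assert network_score("i", c, scores) == pytest.approx(1.8)

    def test_no_qualifying_neighbor_zero(self, corr_from_matrix, gene_scores):
        c = corr_from_matrix(np.eye(3), ["a", "b", "c"])
        s = gene_scores({"a": 0.5, "b": 0.5, "c": 0.5})
        assert network_scores(c, s).max() == 0.0

    def test_all_z_below_threshold_zero(self, corr_from_matrix):
        r = np.full((3, 3), 0.95)
        np.fill_diagonal(r, 1.0)
        c = corr_from_matrix(r, ["a", "b", "c"])
        scores = pd.DataFrame({"gene": ["a", "b", "c"], "z": [1.0, 1.1, 0.5],
                               "p": [0.2] * 3, "dnlof": 0})
        assert network_scores(c, scores).max() == 0.0

    def test_additive_and_order_invariant(self, corr_from_matrix):
        rng = np.random.default_rng(0)
        r = rng.uniform(-1, 1, (8, 8))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        genes = [f"g{i}" for i in range(8)]
        c = corr_from_matrix(r, genes)
        z = rng.uniform(0, 4, 8)
        scores = pd.DataFrame({"gene": genes, "z": z, "p": [0.1] * 8, "dnlof": 0})
        s1 = network_scores(c, scores)
        # manual additive oracle
        for i, gi in enumerate(genes):
            expected = sum(
                abs(r[i, j]) * z[j]
                for j in range(8)
                if j != i and abs(r[i, j]) >= 0.7 and z[j] >= 1.2
            )
            assert s1[gi] == pytest.approx(expected, abs=1e-12)
        # permuting input rows does not change per-gene scores
        perm = rng.permutation(8)
        c2 = corr_from_matrix(r[np.ix_(perm, perm)], [genes[i] for i in perm])
        s2 = network_scores(c2, scores)
        for gi in genes:
            assert s2[gi] == pytest.approx(s1[gi], abs=1e-12)


class TestHypergeomTail:
    def test_printed_enrichment_value(self):
        p = hypergeom_tail(44, 10, 8, 6)
        assert p == pytest.approx(0.0007, abs=5e-5)
        assert p == pytest.approx(121935 / 177232627, rel=1e-12)

    def test_k_zero_is_one(self):
        assert hypergeom_tail(50, 10, 5, 0) == 1.0

    def test_inconsistent_counts(self):
        with pytest.raises(ValueError):
            hypergeom_tail(10, 12, 5, 1)
        with pytest.raises(ValueError):
            hypergeom_tail(10, 5, 5, 6)

    @given(
        N=st.integers(1, 60),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_bruteforce_and_scipy(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(n, K)))
        mine = hypergeom_tail(N, K, n, k)
        assert mine == pytest.approx(float(brute_hypergeom_tail(N, K, n, k)), abs=1e-12)
        assert mine == pytest.approx(hypergeom.sf(k - 1, N, K, n), abs=1e-9)


class TestFisherExact:
    def test_no_prior_dnlof_table(self):
        p, oratio = fisher_exact([[2, 0], [1, 25]])
        assert p == pytest.approx(0.008, abs=5e-4)
        assert math.isinf(oratio)

    def test_prior_dnlof_table(self):
        p, oratio = fisher_exact([[4, 4], [1, 7]])
        assert p == pytest.approx(0.14, abs=5e-3)
        assert oratio == pytest.approx(6.16, abs=5e-3)

    def test_unit_table_enumeration(self):
        # all tables with margins (2,2)/(2,2): P(a>=1) = 1 - P(a=0) = 1 - 1/6
        p, _ = fisher_exact([[1, 1], [1, 1]])
        assert p == pytest.approx(5 / 6, abs=1e-12)

    def test_zero_cell_reduces_to_hypergeom(self):
        for table in ([[3, 0], [2, 5]], [[2, 0], [4, 4]]):
            (a, b), (c, d) = table
            p, _ = fisher_exact(table)
            assert p == pytest.approx(hypergeom_tail(a + b + c + d, a + b, a + c, a),
                                      abs=1e-12)

    def test_cmle_matches_scipy(self):
        from scipy.stats.contingency import odds_ratio

        for table in ([[4, 4], [1, 7]], [[5, 3], [2, 8]], [[1, 9], [3, 7]]):
            _, mine = fisher_exact(table)
            ref = odds_ratio(table, kind="conditional").statistic
            assert mine == pytest.approx(ref, rel=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [0, 0]])


class TestConnectivity:
    def test_planted_cluster_significant(self, two_block_corr):
        c, _ = two_block_corr
        rng = np.random.default_rng(9)
        pool = pd.DataFrame({"gene": c.gene_ids,
                             "mutability": rng.uniform(size=len(c.gene_ids))})
        res = connectivity_test(c.gene_ids[:40], pool, c, n_perm=999, seed=3)
        assert res["p"] <= 0.01

    def test_null_target_uniform_p(self, two_block_corr):
        c, _ = two_block_corr
        rng = np.random.default_rng(10)
        pool = pd.DataFrame({"gene": c.gene_ids,
                             "mutability": rng.uniform(size=len(c.gene_ids))})
        ps = []
        for k in range(50):
            tgt = list(rng.choice(c.gene_ids, 20, replace=False))
            ps.append(connectivity_test(tgt, pool, c, n_perm=49, seed=k)["p"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_zero_permutations_rejected(self, two_block_corr):
        c, _ = two_block_corr
        pool = pd.DataFrame({"gene": c.gene_ids, "mutability": 1.0})
        with pytest.raises(ValueError):
            connectivity_test(c.gene_ids[:5], pool, c, n_perm=0)


class TestDeNovo:
    MODEL = DeNovoModel(1043, 143, 130, 9, 121)

    def test_linear_event_scaling(self):
        out = extrapolate_denovo(self.MODEL, 2500)
        assert out["linear"]["events"] == pytest.approx(143 * 2500 / 1043)
        assert out["linear"]["events"] == pytest.approx(342.8, abs=0.05)

    def test_identity_at_observed(self):
        out = extrapolate_denovo(self.MODEL, 1043)["occupancy"]
        assert out == {"events": 143.0, "unique": 130.0, "multi": 9.0, "single": 121.0}

    def test_occupancy_structure(self):
        out = extrapolate_denovo(self.MODEL, 2500)["occupancy"]
        assert out["unique"] <= out["events"]
        assert out["multi"] + out["single"] == pytest.approx(out["unique"])
        assert out["multi"] >= 0

    def test_monotone_in_target(self):
        uniq = [extrapolate_denovo(self.MODEL, t)["occupancy"]["unique"]
                for t in (1100, 1500, 2500, 4000)]
        assert np.all(np.diff(uniq) > 0)

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_denovo(self.MODEL, 0)

    def test_inconsistent_model_rejected(self):
        with pytest.raises(ValueError):
            DeNovoModel(1043, 143, 130, 10, 121)
        with pytest.raises(ValueError):
            DeNovoModel(1043, 100, 130, 9, 121)

    def test_prior_hit_probability(self):
        assert prior_hit_probability(162, 1000) == pytest.approx(0.162)
        assert 0.15 <= prior_hit_probability(155, 1000) <= 0.16
        with pytest.raises(ValueError):
            prior_hit_probability(5, 0)
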