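import numpy as np
import pandas as pd
import pytest

from netscreen.expr_io import ExpressionMatrix, pearson_correlation
from netscreen.synthdata import generate_expression, node_level_scenario, plant_genetic_signal


@pytest.fixture
def tiny_expr(tmp_path):
    """3-gene x 4-replicate TSV fixture on disk."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene\tS1\tS2\tS3\tS4\n"
        "GA\t1.0\t2.0\t3.0\t4.0\n"
        "GB\t2.0\t4.0\t6.0\t8.0\n"
        "GC\t4.0\t3.0\t2.0\t1.0\n"
    )
    return path


@pytest.fixture
def two_block_expr():
    """Two well-separated 40-gene blocks plus 20 noise genes."""
    x, truth = generate_expression(100, [(40, 0.9), (40, 0.9)], 80, seed=7)
    return x, truth


@pytest.fixture
def two_block_corr(two_block_expr):
    x, truth = two_block_expr
    return pearson_correlation(x), truth


@pytest.fixture
def small_scenario():
    """400-gene expression scenario with planted within-block signal."""
    x, truth = generate_expression(400, [(40, 0.72)] * 6, 100, seed=3)
    scores = plant_genetic_signal(truth, 0.08, 3.0, "within-block", seed=4)
    return x, scores, truth


@pytest.fixture
def node_scenario():
    """Community node graph with clustered risk signal (dilution test bed)."""
    return node_level_scenario(seed=0)


@pytest.fixture
def corr_from_matrix():
    """Helper: wrap an explicit correlation matrix."""
    from netscreen.expr_io import CorrelationMatrix

    def make(r, genes=None):
        r = np.asarray(r, dtype=float)
        genes = genes or [f"g{i}" for i in range(r.shape[0])]
        return CorrelationMatrix(genes, r)

    return make


@pytest.fixture
def gene_scores():
    """Helper: build a score table from gene -> p mapping."""
    from netscreen.genetics import p_to_z

    def make(p_of, dnlof=None):
        genes = list(p_of)
        p = np.array([p_of[g] for g in genes], dtype=float)
        return pd.DataFrame({
            "gene": genes,
            "p": p,
            "z": p_to_z(p),
            "dnlof": [0 if dnlof is None else dnlof.get(g, 0) for g in genes],
        })

    return make
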