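"""Expression matrix I/O and pairwise Pearson correlation.

Expression data arrive as a tab-separated matrix: first column gene symbol,
header row of replicate labels, one row per gene.  The matrix is assumed to
be already quality-controlled and normalized upstream; this module only
parses it and computes gene-gene correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CorrelationMatrix",
    "load_expression",
    "save_expression",
    "pearson_correlation",
]


@dataclass
class ExpressionMatrix:
    """Genes x replicates continuous expression values.

    ``values`` is a float array of shape ``(len(gene_ids), len(replicate_ids))``
    with missing cells stored as NaN.  Every gene must have at least three
    non-missing replicates so that a correlation can in principle be computed.
    """

    gene_ids: list[str]
    values: np.ndarray
    replicate_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.replicate_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.replicate_ids)} replicates"
            )
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise ValueError(f"duplicate gene symbol: {g!r}")
            seen.add(g)
        n_ok = np.sum(~np.isnan(self.values), axis=1)
        bad = np.nonzero(n_ok < 3)[0]
        if bad.size:
            raise ValueError(
                f"gene {self.gene_ids[bad[0]]!r} has fewer than 3 non-missing values"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.replicate_ids)


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation over genes.

    ``r`` has unit diagonal and entries in [-1, 1].  Pairs with fewer than
    three complete observations are unrecoverable and stored as NaN; their
    indices are listed in ``missing_pairs``.  Genes with zero variance are
    listed in ``constant_genes`` and correlate 0 with everything.
    """

    gene_ids: list[str]
    r: np.ndarray
    constant_genes: list[str] = field(default_factory=list)
    missing_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.gene_ids)
        if self.r.shape != (n, n):
            raise ValueError("r must be square over gene_ids")
        if not np.allclose(self.r, self.r.T, equal_nan=True):
            raise ValueError("r must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0):
            raise ValueError("diagonal of r must be 1")
        finite = self.r[np.isfinite(self.r)]
        if finite.size and (finite.min() < -1 - 1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, gene: str) -> int:
        return self.gene_ids.index(gene)

    def abs_r(self, fill_missing: float = 0.0) -> np.ndarray:
        """|r| with NaN pairs replaced (missing evidence => unconnected)."""
        a = np.abs(self.r)
        a[~np.isfinite(a)] = fill_missing
        return a


def load_expression(path: str) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    First column: gene symbol.  Header row: replicate labels.  Empty cells
    and the token ``NA`` are treated as missing.  Duplicate gene symbols and
    non-numeric cells raise ``ValueError`` naming the offender.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    genes = [str(g) for g in df.index]
    dup = pd.Index(genes).duplicated()
    if dup.any():
        raise ValueError(f"duplicate gene symbol: {genes[int(np.argmax(dup))]!r}")
    values = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            s = cell.strip()
            if s == "" or s.upper() in {"NA", "NAN"}:
                continue
            try:
                values[i, j] = float(s)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric cell at gene {genes[i]!r}, replicate {col!r}: {s!r}"
                ) from exc
    return ExpressionMatrix(genes, values, [str(c) for c in df.columns])


def save_expression(x: ExpressionMatrix, path: str) -> None:
    x.to_frame().to_csv(path, sep="\t", index_label="gene", na_rep="NA")


def pearson_correlation(x: ExpressionMatrix, min_periods: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation between gene rows.

    Each pair is correlated over the replicates where both genes are
    observed.  Constant rows get r = 0 against everything (so downstream
    |r| thresholding treats them as unconnected) and are flagged with a
    warning.  Pairs with fewer than ``min_periods`` complete observations
    are stored as NaN and reported in ``missing_pairs``.
    """
    vals = x.values
    if np.isnan(vals).any():
        r = x.to_frame().T.corr(min_periods=min_periods).to_numpy()
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(vals)
    sd = np.nanstd(vals, axis=1)
    constant = np.nonzero(sd == 0)[0]
    constant_genes = [x.gene_ids[i] for i in constant]
    if constant_genes:
        warnings.warn(
            f"{len(constant_genes)} constant gene row(s) set to r=0: "
            f"{constant_genes[:5]}",
            stacklevel=2,
        )
        r[constant, :] = 0.0
        r[:, constant] = 0.0
    missing_pairs: list[tuple[str, str]] = []
    nan_i, nan_j = np.nonzero(np.triu(~np.isfinite(r), k=1))
    for i, j in zip(nan_i, nan_j):
        missing_pairs.append((x.gene_ids[i], x.gene_ids[j]))
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    # clip does not touch NaN; restore exact symmetry after clipping
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(list(x.gene_ids), r, constant_genes, missing_pairs)
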