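"""Pairwise Pearson correlation, directional rank matrices, and mutual rank.

The mutual rank (MR) of a gene pair is the geometric mean of the two
directional correlation ranks,

    MR(AB) = sqrt(Rank(AB) * Rank(BA)),

where Rank(AB) is the position of B when A's partners are sorted by their
correlation with A. A low MR means the two genes are reciprocally among each
other's strongest partners, which is a far more selective signal than the
raw correlation alone. Two rank directions are supported: descending
correlation (positive networks) and ascending correlation (negative
networks), so that strongly anti-correlated pairs can also attain small
mutual ranks on the negative side.

Correlation is computed on TPM values as-is by default; an optional
``log_transform`` flag applies log2(TPM + 1) first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .io import MIN_SAMPLES, ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "RankMatrix",
    "MutualRankMatrix",
    "pearson_matrix",
    "rank_matrix",
    "mutual_rank",
    "topk_partners",
    "write_long_format",
]

DESCENDING = "descending_pcc"
ASCENDING = "ascending_pcc"


@dataclass
class CorrelationMatrix:
    """Symmetric G x G Pearson correlation matrix.

    ``defined[i, j]`` is False (and ``values[i, j]`` NaN) when either gene
    has zero variance across samples; the diagonal is 1 for defined genes.
    """

    gene_ids: list[str]
    values: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        g = len(self.gene_ids)
        if self.values.shape != (g, g) or self.defined.shape != (g, g):
            raise DataError("correlation matrix shape mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(gene_id) from None


@dataclass
class RankMatrix:
    """Directional rank matrix: ranks[a, b] = position of b in a's sorted
    partner list (1-based). 0 marks undefined entries (diagonal, or partners
    with undefined correlation)."""

    gene_ids: list[str]
    ranks: np.ndarray
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (DESCENDING, ASCENDING):
            raise ValueError(f"unknown rank direction: {self.direction!r}")


@dataclass
class MutualRankMatrix:
    """Symmetric MR(AB) = sqrt(Rank(AB) * Rank(BA)); NaN where undefined."""

    gene_ids: list[str]
    values: np.ndarray
    direction: str


def _log2p1(values: np.ndarray) -> np.ndarray:
    return np.log2(values + 1.0)


def pearson_matrix(expr: ExpressionMatrix, log_transform: bool = False) -> CorrelationMatrix:
    """Pearson correlation between every pair of gene expression profiles.

    Parameters
    ----------
    expr
        Expression matrix with at least 3 samples.
    log_transform
        Apply log2(TPM + 1) before correlating (off by default: the
        correlation is defined directly on TPM values).

    Zero-variance genes yield undefined entries (NaN, ``defined`` False)
    rather than a numeric placeholder.
    """
    if expr.n_samples < MIN_SAMPLES:
        raise DataError(
            f"correlation requires at least {MIN_SAMPLES} samples, "
            f"got {expr.n_samples}"
        )
    x = expr.values.astype(float)
    if not np.all(np.isfinite(x)):
        raise DataError("expression values must be finite")
    if log_transform:
        x = _log2p1(x)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    nonzero = norms > 0
    safe = np.where(nonzero, norms, 1.0)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr = (corr + corr.T) / 2.0  # enforce exact symmetry
    np.clip(corr, -1.0, 1.0, out=corr)  # absorb rounding only
    defined = np.outer(nonzero, nonzero)
    corr[~defined] = np.nan
    idx = np.where(nonzero)[0]
    corr[idx, idx] = 1.0
    return CorrelationMatrix(list(expr.gene_ids), corr, defined)


def _lexicographic_order(gene_ids: list[str]) -> np.ndarray:
    """lex[i] = rank of gene_ids[i] in lexicographic id order."""
    order = np.argsort(np.array(gene_ids, dtype=object))
    lex = np.empty(len(gene_ids), dtype=int)
    lex[order] = np.arange(len(gene_ids))
    return lex


def rank_matrix(corr: CorrelationMatrix, direction: str = DESCENDING) -> RankMatrix:
    """Rank each gene's partners by correlation.

    ``descending_pcc`` puts the most positively correlated partner at rank 1
    (positive networks); ``ascending_pcc`` puts the most negatively
    correlated partner at rank 1 (negative networks). Self and undefined
    partners are excluded; ties are broken lexicographically by partner id
    so outputs are bit-reproducible.
    """
    if direction not in (DESCENDING, ASCENDING):
        raise ValueError(f"unknown rank direction: {direction!r}")
    g = corr.n_genes
    lex = _lexicographic_order(corr.gene_ids)
    ranks = np.zeros((g, g), dtype=int)
    for i in range(g):
        valid = corr.defined[i].copy()
        valid[i] = False
        partners = np.where(valid)[0]
        if partners.size == 0:
            continue
        vals = corr.values[i, partners]
        key = -vals if direction == DESCENDING else vals
        # primary: correlation in requested direction; secondary: id order
        order = partners[np.lexsort((lex[partners], key))]
        ranks[i, order] = np.arange(1, order.size + 1)
    return RankMatrix(list(corr.gene_ids), ranks, direction)


def mutual_rank(ranks: RankMatrix) -> MutualRankMatrix:
    """Geometric mean of the two directional ranks, symmetric by construction."""
    r = ranks.ranks.astype(float)
    both = (ranks.ranks > 0) & (ranks.ranks.T > 0)
    mr = np.full(r.shape, np.nan)
    mr[both] = np.sqrt(r[both] * r.T[both])
    return MutualRankMatrix(list(ranks.gene_ids), mr, ranks.direction)


def topk_partners(
    corr: CorrelationMatrix, k: int
) -> dict[str, list[tuple[str, float]]]:
    """Each gene's k highest-correlation partners (descending, ties by id).

    Fewer than k partners are returned when fewer defined partners exist.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    lex = _lexicographic_order(corr.gene_ids)
    out: dict[str, list[tuple[str, float]]] = {}
    for i, gid in enumerate(corr.gene_ids):
        valid = corr.defined[i].copy()
        valid[i] = False
        partners = np.where(valid)[0]
        vals = corr.values[i, partners]
        order = partners[np.lexsort((lex[partners], -vals))][:k]
        out[gid] = [(corr.gene_ids[j], float(corr.values[i, j])) for j in order]
    return out


def write_long_format(matrix, path) -> None:
    """Write a symmetric gene-pair matrix as long-format TSV
    (gene_a, gene_b, value) with gene_a < gene_b; undefined pairs omitted."""
    ids = matrix.gene_ids
    vals = matrix.values
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tvalue\n")
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                v = vals[i, j]
                if np.isnan(v):
                    continue
                a, b = sorted((ids[i], ids[j]))
                fh.write(f"{a}\t{b}\t{float(v)!r}\n")
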