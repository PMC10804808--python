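"""Threshold calibration against prior gene sets via ROC/AUC.

The operating thresholds of the coexpression network (a correlation cut and
a mutual-rank cut) are chosen by benchmarking candidate threshold pairs
against functional co-annotation. Terms with a modest number of annotated
genes (4-20 by default, typically GO biological-process terms) form the
*prior gene sets*; gene pairs that share at least one prior term are the
positive class, pairs of annotated genes sharing none are the negative
class. For each candidate cell of the threshold grid, pairs passing the
cell's cuts are scored by |PCC| and everything else scores 0; the AUC of
that score against the co-annotation labels measures how well the
thresholded network predicts shared function. The selected cell maximises
AUC, except that when the top cells are within ``tie_epsilon`` of the
maximum the loosest thresholds win — an inclusiveness preference that keeps
more genes in the network when the evidence cannot distinguish the cells.

This module is fully deterministic: no randomness anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .coexpr import CorrelationMatrix, MutualRankMatrix
from .errors import DataError
from .io import GeneSet, GeneSetCollection

__all__ = [
    "PriorSetConfig",
    "ThresholdGrid",
    "GridCell",
    "CalibrationResult",
    "PairLabels",
    "build_prior_sets",
    "label_pairs",
    "roc_auc",
    "pair_scores",
    "calibrate",
    "write_calibration_result",
]

DEFAULT_POSITIVE_PCC_GRID = (0.6, 0.7, 0.8, 0.9)
DEFAULT_NEGATIVE_PCC_GRID = (-0.4, -0.5, -0.6, -0.7)
DEFAULT_MR_GRID = (10.0, 25.0, 50.0, 100.0)


@dataclass(frozen=True)
class PriorSetConfig:
    """Size window for prior gene sets (post-intersection by default)."""

    min_size: int = 4
    max_size: int = 20

    def __post_init__(self) -> None:
        if not (1 <= self.min_size <= self.max_size):
            raise ValueError(
                f"require 1 <= min_size <= max_size, got {self.min_size}..{self.max_size}"
            )


@dataclass(frozen=True)
class ThresholdGrid:
    """Candidate PCC and MR cuts; PCC candidates all one sign."""

    pcc_candidates: tuple[float, ...] = DEFAULT_POSITIVE_PCC_GRID
    mr_candidates: tuple[float, ...] = DEFAULT_MR_GRID

    def __post_init__(self) -> None:
        for name, cand in (("pcc", self.pcc_candidates), ("mr", self.mr_candidates)):
            arr = np.asarray(cand, dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name}_candidates must be non-empty")
            if not (np.all(np.diff(arr) > 0) or np.all(np.diff(arr) < 0)):
                raise ValueError(f"{name}_candidates must be strictly monotone")
        if np.any(np.asarray(self.mr_candidates) <= 0):
            raise ValueError("mr_candidates must be positive")

    @classmethod
    def negative_default(cls) -> "ThresholdGrid":
        return cls(DEFAULT_NEGATIVE_PCC_GRID, DEFAULT_MR_GRID)


@dataclass(frozen=True)
class GridCell:
    pcc_threshold: float
    mr_threshold: float
    auc: float
    n_positive_pairs: int
    n_negative_pairs: int


@dataclass
class CalibrationResult:
    cells: list[GridCell]
    selected: tuple[float, float]
    tie_epsilon: float
    sign: str

    @property
    def selected_cell(self) -> GridCell:
        for c in self.cells:
            if (c.pcc_threshold, c.mr_threshold) == self.selected:
                return c
        raise KeyError(self.selected)

    @property
    def max_auc(self) -> float:
        return max(c.auc for c in self.cells)


@dataclass
class PairLabels:
    """Labeled unordered gene pairs over the prior-annotated universe."""

    genes: list[str]  # sorted universe of annotated genes
    idx_a: np.ndarray  # pair indices into ``genes``, idx_a < idx_b
    idx_b: np.ndarray
    labels: np.ndarray  # 1 = shares >= 1 prior term, 0 = not

    def __len__(self) -> int:
        return len(self.labels)


def build_prior_sets(
    collection: GeneSetCollection,
    expr_genes: set[str] | frozenset[str],
    config: PriorSetConfig = PriorSetConfig(),
    intersect_first: bool = True,
) -> GeneSetCollection:
    """Filter a collection down to prior gene sets.

    Each set is intersected with the expressed genes, then kept iff its
    (post-intersection) size lies in ``[min_size, max_size]``. With
    ``intersect_first=False`` the size filter applies to the raw set before
    intersection instead.
    """
    expr_genes = frozenset(expr_genes)
    kept: list[GeneSet] = []
    for s in collection:
        members = s.gene_ids & expr_genes
        size_basis = len(members) if intersect_first else len(s.gene_ids)
        if config.min_size <= size_basis <= config.max_size and members:
            kept.append(GeneSet(s.term_id, s.term_name, frozenset(members)))
    if not kept:
        warnings.warn("no prior gene sets survived filtering", stacklevel=2)
    return GeneSetCollection(kept, universe=frozenset(expr_genes))


def label_pairs(prior: GeneSetCollection) -> PairLabels:
    """Enumerate all unordered pairs of prior-annotated genes.

    A pair is positive iff the two genes share at least one prior term.
    Raises if either class is empty (the AUC would be undefined).
    """
    if len(prior) == 0:
        raise DataError("prior collection is empty")
    genes = sorted(prior.all_genes())
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    if n < 2:
        raise DataError("fewer than 2 annotated genes; no pairs to label")
    positive = np.zeros((n, n), dtype=bool)
    for s in prior:
        idx = np.array([index[g] for g in s.gene_ids], dtype=int)
        positive[np.ix_(idx, idx)] = True
    iu, ju = np.triu_indices(n, k=1)
    labels = positive[iu, ju].astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise DataError("no positive pairs (no term with >= 2 members)")
    if n_pos == len(labels):
        raise DataError("no negative pairs (all annotated pairs share a term)")
    return PairLabels(genes, iu, ju, labels)


def roc_auc(labels, scores) -> float:
    """AUC as the Mann-Whitney statistic; ties count one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def pair_scores(
    corr: CorrelationMatrix,
    mr: MutualRankMatrix,
    pairs: PairLabels,
    pcc_threshold: float,
    mr_threshold: float,
) -> np.ndarray:
    """Per-pair prediction scores at one grid cell: |PCC| for pairs passing
    (PCC beyond the threshold on its side AND MR strictly below the cut),
    0 otherwise."""
    gidx = np.array([corr.index_of(g) for g in pairs.genes], dtype=int)
    a = gidx[pairs.idx_a]
    b = gidx[pairs.idx_b]
    pcc = corr.values[a, b]
    mrv = mr.values[a, b]
    with np.errstate(invalid="ignore"):
        if pcc_threshold >= 0:
            passing = (pcc > pcc_threshold) & (mrv < mr_threshold)
        else:
            passing = (pcc < pcc_threshold) & (mrv < mr_threshold)
    scores = np.where(passing & np.isfinite(pcc), np.abs(pcc), 0.0)
    return scores


def calibrate(
    corr: CorrelationMatrix,
    mr_matrix: MutualRankMatrix,
    prior: GeneSetCollection,
    grid: ThresholdGrid = ThresholdGrid(),
    sign: str = "positive",
    tie_epsilon: float = 0.01,
) -> CalibrationResult:
    """Score every (PCC, MR) grid cell by co-annotation AUC and select one.

    For each cell, annotated gene pairs passing the cell's cuts (PCC beyond
    the threshold on its side, MR strictly below the cut) score |PCC|;
    everything else scores 0. The selected cell maximises AUC; among cells
    within ``tie_epsilon`` of the maximum, the loosest (smallest |PCC| cut,
    then largest MR cut) wins.
    """
    if sign not in ("positive", "negative"):
        raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")
    expected = (lambda t: t > 0) if sign == "positive" else (lambda t: t < 0)
    if not all(expected(t) for t in grid.pcc_candidates):
        raise ValueError(f"pcc_candidates inconsistent with sign={sign!r}")
    pairs = label_pairs(prior)
    missing = [g for g in pairs.genes if g not in corr.gene_ids]
    if missing:
        raise DataError(
            f"{len(missing)} prior gene(s) absent from the correlation matrix, "
            f"e.g. {missing[:3]}"
        )
    n_pos = int(pairs.labels.sum())
    n_neg = len(pairs) - n_pos
    cells: list[GridCell] = []
    for pcc_t in grid.pcc_candidates:
        for mr_t in grid.mr_candidates:
            scores = pair_scores(corr, mr_matrix, pairs, pcc_t, mr_t)
            cells.append(
                GridCell(float(pcc_t), float(mr_t), roc_auc(pairs.labels, scores), n_pos, n_neg)
            )
    max_auc = max(c.auc for c in cells)
    near = [c for c in cells if c.auc >= max_auc - tie_epsilon]
    # loosest wins among near-ties: smallest |PCC| cut, then largest MR cut
    chosen = min(near, key=lambda c: (abs(c.pcc_threshold), -c.mr_threshold))
    return CalibrationResult(
        cells, (chosen.pcc_threshold, chosen.mr_threshold), tie_epsilon, sign
    )


def write_calibration_result(result: CalibrationResult, path) -> None:
    """One row per grid cell plus a one-line selection record."""
    with open(path, "w") as fh:
        fh.write("pcc_threshold\tmr_threshold\tauc\tn_positive_pairs\tn_negative_pairs\n")
        for c in result.cells:
            fh.write(
                f"{c.pcc_threshold!r}\t{c.mr_threshold!r}\t{c.auc!r}"
                f"\t{c.n_positive_pairs}\t{c.n_negative_pairs}\n"
            )
        fh.write(
            f"#selected\t{result.selected[0]!r}\t{result.selected[1]!r}"
            f"\t{result.selected_cell.auc!r}\ttie_epsilon={result.tie_epsilon!r}\n"
        )
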