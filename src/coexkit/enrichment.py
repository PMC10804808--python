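"""Gene-set enrichment: hypergeometric ORA and preranked GSEA.

Over-representation analysis (ORA) tests a query gene list (e.g. a network
neighborhood) against each annotated term with the upper-tail
hypergeometric test P(X >= k) for an overlap of k query genes with a
K-gene term in an N-gene universe, followed by Benjamini-Hochberg FDR
across terms.

Preranked GSEA walks a score-ordered gene list accumulating a weighted
running sum: hits (term members) add |score|^weight normalised over the
term, misses subtract 1/(N-K); the enrichment score (ES) is the running
sum's maximum signed deviation from zero. Significance comes from gene-label
permutations with the (count+1)/(n_permutations+1) estimator on |ES|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .io import GeneSet, GeneSetCollection

__all__ = ["EnrichmentResult", "GseaResult", "ora", "gsea_preranked", "write_ora_results"]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # overlap
    n: int  # query size
    K: int  # term size within the universe
    N: int  # universe size
    p_value: float
    fdr: float


@dataclass(frozen=True)
class GseaResult:
    term_id: str
    es: float
    p_value: float
    n_permutations: int
    seed: int


def ora(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a query list against each term.

    Query genes outside the universe are dropped (their count is not an
    error); term memberships are intersected with the universe. Results are
    sorted by p-value, then term id.
    """
    universe = frozenset(universe)
    if not universe:
        raise DataError("empty universe")
    query_in = frozenset(query) & universe
    if not query_in:
        raise DataError("query is empty after restricting to the universe")
    N = len(universe)
    n = len(query_in)
    raw: list[tuple[str, str, int, int, float]] = []
    for s in collection:
        members = s.gene_ids & universe
        if not members:
            continue
        K = len(members)
        k = len(members & query_in)
        # upper tail P(X >= k) = survival function at k-1
        p = float(hypergeom.sf(k - 1, N, K, n))
        raw.append((s.term_id, s.term_name, k, K, min(p, 1.0)))
    if not raw:
        return []
    pvals = np.array([r[4] for r in raw])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    results = [
        EnrichmentResult(tid, tname, k, n, K, N, p, float(q))
        for (tid, tname, k, K, p), q in zip(raw, fdr)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.term_id))


def _enrichment_score(
    scores: np.ndarray, hit_mask: np.ndarray, weight: float
) -> float:
    """ES of one ranked list: max signed deviation of the running sum."""
    n = scores.size
    k = int(hit_mask.sum())
    if k == 0 or k == n:
        raise DataError("term must hit a strict subset of the ranked list")
    w = np.abs(scores) ** weight
    hit_total = w[hit_mask].sum()
    steps = np.where(hit_mask, np.where(hit_total > 0, w / max(hit_total, 1e-300), 1.0 / k), -1.0 / (n - k))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_preranked(
    ranked: list[tuple[str, float]],
    term: GeneSet,
    weight: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Preranked GSEA for one term.

    ``ranked`` is the full gene list ordered by score (best first) with
    unique genes. The null distribution permutes gene labels: each
    permutation draws a random same-size gene set from the list and
    recomputes ES; p = (#{|ES_perm| >= |ES|} + 1) / (n_permutations + 1),
    two-sided and never zero. Fully reproducible from ``seed``.
    """
    genes = [g for g, _ in ranked]
    if len(genes) != len(set(genes)):
        raise DataError("ranked list contains duplicate genes")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    scores = np.array([s for _, s in ranked], dtype=float)
    n = scores.size
    hit_mask = np.array([g in term.gene_ids for g in genes])
    k = int(hit_mask.sum())
    if k == 0:
        raise DataError(f"term {term.term_id!r} shares no genes with the ranked list")
    if k == n:
        raise DataError(f"term {term.term_id!r} covers the entire ranked list")
    es = _enrichment_score(scores, hit_mask, weight)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm_hits = np.zeros(n, dtype=bool)
        perm_hits[rng.choice(n, size=k, replace=False)] = True
        if abs(_enrichment_score(scores, perm_hits, weight)) >= abs(es):
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return GseaResult(term.term_id, es, float(p), n_permutations, seed)


def write_ora_results(results: list[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tterm_name\tk\tn\tK\tN\tp_value\tfdr\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.k}\t{r.n}\t{r.K}\t{r.N}"
                f"\t{r.p_value!r}\t{r.fdr!r}\n"
            )
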