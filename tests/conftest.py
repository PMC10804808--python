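import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from coexkit import (
    ASCENDING,
    DESCENDING,
    ExpressionMatrix,
    SyntheticSpec,
    generate,
    mutual_rank,
    pearson_matrix,
    rank_matrix,
)


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """4 genes x 5 samples, hand-written, all-positive TPM."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [2.0, 4.0, 6.0, 8.0, 10.0],
            [5.0, 4.0, 3.0, 2.0, 1.0],
            [3.0, 1.0, 4.0, 1.0, 5.0],
        ]
    )
    return ExpressionMatrix(["gA", "gB", "gC", "gD"], ["s1", "s2", "s3", "s4", "s5"], values)


@pytest.fixture(scope="session")
def synthetic_run():
    """Default study conditions (no anticorrelated members), analyzed on
    log2(TPM+1) — the scale the modules are planted on."""
    expr, truth = generate(SyntheticSpec(seed=1))
    corr = pearson_matrix(expr, log_transform=True)
    mr_pos = mutual_rank(rank_matrix(corr, DESCENDING))
    mr_neg = mutual_rank(rank_matrix(corr, ASCENDING))
    return expr, truth, corr, mr_pos, mr_neg


@pytest.fixture(scope="session")
def synthetic_run_anticorrelated():
    """Same conditions with 2 anticorrelated members planted per module."""
    expr, truth = generate(SyntheticSpec(n_anticorrelated_per_module=2, seed=1))
    corr = pearson_matrix(expr, log_transform=True)
    mr_pos = mutual_rank(rank_matrix(corr, DESCENDING))
    mr_neg = mutual_rank(rank_matrix(corr, ASCENDING))
    return expr, truth, corr, mr_pos, mr_neg


def brute_force_ranks(corr_values: np.ndarray, gene_ids: list[str], descending: bool) -> np.ndarray:
    """Independent oracle: sort each row's partners with an explicit sort."""
    g = len(gene_ids)
    ranks = np.zeros((g, g), dtype=int)
    for i in range(g):
        partners = [j for j in range(g) if j != i and not np.isnan(corr_values[i, j])]
        key = (
            (lambda j: (-corr_values[i, j], gene_ids[j]))
            if descending
            else (lambda j: (corr_values[i, j], gene_ids[j]))
        )
        for r, j in enumerate(sorted(partners, key=key), start=1):
            ranks[i, j] = r
    return ranks
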