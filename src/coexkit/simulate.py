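"""Synthetic expression data with planted coexpression modules.

The generator emulates, at desk scale, the kind of multi-sample TPM matrix
a coexpression pipeline consumes, with known ground truth so recovery can
be measured exactly. The model is log-normal: each module m has a latent
per-sample profile z_m(s) ~ Normal(0, signal_sd^2); a member gene g gets

    log-expression(g, s) = b_g + polarity_g * z_m(s) + eps(g, s)

with baseline b_g ~ Normal(2, 1), noise eps ~ Normal(0, noise_sd^2) and
polarity +1 for regular members, -1 for anti-correlated members. Background
genes carry baseline plus noise only. TPM = exp(log-expression), which
guarantees non-negativity; correlation structure is therefore exact on the
log scale and attenuated (especially for negative pairs) on the raw TPM
scale.

Ground truth includes the module assignment, each gene's polarity, and a
term collection in which each module is one term over all its members —
the synthetic analogue of a functional annotation.

All randomness flows through one seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DEGRecord, DEGTable, ExpressionMatrix, GeneSet, GeneSetCollection, OrthologMap

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate",
    "generate_deg_table",
    "generate_ortholog_fixture",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults mirror a small but well-powered coexpression study: 10 planted
    modules of 8 genes each, 40 unstructured background genes, 30 samples,
    module signal with unit log-scale spread and moderate gene-level noise.
    Anti-correlated module members are off by default and opt-in via
    ``n_anticorrelated_per_module``.
    """

    n_modules: int = 10
    module_size: int = 8
    n_background_genes: int = 40
    n_samples: int = 30
    n_anticorrelated_per_module: int = 0
    noise_sd: float = 0.3
    signal_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_modules, self.module_size, self.n_background_genes,
               self.n_anticorrelated_per_module) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.noise_sd < 0 or self.signal_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic dataset."""

    module_of: dict[str, int | None]  # None = background
    polarity: dict[str, int]  # +1 / -1 (background genes are +1)
    terms: GeneSetCollection  # one term per module, all members

    def module_members(self, module: int, polarity: int | None = None) -> list[str]:
        out = [
            g
            for g, m in self.module_of.items()
            if m == module and (polarity is None or self.polarity[g] == polarity)
        ]
        return sorted(out)

    def background_genes(self) -> list[str]:
        return sorted(g for g, m in self.module_of.items() if m is None)

    def positive_pairs(self) -> list[tuple[str, str]]:
        """All within-module pairs of equal polarity (planted positive corr)."""
        out: list[tuple[str, str]] = []
        for m in sorted({v for v in self.module_of.values() if v is not None}):
            for pol in (1, -1):
                members = self.module_members(m, pol)
                for i in range(len(members)):
                    for j in range(i + 1, len(members)):
                        out.append((members[i], members[j]))
        return out

    def anticorrelated_pairs(self) -> list[tuple[str, str]]:
        """All within-module pairs of opposite polarity."""
        out: list[tuple[str, str]] = []
        for m in sorted({v for v in self.module_of.values() if v is not None}):
            pos = self.module_members(m, 1)
            neg = self.module_members(m, -1)
            for a in pos:
                for b in neg:
                    out.append((min(a, b), max(a, b)))
        return out


def _gene_name(prefix: str, i: int, width: int) -> str:
    return f"{prefix}{i:0{width}d}"


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a TPM matrix and its ground truth, reproducibly from the seed."""
    rng = np.random.default_rng(spec.seed)
    n_module_genes = spec.n_modules * (spec.module_size + spec.n_anticorrelated_per_module)
    n_genes = n_module_genes + spec.n_background_genes
    width = max(3, len(str(n_genes)))
    gene_ids: list[str] = []
    module_of: dict[str, int | None] = {}
    polarity: dict[str, int] = {}

    # latent module profiles
    z = rng.normal(0.0, spec.signal_sd, size=(spec.n_modules, spec.n_samples))
    log_expr = np.empty((n_genes, spec.n_samples))
    row = 0
    term_sets: list[GeneSet] = []
    for m in range(spec.n_modules):
        members: list[str] = []
        for j in range(spec.module_size + spec.n_anticorrelated_per_module):
            gid = _gene_name(f"M{m:02d}G", j, 3)
            pol = 1 if j < spec.module_size else -1
            gene_ids.append(gid)
            members.append(gid)
            module_of[gid] = m
            polarity[gid] = pol
            b = rng.normal(2.0, 1.0)
            eps = rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
            log_expr[row] = b + pol * z[m] + eps
            row += 1
        term_sets.append(
            GeneSet(f"MOD:{m:04d}", f"planted module {m}", frozenset(members))
        )
    for j in range(spec.n_background_genes):
        gid = _gene_name("BGG", j, 3)
        gene_ids.append(gid)
        module_of[gid] = None
        polarity[gid] = 1
        b = rng.normal(2.0, 1.0)
        eps = rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
        log_expr[row] = b + eps
        row += 1

    tpm = np.exp(log_expr)
    sample_ids = [f"S{s:03d}" for s in range(spec.n_samples)]
    expr = ExpressionMatrix(gene_ids, sample_ids, tpm)
    truth = SyntheticTruth(module_of, polarity, GeneSetCollection(term_sets))
    return expr, truth


def generate_deg_table(
    truth: SyntheticTruth,
    contrast_name: str,
    fraction_up: float,
    fraction_down: float,
    seed: int = 0,
) -> DEGTable:
    """Label random disjoint gene subsets up/down for one contrast."""
    if not (0 <= fraction_up <= 1 and 0 <= fraction_down <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if fraction_up + fraction_down > 1:
        raise ValueError("fraction_up + fraction_down must be <= 1")
    rng = np.random.default_rng(seed)
    genes = sorted(truth.module_of)
    n = len(genes)
    n_up = int(round(fraction_up * n))
    n_down = int(round(fraction_down * n))
    chosen = rng.choice(n, size=min(n, n_up + n_down), replace=False)
    records = [
        DEGRecord(genes[i], contrast_name, "up" if pos < n_up else "down")
        for pos, i in enumerate(chosen)
    ]
    return DEGTable(records)


def generate_ortholog_fixture(
    n_source: int,
    n_target: int,
    many_to_many_fraction: float = 0.0,
    seed: int = 0,
    n_source_edges: int | None = None,
) -> tuple[OrthologMap, list[tuple[str, str]]]:
    """Random ortholog map plus a random source edge list.

    Each source gene maps to one random target; a ``many_to_many_fraction``
    share of source genes get one extra target. With the fraction at 0 and
    n_source <= n_target, the map is injective. The source edge list draws
    ``n_source_edges`` (default n_source) random gene pairs (self-pairs
    allowed, so projections may legitimately drop them).
    """
    if n_source < 1 or n_target < 1:
        raise ValueError("counts must be >= 1")
    if not (0 <= many_to_many_fraction <= 1):
        raise ValueError("many_to_many_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sources = [f"SRC{i:04d}" for i in range(n_source)]
    targets = [f"TGT{i:04d}" for i in range(n_target)]
    pairs: list[tuple[str, str]] = []
    primary = rng.permutation(n_target)
    for i, s in enumerate(sources):
        pairs.append((s, targets[primary[i % n_target]]))
    n_extra = int(round(many_to_many_fraction * n_source))
    extra_sources = rng.choice(n_source, size=n_extra, replace=False)
    for i in extra_sources:
        t = targets[int(rng.integers(n_target))]
        if (sources[i], t) not in pairs:
            pairs.append((sources[i], t))
    n_edges = n_source if n_source_edges is None else n_source_edges
    edges = [
        (sources[int(rng.integers(n_source))], sources[int(rng.integers(n_source))])
        for _ in range(n_edges)
    ]
    return OrthologMap(pairs), edges
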