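"""Core domain types and readers/writers for the plain-text formats.

All tabular formats are tab-separated, unquoted, with ``#``-prefixed lines
treated as comments. Gene identifiers are case-sensitive opaque strings.

Domain types
------------
ExpressionMatrix
    genes x samples TPM values (non-negative, finite, no missing data).
GeneSet / GeneSetCollection
    term -> member-gene mappings (GMT or two-column TSV on disk).
DEGTable
    per-contrast up/down calls with optional log2 fold change and adjusted p.
OrthologMap
    (source_gene, target_gene) pairs, possibly many-to-many.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import DataError

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "DEGRecord",
    "DEGTable",
    "OrthologMap",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_deg_table",
    "write_deg_table",
    "read_ortholog_map",
    "read_edge_pairs",
    "extract_sequences",
]

MIN_SAMPLES = 3  # Pearson correlation needs at least 3 observations


def _fmt(x: float) -> str:
    """Full-precision, round-trippable float formatting."""
    return repr(float(x))


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of TPM values.

    Invariants (checked on construction): unique gene and sample ids,
    all values finite and >= 0. Missing values are not supported.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise DataError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression values must be finite (no NaN/inf)")
        if np.any(self.values < 0):
            raise DataError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class GeneSet:
    """A named term with a non-empty set of member genes."""

    term_id: str
    term_name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise DataError(f"gene set {self.term_id!r} has no members")
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GeneSetCollection:
    """An ordered collection of gene sets with unique term ids."""

    sets: list[GeneSet]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        ids = [s.term_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise DataError(f"duplicate term id: {dup!r}")
        if self.universe is not None:
            self.universe = frozenset(self.universe)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def term_ids(self) -> list[str]:
        return [s.term_id for s in self.sets]

    def get(self, term_id: str) -> GeneSet:
        for s in self.sets:
            if s.term_id == term_id:
                return s
        raise KeyError(term_id)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.gene_ids
        return frozenset(out)

    def check_universe(self) -> None:
        """Strict mode: every member gene must be in the declared universe."""
        if self.universe is None:
            return
        stray = self.all_genes() - self.universe
        if stray:
            raise DataError(
                f"{len(stray)} member gene(s) outside the declared universe, "
                f"e.g. {sorted(stray)[:3]}"
            )


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    contrast: str
    direction: str  # "up" | "down"
    log2fc: float | None = None
    padj: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise DataError(
                f"direction must be 'up' or 'down', got {self.direction!r} "
                f"for gene {self.gene_id!r}"
            )
        if self.log2fc is not None:
            if self.direction == "up" and self.log2fc < 0:
                raise DataError(f"gene {self.gene_id!r}: direction 'up' but log2fc < 0")
            if self.direction == "down" and self.log2fc > 0:
                raise DataError(f"gene {self.gene_id!r}: direction 'down' but log2fc > 0")


@dataclass
class DEGTable:
    """Differential-expression calls, unique per (gene, contrast)."""

    records: list[DEGRecord]

    def __post_init__(self) -> None:
        keys = [(r.gene_id, r.contrast) for r in self.records]
        if len(keys) != len(set(keys)):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise DataError(f"duplicate (gene, contrast) entry: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def contrasts(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.contrast not in out:
                out.append(r.contrast)
        return out

    def for_contrast(self, contrast: str) -> dict[str, str]:
        """gene_id -> direction for one contrast."""
        return {r.gene_id: r.direction for r in self.records if r.contrast == contrast}


@dataclass
class OrthologMap:
    """Many-to-many (source_gene, target_gene) pairs, no duplicates."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.pairs) != len(set(self.pairs)):
            raise DataError("duplicate ortholog pair")
        self.pairs = [tuple(p) for p in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)

    def targets_of(self, source: str) -> list[str]:
        return sorted({t for s, t in self.pairs if s == source})

    def as_dict(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for s, t in self.pairs:
            out.setdefault(s, set()).add(t)
        return out


# ---------------------------------------------------------------------------
# Tabular readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, line) skipping comments and blank lines."""
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        yield lineno, raw


def read_expression_matrix(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples TPM matrix.

    First header row holds sample ids; first column holds gene ids.
    Row/column order from the file is preserved.
    """
    lines = list(_data_lines(path))
    if not lines:
        raise DataError(f"empty expression matrix file: {path}")
    header = lines[0][1].split(delimiter)
    sample_ids = [c.strip() for c in header[1:]]
    if not sample_ids:
        raise DataError(f"{path}: header has no sample columns")
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in lines[1:]:
        cells = line.split(delimiter)
        gid = cells[0].strip()
        if gid in seen:
            raise DataError(f"{path}: duplicate gene id {gid!r} (line {lineno})")
        seen.add(gid)
        if len(cells) - 1 != len(sample_ids):
            raise DataError(
                f"{path}: line {lineno} has {len(cells) - 1} values, "
                f"expected {len(sample_ids)}"
            )
        vals: list[float] = []
        for col, cell in enumerate(cells[1:], start=2):
            try:
                vals.append(float(cell))
            except ValueError:
                raise DataError(
                    f"{path}: non-numeric cell at line {lineno}, column {col}: {cell!r}"
                ) from None
        gene_ids.append(gid)
        rows.append(vals)
    if not gene_ids:
        raise DataError(f"{path}: no gene rows")
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float))


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write("gene_id" + delimiter + delimiter.join(expr.sample_ids) + "\n")
        for gid, row in zip(expr.gene_ids, expr.values):
            fh.write(gid + delimiter + delimiter.join(_fmt(v) for v in row) + "\n")


def read_gene_sets(path: str | Path, format: str = "gmt") -> GeneSetCollection:
    """Read term -> gene annotations.

    ``gmt``: one term per line, ``term<TAB>description<TAB>gene1<TAB>...``.
    ``tsv2col``: one (term_id, gene_id[, term_name]) pair per line; duplicate
    pairs collapse; one GeneSet per distinct term.
    """
    if format not in ("gmt", "tsv2col"):
        raise ValueError(f"unknown gene-set format: {format!r}")
    if format == "gmt":
        sets: list[GeneSet] = []
        for lineno, line in _data_lines(path):
            cells = line.split("\t")
            if len(cells) < 3:
                raise DataError(
                    f"{path}: GMT line {lineno} has {len(cells)} fields, needs >= 3"
                )
            term, name, members = cells[0], cells[1], [c for c in cells[2:] if c.strip()]
            if not members:
                raise DataError(f"{path}: GMT line {lineno}: term {term!r} has no members")
            sets.append(GeneSet(term, name, frozenset(members)))
        return GeneSetCollection(sets)
    members_by_term: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    order: list[str] = []
    for lineno, line in _data_lines(path):
        cells = line.split("\t")
        if len(cells) < 2:
            raise DataError(f"{path}: line {lineno} has {len(cells)} fields, needs >= 2")
        term, gene = cells[0].strip(), cells[1].strip()
        if term not in members_by_term:
            members_by_term[term] = set()
            order.append(term)
        members_by_term[term].add(gene)
        if len(cells) >= 3 and cells[2].strip():
            names[term] = cells[2].strip()
    return GeneSetCollection(
        [GeneSet(t, names.get(t, t), frozenset(members_by_term[t])) for t in order]
    )


def write_gene_sets(collection: GeneSetCollection, path: str | Path, format: str = "gmt") -> None:
    with open(path, "w") as fh:
        for s in collection:
            members = sorted(s.gene_ids)
            if format == "gmt":
                fh.write("\t".join([s.term_id, s.term_name] + members) + "\n")
            elif format == "tsv2col":
                for g in members:
                    fh.write(f"{s.term_id}\t{g}\t{s.term_name}\n")
            else:
                raise ValueError(f"unknown gene-set format: {format!r}")


_DEG_HEADER = ["gene_id", "contrast", "direction", "log2fc", "padj"]


def read_deg_table(path: str | Path) -> DEGTable:
    """Read a DEG table: gene_id, contrast, direction[, log2fc[, padj]]."""
    lines = list(_data_lines(path))
    if not lines:
        return DEGTable([])
    start = 1 if lines[0][1].split("\t")[0].strip() == "gene_id" else 0
    records: list[DEGRecord] = []
    for lineno, line in lines[start:]:
        cells = [c.strip() for c in line.split("\t")]
        if len(cells) < 3:
            raise DataError(f"{path}: line {lineno} has {len(cells)} fields, needs >= 3")
        log2fc = float(cells[3]) if len(cells) > 3 and cells[3] not in ("", "NA") else None
        padj = float(cells[4]) if len(cells) > 4 and cells[4] not in ("", "NA") else None
        records.append(DEGRecord(cells[0], cells[1], cells[2], log2fc, padj))
    return DEGTable(records)


def write_deg_table(table: DEGTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_DEG_HEADER) + "\n")
        for r in table.records:
            fh.write(
                "\t".join(
                    [
                        r.gene_id,
                        r.contrast,
                        r.direction,
                        "" if r.log2fc is None else _fmt(r.log2fc),
                        "" if r.padj is None else _fmt(r.padj),
                    ]
                )
                + "\n"
            )


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read (source_gene, target_gene) pairs; duplicate rows collapse."""
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for lineno, line in _data_lines(path):
        cells = [c.strip() for c in line.split("\t")]
        if len(cells) < 2:
            raise DataError(f"{path}: line {lineno} has {len(cells)} fields, needs >= 2")
        if cells[0] == "source_gene":  # optional header
            continue
        pair = (cells[0], cells[1])
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    return OrthologMap(pairs)


def read_edge_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column edge list (e.g. a reference PPI network)."""
    edges: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        cells = [c.strip() for c in line.split("\t")]
        if len(cells) < 2:
            raise DataError(f"{path}: line {lineno} has {len(cells)} fields, needs >= 2")
        if cells[0] in ("gene_a", "protein_a"):
            continue
        edges.append((cells[0], cells[1]))
    return edges


# ---------------------------------------------------------------------------
# FASTA sequence extraction
# ---------------------------------------------------------------------------

def extract_sequences(
    fasta_path: str | Path,
    requests: Sequence[tuple],
) -> str:
    """Extract (sub)sequences from a FASTA file.

    Each request is ``(seq_id,)`` for the full record or
    ``(seq_id, start, end, strand)`` with 1-based, both-ends-inclusive
    coordinates and strand ``+`` or ``-`` (``-`` returns the reverse
    complement). Records are returned in request order as FASTA text
    wrapped at 60 columns.
    """
    records = {rec.id: rec for rec in SeqIO.parse(str(fasta_path), "fasta")}
    out = _stdio.StringIO()
    for req in requests:
        seq_id = req[0]
        start = req[1] if len(req) > 1 else None
        end = req[2] if len(req) > 2 else None
        strand = req[3] if len(req) > 3 else "+"
        if seq_id not in records:
            raise DataError(f"unknown sequence id: {seq_id!r}")
        seq = records[seq_id].seq
        if start is None and end is None:
            sub = seq
            header = seq_id
        else:
            start = 1 if start is None else int(start)
            end = len(seq) if end is None else int(end)
            if start < 1:
                raise DataError(f"{seq_id}: start must be >= 1, got {start}")
            if start > end:
                raise DataError(f"{seq_id}: start {start} > end {end}")
            if end > len(seq):
                raise DataError(
                    f"{seq_id}: end {end} beyond sequence length {len(seq)}"
                )
            sub = seq[start - 1 : end]  # 1-based inclusive -> 0-based half-open
            header = f"{seq_id}:{start}-{end}"
        if strand not in ("+", "-"):
            raise DataError(f"{seq_id}: strand must be '+' or '-', got {strand!r}")
        if strand == "-":
            sub = Seq(str(sub)).reverse_complement()
            header += "(-)"
        out.write(f">{header}\n")
        s = str(sub)
        for i in range(0, len(s), 60):
            out.write(s[i : i + 60] + "\n")
    return out.getvalue()
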