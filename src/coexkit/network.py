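"""Signed coexpression network assembly, PPI projection, DEG overlay.

A positive edge requires PCC > pcc_pos_cut and descending-rank MR < mr_cut;
a negative edge requires PCC < pcc_neg_cut and ascending-rank MR < mr_cut
(strict inequalities). On top of the thresholded edges, each gene's top-k
highest-PCC partners are guaranteed inclusion (union semantics): they enter
the network even below threshold, tagged with origin "topk" ("both" when
they also pass the thresholds). Networks are undirected, deduplicated by
lexicographically sorted endpoints, with no self-loops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .coexpr import (
    ASCENDING,
    DESCENDING,
    CorrelationMatrix,
    MutualRankMatrix,
    topk_partners,
)
from .errors import DataError
from .io import DEGTable, OrthologMap

__all__ = [
    "CoexpressionEdge",
    "Network",
    "build_signed_network",
    "project_ppi",
    "overlay_degs",
    "neighborhood",
    "write_edge_list",
    "write_node_attributes",
    "write_graphml",
]

UP_COLOR = "#FF0000"
DOWN_COLOR = "#0000FF"


@dataclass(frozen=True)
class CoexpressionEdge:
    """Undirected signed edge; gene_a < gene_b lexicographically."""

    gene_a: str
    gene_b: str
    pcc: float
    mr: float
    sign: str  # "positive" | "negative"
    origin: str  # "threshold" | "topk" | "both"

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise DataError(f"edge endpoints not canonical: {self.gene_a!r} >= {self.gene_b!r}")
        if self.sign == "positive" and self.pcc <= 0:
            raise DataError(f"positive edge with pcc <= 0: {self.gene_a}-{self.gene_b}")
        if self.sign == "negative" and self.pcc >= 0:
            raise DataError(f"negative edge with pcc >= 0: {self.gene_a}-{self.gene_b}")


class Network:
    """Thin wrapper over an undirected ``networkx.Graph``.

    Edge attributes: pcc, mr, sign, origin. Node attributes: one
    ``deg::<contrast>`` key per overlaid contrast with value up/down/none.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_edge(self, edge: CoexpressionEdge) -> None:
        self.graph.add_edge(
            edge.gene_a,
            edge.gene_b,
            pcc=edge.pcc,
            mr=edge.mr,
            sign=edge.sign,
            origin=edge.origin,
        )

    def edges(self, sign: str | None = None) -> list[CoexpressionEdge]:
        out = []
        for a, b, d in self.graph.edges(data=True):
            if sign is not None and d.get("sign") != sign:
                continue
            a2, b2 = sorted((a, b))
            out.append(CoexpressionEdge(a2, b2, d["pcc"], d["mr"], d["sign"], d["origin"]))
        return sorted(out, key=lambda e: (e.gene_a, e.gene_b))

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def edge_data(self, a: str, b: str) -> dict:
        return dict(self.graph.edges[a, b])


def build_signed_network(
    corr: CorrelationMatrix,
    mr_pos: MutualRankMatrix,
    mr_neg: MutualRankMatrix,
    pcc_pos_cut: float = 0.6,
    pcc_neg_cut: float = -0.5,
    mr_cut: float = 50.0,
    top_k: int = 3,
    topk_mode: str = "union",
) -> Network:
    """Assemble the signed network at an operating point.

    Positive edge iff PCC > ``pcc_pos_cut`` and MR_pos < ``mr_cut``;
    negative edge iff PCC < ``pcc_neg_cut`` and MR_neg < ``mr_cut`` (all
    strict). With ``topk_mode="union"`` (default) each gene's ``top_k``
    highest-PCC partners are additionally retained (origin "topk"/"both");
    with ``topk_mode="cap"`` the network is instead restricted to edges that
    are in some endpoint's top-k list. ``top_k=0`` disables retention.

    All genes of the correlation matrix appear as nodes, including isolated
    ones.
    """
    if not (pcc_pos_cut > 0 > pcc_neg_cut):
        raise ValueError("require pcc_pos_cut > 0 > pcc_neg_cut")
    if mr_cut < 1:
        raise ValueError("mr_cut must be >= 1")
    if top_k < 0:
        raise ValueError("top_k must be >= 0")
    if topk_mode not in ("union", "cap"):
        raise ValueError(f"topk_mode must be 'union' or 'cap', got {topk_mode!r}")
    for m, name, want in ((mr_pos, "mr_pos", DESCENDING), (mr_neg, "mr_neg", ASCENDING)):
        if list(m.gene_ids) != list(corr.gene_ids):
            raise DataError(f"{name} gene universe differs from the correlation matrix")
        if m.direction != want:
            raise DataError(f"{name} must use {want} ranks, got {m.direction}")

    ids = corr.gene_ids
    g = corr.n_genes
    net = Network()
    net.graph.add_nodes_from(ids)

    with np.errstate(invalid="ignore"):
        pos_mask = (corr.values > pcc_pos_cut) & (mr_pos.values < mr_cut)
        neg_mask = (corr.values < pcc_neg_cut) & (mr_neg.values < mr_cut)
    pos_mask &= corr.defined
    neg_mask &= corr.defined
    np.fill_diagonal(pos_mask, False)
    np.fill_diagonal(neg_mask, False)

    # top-k guaranteed-inclusion pairs (positive network side)
    topk_pairs: set[tuple[int, int]] = set()
    if top_k >= 1:
        by_gene = topk_partners(corr, top_k)
        index = {gid: i for i, gid in enumerate(ids)}
        for gid, partners in by_gene.items():
            i = index[gid]
            for pid, _pcc in partners:
                j = index[pid]
                topk_pairs.add((min(i, j), max(i, j)))

    def add(i: int, j: int, sign: str, origin: str) -> None:
        a, b = sorted((ids[i], ids[j]))
        mr_val = mr_pos.values[i, j] if sign == "positive" else mr_neg.values[i, j]
        net.add_edge(
            CoexpressionEdge(a, b, float(corr.values[i, j]), float(mr_val), sign, origin)
        )

    iu, ju = np.triu_indices(g, k=1)
    for i, j in zip(iu[pos_mask[iu, ju]], ju[pos_mask[iu, ju]]):
        in_topk = (i, j) in topk_pairs
        if topk_mode == "cap" and top_k >= 1 and not in_topk:
            continue
        add(int(i), int(j), "positive", "both" if in_topk else "threshold")
    for i, j in zip(iu[neg_mask[iu, ju]], ju[neg_mask[iu, ju]]):
        add(int(i), int(j), "negative", "threshold")

    if topk_mode == "union":
        for i, j in sorted(topk_pairs):
            if net.has_edge(ids[i], ids[j]):
                continue
            pcc = corr.values[i, j]
            if not np.isfinite(pcc) or pcc == 0:
                continue  # sign undefined
            add(i, j, "positive" if pcc > 0 else "negative", "topk")
    return net


def project_ppi(
    ortholog_map: OrthologMap, source_edges: list[tuple[str, str]]
) -> tuple[list[tuple[str, str]], int]:
    """Project a reference interaction edge list through an ortholog map.

    For each source edge (s1, s2), every target pair (t1, t2) with s1->t1
    and s2->t2 in the map is emitted; self-loops are dropped and pairs are
    deduplicated with sorted endpoints. Returns ``(edges, n_unprojected)``
    where the count is the number of source edges with no projection.
    """
    mapping = ortholog_map.as_dict()
    if not mapping:
        warnings.warn("empty ortholog map: projection is empty", stacklevel=2)
    out: set[tuple[str, str]] = set()
    n_unprojected = 0
    for s1, s2 in source_edges:
        t1s = mapping.get(s1, set())
        t2s = mapping.get(s2, set())
        produced = False
        for t1 in t1s:
            for t2 in t2s:
                if t1 == t2:
                    continue
                out.add((min(t1, t2), max(t1, t2)))
                produced = True
        if not produced:
            n_unprojected += 1
    return sorted(out), n_unprojected


def overlay_degs(
    network: Network, degs: DEGTable, contrast: str
) -> tuple[Network, int]:
    """Annotate nodes with up/down status for one contrast.

    Each contrast gets its own independent node attribute ``deg::<contrast>``
    (overlaying a second contrast does not overwrite the first). Topology is
    unchanged. DEG genes absent from the network are silently ignored;
    their count is returned.
    """
    if contrast not in degs.contrasts():
        raise DataError(f"contrast {contrast!r} not present in the DEG table")
    status = degs.for_contrast(contrast)
    key = f"deg::{contrast}"
    n_missing = 0
    for gene, direction in status.items():
        if gene in network.graph:
            network.graph.nodes[gene][key] = direction
        else:
            n_missing += 1
    for node in network.graph.nodes:
        network.graph.nodes[node].setdefault(key, "none")
    return network, n_missing


def neighborhood(network: Network, gene_id: str, sign: str | None = None) -> list[CoexpressionEdge]:
    """All edges incident to a gene, optionally sign-filtered, by |pcc| desc."""
    if gene_id not in network.graph:
        raise DataError(f"gene {gene_id!r} not in the network")
    out = []
    for nbr, d in network.graph[gene_id].items():
        if sign is not None and d.get("sign") != sign:
            continue
        a, b = sorted((gene_id, nbr))
        out.append(CoexpressionEdge(a, b, d["pcc"], d["mr"], d["sign"], d["origin"]))
    return sorted(out, key=lambda e: (-abs(e.pcc), e.gene_a, e.gene_b))


def write_edge_list(network: Network, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tpcc\tmr\tsign\torigin\n")
        for e in network.edges():
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.pcc!r}\t{e.mr!r}\t{e.sign}\t{e.origin}\n")


def write_node_attributes(network: Network, path) -> None:
    """Long-format gene_id, contrast, deg_status for every overlaid contrast."""
    with open(path, "w") as fh:
        fh.write("gene_id\tcontrast\tdeg_status\n")
        for node in sorted(network.graph.nodes):
            for key, val in sorted(network.graph.nodes[node].items()):
                if key.startswith("deg::"):
                    fh.write(f"{node}\t{key[5:]}\t{val}\n")


def write_graphml(network: Network, path, contrast: str | None = None) -> None:
    """GraphML export with viewer color hints (red = up, blue = down)."""
    g = network.graph.copy()
    if contrast is not None:
        key = f"deg::{contrast}"
        for node in g.nodes:
            status = g.nodes[node].get(key, "none")
            if status == "up":
                g.nodes[node]["color"] = UP_COLOR
            elif status == "down":
                g.nodes[node]["color"] = DOWN_COLOR
    nx.write_graphml(g, path)
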