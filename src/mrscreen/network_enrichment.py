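"""Hub-gene ranking and hypergeometric drug-set over-representation.

Candidate proteins from the MR screen are interpreted as nodes of a
protein-protein interaction network; hub genes are the nodes of highest
degree. Drug repurposing candidates are then found by asking, for each
drug's target gene set, whether the hub/core genes overlap it more than
chance would allow under sampling without replacement from a finite gene
universe — the upper tail of the hypergeometric distribution — with
Benjamini-Hochberg adjustment across drugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneNetwork:
    """Undirected interaction network over gene symbols.

    Self-loops are rejected; duplicate edges collapse (dedup contract).
    """

    nodes: set[str] = field(default_factory=set)
    edges: set[frozenset[str]] = field(default_factory=set)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "GeneNetwork":
        net = cls()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            net.nodes.update((a, b))
            net.edges.add(frozenset((a, b)))
        return net

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(tuple(sorted(e)) for e in self.edges))
        return g


@dataclass
class EnrichmentResult:
    set_id: str
    set_size: int
    query_size: int
    universe_size: int
    overlap: int
    overlap_genes: list[str]
    pval: float
    padj: float


def read_edge_list(path) -> GeneNetwork:
    """Two-column (optionally more) TSV edge list; extra columns ignored."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"edge line has fewer than two columns: {line!r}")
            edges.append((parts[0], parts[1]))
    return GeneNetwork.from_edges(edges)


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: set id, description, then members, tab-separated."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def degree_hubs(network: GeneNetwork, k: int) -> list[tuple[str, int]]:
    """Top-k genes by node degree, descending; ties lexicographic."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if not network.nodes:
        raise ValueError("empty network")
    g = network.to_networkx()
    ranked = sorted(g.degree(), key=lambda nd: (-nd[1], nd[0]))
    return [(gene, int(deg)) for gene, deg in ranked[:k]]


def hypergeom_enrich(
    query: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str] | None = None,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of a query gene list.

    For each set, ``pval = P[X >= overlap]`` with
    ``X ~ Hypergeom(universe_size, set_size, query_size)``. The universe
    defaults to the union of all gene-set members and the query. Query genes
    outside the universe are logged and dropped; sets are intersected with
    the universe. Adjustment is Benjamini-Hochberg across sets; output is
    sorted by (padj, pval, set_id).
    """
    if universe is None:
        uni = set(query)
        for members in gene_sets.values():
            uni.update(members)
    else:
        uni = set(universe)
        if not uni:
            raise ValueError("empty universe")
    q = set(query) & uni
    dropped = set(query) - uni
    if dropped:
        logger.warning("query genes outside universe dropped: %s", sorted(dropped))
    if not uni:
        raise ValueError("empty universe")

    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & uni
        overlap = sorted(q & members)
        M, n, N, k = len(uni), len(members), len(q), len(overlap)
        pval = float(hypergeom.sf(k - 1, M, n, N)) if k > 0 else 1.0
        rows.append((set_id, n, N, M, k, overlap, min(1.0, pval)))
    if not rows:
        return []
    padj = multipletests([r[6] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(sid, n, N, M, k, ov, p, float(max(a, p)))
        for (sid, n, N, M, k, ov, p), a in zip(rows, padj)
    ]
    return sorted(results, key=lambda r: (r.padj, r.pval, r.set_id))
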