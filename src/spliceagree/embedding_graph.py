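"""Directed graph over maximal pairings encoding all plausible anchor chains.

An *embedding* is an ordered chain of non-overlapping pairings tracing a
transcript through the genome. Rather than enumerating embeddings directly,
the pipeline builds a directed graph whose vertices are the maximal
pairings and whose edges mark pairs of anchors that can appear
consecutively in a representative (biologically constrained) embedding:
the transcript gap between them must fit inside one exon (<= ell_D) and
the genomic drift must be either exon-noise (|drift| <= ell_D) or an
intron (drift >= ell_I).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .pairings import Pairing, find_maximal_pairings
from .params import Parameters


def edge_condition(v1: Pairing, v2: Pairing, params: Parameters) -> bool:
    """True iff ``v2`` may follow ``v1`` in a representative embedding.

    Conditions: (i) the transcript gap ``p2 - (p1 + l1)`` is at most
    ell_D; (ii) the genomic drift ``t2 - t1 - (p2 - p1)`` is either small
    (|drift| <= ell_D, same exon) or intron-sized (>= ell_I). A forward
    orientation constraint (p1 < p2, ties by t) excludes chains moving
    backwards on the transcript; self-edges are excluded.
    """
    if v1 == v2:
        return False
    if not (v1.p < v2.p or (v1.p == v2.p and v1.t < v2.t)):
        return False
    if v2.p - (v1.p + v1.l) > params.ell_D:
        return False
    drift = v2.t - v1.t - (v2.p - v1.p)
    return abs(drift) <= params.ell_D or drift >= params.ell_I


@dataclass
class EmbeddingGraph:
    """Embedding graph of a transcript against the genome."""

    vertices: list[Pairing]
    params: Parameters
    graph: nx.DiGraph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vertices = sorted(set(self.vertices))
        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        for v1 in self.vertices:
            for v2 in self.vertices:
                if edge_condition(v1, v2, self.params):
                    g.add_edge(v1, v2)
        self.graph = g

    @property
    def edges(self) -> list[tuple[Pairing, Pairing]]:
        return sorted(self.graph.edges())

    def successors(self, v: Pairing) -> list[Pairing]:
        return sorted(self.graph.successors(v))

    def to_dot(self) -> str:
        lines = ["digraph embedding {"]
        for v in self.vertices:
            lines.append(f'  "{v.p}_{v.t}_{v.l}";')
        for a, b in self.edges:
            lines.append(f'  "{a.p}_{a.t}_{a.l}" -> "{b.p}_{b.t}_{b.l}";')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_tsv(self) -> str:
        rows = ["v1_p\tv1_t\tv1_l\tv2_p\tv2_t\tv2_l"]
        for a, b in self.edges:
            rows.append(f"{a.p}\t{a.t}\t{a.l}\t{b.p}\t{b.t}\t{b.l}")
        return "\n".join(rows) + "\n"


def build_embedding_graph(vertices: list[Pairing], params: Parameters) -> EmbeddingGraph:
    """Build the graph by the all-pairs edge test (O(|V|^2))."""
    return EmbeddingGraph(vertices, params)


def build_from_sequences(P: str, T: str, params: Parameters) -> EmbeddingGraph:
    """Compute maximal pairings of P in T and assemble their embedding graph."""
    return EmbeddingGraph(find_maximal_pairings(P, T, params.ell_E), params)


def extended_sources(g: EmbeddingGraph, params: Parameters | None = None) -> list[Pairing]:
    """Vertices from which the embedding visit starts.

    Union of in-degree-0 vertices and vertices anchored near the
    transcript 5' end (p <= source_window): a superset guaranteeing that
    the first anchor of every representative embedding is reachable, even
    inside directed cycles among overlapping pairings.
    """
    params = params or g.params
    out = [v for v in g.vertices
           if g.graph.in_degree(v) == 0 or v.p <= params.source_window]
    return sorted(out)
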