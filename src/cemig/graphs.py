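"""Hamming-distance and de Bruijn graphs over significant k-mers.

The Hamming graph G joins k-mers of the significant tier K2 whose Hamming
distance is below two: with distinct vertices that forces distance exactly
one, so each edge links a k-mer to a single-substitution neighbour.  The
de Bruijn graph G_DB is directed over K2 union K3, with an edge u -> v
whenever the (k-1)-suffix of u equals the (k-1)-prefix of v; the edge
weight is the frequency of the concatenated (k+1)-mer counted over the
input sequences and their reverse complements.
"""

from __future__ import annotations

import logging

import networkx as nx

from .background import count_kmers
from .sequences import SequenceSet

log = logging.getLogger(__name__)


def hamming_distance(u: str, v: str) -> int:
    if len(u) != len(v):
        raise ValueError(f"length mismatch: {len(u)} vs {len(v)}")
    return sum(a != b for a, b in zip(u, v))


def _substitution_neighbors(kmer: str):
    for i, base in enumerate(kmer):
        for b in "ACGT":
            if b != base:
                yield kmer[:i] + b + kmer[i + 1 :]


def build_hamming_graph(k2) -> nx.Graph:
    """Undirected graph over K2 with an edge per distance-1 pair.

    Built by enumerating each k-mer's 3k single-substitution neighbours and
    intersecting with K2 — O(|K2| * k) expected, not all-pairs.  Edge
    weights store the Hamming distance (always 1 here); downstream scoring
    uses the inverse weight.
    """
    vertices = set(k2)
    g = nx.Graph()
    g.add_nodes_from(vertices)
    if not vertices:
        log.warning("building Hamming graph over an empty k-mer set")
        return g
    lengths = {len(t) for t in vertices}
    if len(lengths) > 1:
        raise ValueError("all k-mers must have equal length")
    for u in vertices:
        for v in _substitution_neighbors(u):
            if v in vertices and u < v:
                g.add_edge(u, v, weight=1)
    return g


def build_debruijn_graph(seqs: SequenceSet, vertices, k: int) -> nx.DiGraph:
    """Directed de Bruijn graph over the given k-mers.

    An ordered pair (u, v) with a (k-1)-overlap receives weight equal to
    the number of occurrences of the (k+1)-mer u + v[-1] across the forward
    sequences and their reverse complements; zero-weight edges are omitted.
    Each (k+1)-mer determines its flanking pair uniquely, so the graph is
    assembled from one (k+1)-mer counting pass.
    """
    vertex_set = set(vertices)
    g = nx.DiGraph()
    g.add_nodes_from(vertex_set)
    counts = count_kmers(seqs, k + 1, both_strands=True)
    for word, c in counts.items():
        u, v = word[:k], word[1:]
        if u in vertex_set and v in vertex_set:
            g.add_edge(u, v, weight=c)
    return g


def dump_edges_tsv(path, *graphs: tuple[str, nx.Graph]) -> None:
    """Write (u, v, weight, graph_name) rows for debugging/visualization."""
    with open(path, "w") as fh:
        fh.write("u\tv\tweight\tgraph\n")
        for name, g in graphs:
            for u, v, data in g.edges(data=True):
                fh.write(f"{u}\t{v}\t{data.get('weight', 1)}\t{name}\n")
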