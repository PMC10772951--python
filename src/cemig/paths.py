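"""Motif assembly: cluster digraph, greedy path extension and refinement.

Clusters found on the Hamming graph collapse into vertices of a directed
cluster graph G_C whose edge weights aggregate the de Bruijn (k+1)-mer
frequencies between member k-mers.  Candidate motifs are greedy paths in
G_C: starting from the uncovered cluster with the highest f score, the
path repeatedly extends along the heaviest available edge upstream or
downstream, capped at three added vertices per direction and a total
spelled length of max_len (default 18) nt.  Each path yields occurrence
sets O1 (upstream sub-path, start cluster included) and O2 (downstream
equivalent); their overlap ratio decides whether the path is reported as
one motif (whole path), two (O1 and O2 separately), or three (O1, O2 and
their intersection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np

from .clustering import KmerCluster
from .sequences import SequenceSet, reverse_complement

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class Occurrence(NamedTuple):
    """A motif site: 0-based half-open interval on the forward sequence."""

    seq_id: str
    start: int
    end: int
    strand: str
    word: str


@dataclass
class MotifPath:
    """A path of cluster ids with a marked start vertex."""

    vertices: list[int]
    start_index: int

    @property
    def upstream(self) -> list[int]:
        """Head .. start, start cluster included."""
        return self.vertices[: self.start_index + 1]

    @property
    def downstream(self) -> list[int]:
        """Start .. tail, start cluster included."""
        return self.vertices[self.start_index :]

    def spelled_length(self, k: int) -> int:
        return k + len(self.vertices) - 1


@dataclass
class MotifResult:
    """A discovered motif: consensus, PWM and its genomic occurrences."""

    name: str
    consensus: str
    pwm: np.ndarray  # (4, L) column-stochastic, rows A,C,G,T
    occurrences: list[Occurrence]
    source: str  # O1 | O2 | intersection | full-path

    @property
    def nsites(self) -> int:
        return len(self.occurrences)

    @property
    def length(self) -> int:
        return self.pwm.shape[1]

    def information_content(self) -> float:
        """Mean per-column information content in bits."""
        p = np.clip(self.pwm, 1e-12, 1.0)
        return float(np.mean(2.0 + np.sum(p * np.log2(p), axis=0)))


def build_cluster_digraph(
    dbg: nx.DiGraph, clusters: list[KmerCluster]
) -> nx.DiGraph:
    """Collapse clusters into vertices of a directed cluster graph.

    Each cluster becomes one vertex carrying its f score, seed and the
    member k-mers assigned to it.  K-mers outside every cluster (the
    insignificant tier and unclustered significant k-mers) are dropped;
    a k-mer claimed by several clusters goes to the one with the higher f
    (ties by lexicographic seed).  The edge c1 -> c2 sums the de Bruijn
    edge weights over all assigned member pairs; zero-weight edges are
    omitted.  Within-cluster de Bruijn edges become self-loops, recorded
    but never traversed during path extension.
    """
    if not clusters:
        raise ValueError("no clusters to collapse")
    ranked = sorted(clusters, key=lambda c: (-c.score, c.seed))
    assignment: dict[str, int] = {}
    for idx, c in enumerate(ranked):
        for kmer in c.members:
            assignment.setdefault(kmer, idx)

    gc = nx.DiGraph()
    assigned_members: dict[int, set[str]] = {}
    for kmer, idx in assignment.items():
        assigned_members.setdefault(idx, set()).add(kmer)
    for idx, c in enumerate(ranked):
        members = assigned_members.get(idx, set())
        if not members:
            continue  # every member claimed by a higher-f cluster
        gc.add_node(idx, f=c.score, seed=c.seed, members=frozenset(members))

    for u, v, data in dbg.edges(data=True):
        cu = assignment.get(u)
        cv = assignment.get(v)
        if cu is None or cv is None or cu not in gc or cv not in gc:
            continue
        w = data["weight"]
        if w <= 0:
            continue
        if gc.has_edge(cu, cv):
            gc[cu][cv]["weight"] += w
        else:
            gc.add_edge(cu, cv, weight=w)
    return gc


def _best_edge(gc: nx.DiGraph, edges, on_path: set[int]):
    """Heaviest admissible edge; ties broken by lexicographic target seed."""
    best = None
    for u, v, data in edges:
        cand = v if v not in on_path else u
        # for out_edges the candidate is v; for in_edges it is u
        if cand in on_path:
            continue
        key = (-data["weight"], gc.nodes[cand]["seed"])
        if best is None or key < best[0]:
            best = (key, cand, data["weight"])
    return best


def extend_paths(gc: nx.DiGraph, k: int, max_len: int = 18) -> list[MotifPath]:
    """Greedy path extension over the cluster digraph.

    Repeatedly start from the uncovered vertex with the highest f (ties by
    seed), then extend: each step considers the heaviest outgoing edge at
    the downstream end and the heaviest incoming edge at the upstream end,
    takes whichever is heavier (downstream on ties), and rejects a step if
    the candidate is already on the path, that direction already gained 3
    vertices, or the total added edges would exceed max_len - k.  When both
    directions are blocked the path is emitted and all its vertices are
    marked covered; the loop ends when every cluster vertex is covered.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    max_edges = max_len - k
    covered: set[int] = set()
    paths: list[MotifPath] = []

    while True:
        uncovered = [v for v in gc.nodes if v not in covered]
        if not uncovered:
            break
        start = min(
            uncovered, key=lambda v: (-gc.nodes[v]["f"], gc.nodes[v]["seed"])
        )
        path: list[int] = [start]
        on_path = {start}
        up_added = down_added = 0

        while True:
            cand_down = cand_up = None
            if down_added < 3 and len(path) - 1 < max_edges:
                cand_down = _best_edge(gc, gc.out_edges(path[-1], data=True), on_path)
            if up_added < 3 and len(path) - 1 < max_edges:
                cand_up = _best_edge(gc, gc.in_edges(path[0], data=True), on_path)
            if cand_down is None and cand_up is None:
                break
            take_down = cand_up is None or (
                cand_down is not None and cand_down[2] >= cand_up[2]
            )
            if take_down:
                path.append(cand_down[1])
                on_path.add(cand_down[1])
                down_added += 1
            else:
                path.insert(0, cand_up[1])
                on_path.add(cand_up[1])
                up_added += 1

        covered.update(on_path)
        paths.append(MotifPath(vertices=path, start_index=path.index(start)))
    return paths


def collect_occurrences(
    segment: list[int], gc: nx.DiGraph, seqs: SequenceSet, k: int
) -> list[Occurrence]:
    """Find all windows spelling the segment's cluster sequence.

    A window of length k + (len(segment) - 1) matches when its j-th
    length-k sub-window belongs to the j-th cluster's member set, for all
    j in order.  Both strands of every sequence are scanned; minus-strand
    matches are reported in forward coordinates with strand '-'.
    Overlapping matches at different offsets are all kept.
    """
    if not segment:
        raise ValueError("empty path segment")
    member_sets = [gc.nodes[c]["members"] for c in segment]
    L = k + len(segment) - 1
    out: list[Occurrence] = []
    for seq_id, seq in seqs:
        n = len(seq)
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            for off in range(n - L + 1):
                window = s[off : off + L]
                if all(
                    window[j : j + k] in member_sets[j]
                    for j in range(len(segment))
                ):
                    if strand == "+":
                        out.append(Occurrence(seq_id, off, off + L, "+", window))
                    else:
                        out.append(
                            Occurrence(seq_id, n - off - L, n - off, "-", window)
                        )
    return out


def _intervals_overlap(a: Occurrence, b: Occurrence) -> bool:
    return (
        a.seq_id == b.seq_id
        and a.strand == b.strand
        and a.start < b.end
        and b.start < a.end
    )


def occurrence_overlap(
    o1: list[Occurrence], o2: list[Occurrence]
) -> tuple[float, list[Occurrence]]:
    """Overlap ratio r = |O1 n O2| / min(|O1|, |O2|) and the shared sites.

    Membership in the intersection: an element of the smaller set counts
    when it overlaps (same sequence and strand, intersecting intervals) at
    least one element of the other set; those elements are returned as the
    intersection occurrence set.  Either set empty gives r = 0.
    """
    if not o1 or not o2:
        return 0.0, []
    smaller, other = (o1, o2) if len(o1) <= len(o2) else (o2, o1)
    by_key: dict[tuple[str, str], list[Occurrence]] = {}
    for occ in other:
        by_key.setdefault((occ.seq_id, occ.strand), []).append(occ)
    shared = [
        occ
        for occ in smaller
        if any(
            _intervals_overlap(occ, cand)
            for cand in by_key.get((occ.seq_id, occ.strand), ())
        )
    ]
    return len(shared) / len(smaller), shared


def build_pwm(
    occurrences: list[Occurrence],
    pseudocount: float = 0.25,
    name: str = "motif",
    source: str = "full-path",
) -> MotifResult:
    """Estimate a PWM and consensus from aligned occurrence words.

    Column probability of base b is (count + pseudocount) /
    (nsites + 4 * pseudocount); the consensus takes the per-column argmax
    base with ties resolved in A < C < G < T order.
    """
    if not occurrences:
        raise ValueError("cannot build a PWM from an empty occurrence set")
    L = len(occurrences[0].word)
    if any(len(o.word) != L for o in occurrences):
        raise ValueError("occurrence words differ in length")
    counts = np.zeros((4, L))
    for occ in occurrences:
        for j, b in enumerate(occ.word):
            if b in BASE_INDEX:
                counts[BASE_INDEX[b], j] += 1
    pwm = (counts + pseudocount) / (counts.sum(axis=0, keepdims=True) + 4 * pseudocount)
    consensus = "".join(BASES[int(np.argmax(pwm[:, j]))] for j in range(L))
    return MotifResult(
        name=name, consensus=consensus, pwm=pwm, occurrences=list(occurrences),
        source=source,
    )


def refine_motifs(
    path: MotifPath,
    o1: list[Occurrence],
    o2: list[Occurrence],
    full_occurrences: list[Occurrence],
    name_prefix: str = "motif",
    pseudocount: float = 0.25,
) -> list[MotifResult]:
    """Decide how many motifs a path yields from the O1/O2 overlap ratio r.

    r > 1/2: one motif from the whole path's occurrences.  1/4 < r <= 1/2:
    three motifs, from O1, O2 and their intersection.  r <= 1/4: two
    motifs, from O1 and O2.  Branches whose occurrence set is empty are
    dropped rather than reported as empty motifs.
    """
    r, shared = occurrence_overlap(o1, o2)
    if r > 0.5:
        candidates = [("full-path", full_occurrences)]
    elif r > 0.25:
        candidates = [("O1", o1), ("O2", o2), ("intersection", shared)]
    else:
        candidates = [("O1", o1), ("O2", o2)]
    motifs = []
    for source, occs in candidates:
        if occs:
            motifs.append(
                build_pwm(
                    occs,
                    pseudocount=pseudocount,
                    name=f"{name_prefix}_{source}",
                    source=source,
                )
            )
    return motifs


def write_meme(
    motifs: list[MotifResult], path, background: np.ndarray | None = None
) -> None:
    """Write motifs in MEME minimal motif format."""
    bg = background if background is not None else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*(float(x) for x in bg))
        )
        for m in motifs:
            fh.write(f"MOTIF {m.name} {m.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.length} "
                f"nsites= {m.nsites} E= 0\n"
            )
            for j in range(m.length):
                fh.write(" ".join(f"{m.pwm[i, j]:.6f}" for i in range(4)) + "\n")
            fh.write("\n")


def write_sites_bed(motifs: list[MotifResult], path) -> None:
    """Write motif sites as BED6; score is the mean column information content."""
    with open(path, "w") as fh:
        for m in motifs:
            score = m.information_content()
            for occ in sorted(m.occurrences):
                fh.write(
                    f"{occ.seq_id}\t{occ.start}\t{occ.end}\t{m.name}\t"
                    f"{score:.4f}\t{occ.strand}\n"
                )
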