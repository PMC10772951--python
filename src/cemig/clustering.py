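"""Seeded clustering of k-mers on the Hamming-distance graph.

Cluster seeds are a greedy maximal independent set drawn from the
highly-significant tier K1, so seeds are mutually non-adjacent (no two
seeds one substitution apart).  Each seed grows a cluster C by
hill-climbing the objective

    f(C) = [ -sum_{{u,v} in E(G), u,v in C} w(u,v)^-1 * log(p(u) p(v)) ]
           / ( |C| (|C|-1) ) * log(|C|)

(natural log; p(u) is the k-mer's Poisson P-value; the pair sum runs over
adjacent member pairs).  f rewards densely connected sets of individually
significant k-mers while the |C|(|C|-1) normalisation and log|C| factor
balance cluster size.  A singleton's f is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx


@dataclass
class IndependentSet:
    """Greedy maximal independent set, in insertion order."""

    members: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.members)

    def __len__(self):
        return len(self.members)


@dataclass
class KmerCluster:
    """A connected cluster of k-mers grown from a seed on the Hamming graph."""

    seed: str
    members: frozenset[str]
    score: float

    def __len__(self):
        return len(self.members)


def greedy_independent_set(g: nx.Graph, k1: list[str]) -> IndependentSet:
    """Scan k1 in order, keeping each k-mer with no kept neighbour.

    k1 must be sorted by decreasing significance; every k1 k-mer must be a
    vertex of g.  The result is independent and maximal with respect to k1
    under the insertion order.
    """
    chosen: list[str] = []
    chosen_set: set[str] = set()
    for v in k1:
        if v not in g:
            raise ValueError(f"K1 k-mer {v!r} missing from the Hamming graph")
        if not any(nb in chosen_set for nb in g[v]):
            chosen.append(v)
            chosen_set.add(v)
    return IndependentSet(chosen)


def _neglogp(pvalues: dict[str, float], u: str) -> float:
    p = pvalues[u]
    if p <= 0:
        raise ValueError(f"non-positive P-value for {u!r}")
    return -math.log(p)


def eval_f(members, g: nx.Graph, pvalues: dict[str, float]) -> float:
    """Cluster objective f(C); 0 for a singleton."""
    members = set(members)
    m = len(members)
    if m < 1:
        raise ValueError("empty cluster")
    if m == 1:
        return 0.0
    s = 0.0
    for u, v, data in g.subgraph(members).edges(data=True):
        w = data.get("weight", 1)
        s += (1.0 / w) * (_neglogp(pvalues, u) + _neglogp(pvalues, v))
    return s / (m * (m - 1)) * math.log(m)


class _ClusterState:
    """Incremental f(C) bookkeeping: edge sum updated per added/removed vertex."""

    def __init__(self, g: nx.Graph, pvalues: dict[str, float]):
        self.g = g
        self.nlp = {u: _neglogp(pvalues, u) for u in g}
        self.members: set[str] = set()
        self.edge_sum = 0.0

    def f(self) -> float:
        m = len(self.members)
        if m <= 1:
            return 0.0
        return self.edge_sum / (m * (m - 1)) * math.log(m)

    def delta_sum(self, x: str) -> float:
        """Edge-sum change from adding x (or negated, from removing it)."""
        s = 0.0
        for nb, data in self.g[x].items():
            if nb in self.members and nb != x:
                s += (1.0 / data.get("weight", 1)) * (self.nlp[x] + self.nlp[nb])
        return s

    def f_with(self, x: str) -> float:
        m = len(self.members) + 1
        s = self.edge_sum + self.delta_sum(x)
        return 0.0 if m <= 1 else s / (m * (m - 1)) * math.log(m)

    def f_without(self, x: str) -> float:
        m = len(self.members) - 1
        s = self.edge_sum - self.delta_sum(x)
        return 0.0 if m <= 1 else s / (m * (m - 1)) * math.log(m)

    def add(self, x: str) -> None:
        self.edge_sum += self.delta_sum(x)
        self.members.add(x)

    def remove(self, x: str) -> None:
        self.members.remove(x)
        self.edge_sum -= self.delta_sum(x)


def grow_cluster(seed: str, g: nx.Graph, pvalues: dict[str, float]) -> KmerCluster:
    """Grow a cluster from a seed by local search on f.

    Initialisation takes the seed plus the pair of its neighbours that
    maximises f (all available neighbours when fewer than two exist).  Then
    single-vertex moves are applied until none improves f: an add phase
    admitting the boundary neighbour with the largest strict increase, and
    a remove phase evicting the non-seed member whose removal most
    increases f while keeping the cluster connected and seed-containing.
    Ties break by lexicographic k-mer order.  f strictly increases on every
    accepted move, so the search terminates.
    """
    if seed not in g:
        raise ValueError(f"seed {seed!r} not in graph")
    state = _ClusterState(g, pvalues)
    state.add(seed)

    neighbors = sorted(g[seed])
    if len(neighbors) <= 2:
        for nb in neighbors:
            state.add(nb)
    else:
        best_pair, best_f = None, -math.inf
        for i in range(len(neighbors)):
            state.add(neighbors[i])
            for j in range(i + 1, len(neighbors)):
                fij = state.f_with(neighbors[j])
                if fij > best_f:
                    best_f = fij
                    best_pair = (neighbors[i], neighbors[j])
            state.remove(neighbors[i])
        state.add(best_pair[0])
        state.add(best_pair[1])

    while True:
        changed = False

        # add phase: best strictly improving boundary neighbour
        boundary = sorted(
            {nb for u in state.members for nb in g[u]} - state.members
        )
        cur = state.f()
        best_x, best_f = None, cur
        for x in boundary:
            fx = state.f_with(x)
            if fx > best_f:
                best_f, best_x = fx, x
        if best_x is not None:
            state.add(best_x)
            changed = True

        # remove phase: best strictly improving eviction keeping the seed
        # and connectivity
        cur = state.f()
        best_x, best_f = None, cur
        for x in sorted(state.members):
            if x == seed:
                continue
            fx = state.f_without(x)
            if fx > best_f:
                rest = state.members - {x}
                if nx.is_connected(g.subgraph(rest)):
                    best_f, best_x = fx, x
        if best_x is not None:
            state.remove(best_x)
            changed = True

        if not changed:
            break

    return KmerCluster(seed=seed, members=frozenset(state.members), score=state.f())


def cluster_all(
    g: nx.Graph, is_set: IndependentSet, pvalues: dict[str, float]
) -> list[KmerCluster]:
    """Grow one cluster per independent-set seed; sort by decreasing f.

    Clusters are grown independently, so a k-mer may belong to several;
    overlaps are resolved later when clusters collapse into digraph
    vertices.  Ties in f break by lexicographic seed order.
    """
    clusters = [grow_cluster(seed, g, pvalues) for seed in is_set]
    clusters.sort(key=lambda c: (-c.score, c.seed))
    return clusters


def clusters_to_tsv(clusters: list[KmerCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tseed\tf_score\tn_members\tmembers\n")
        for i, c in enumerate(clusters):
            fh.write(
                f"{i}\t{c.seed}\t{c.score:.6g}\t{len(c)}\t{','.join(sorted(c.members))}\n"
            )
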