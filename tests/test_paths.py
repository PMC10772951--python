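import itertools

import networkx as nx
import numpy as np
import pytest

import cemig
from cemig.clustering import KmerCluster
from cemig.paths import Occurrence
from cemig.sequences import reverse_complement

from conftest import random_sequence_set


def make_gc(nodes, edges):
    """nodes: {id: (f, seed, members)}; edges: {(u, v): weight}."""
    gc = nx.DiGraph()
    for nid, (f, seed, members) in nodes.items():
        gc.add_node(nid, f=f, seed=seed, members=frozenset(members))
    for (u, v), w in edges.items():
        gc.add_edge(u, v, weight=w)
    return gc


class TestBuildClusterDigraph:
    def test_singleton_clusters_inherit_dbg_edge(self):
        dbg = nx.DiGraph()
        dbg.add_edge("AGCTAG", "GCTAGC", weight=7)
        clusters = [
            KmerCluster("AGCTAG", frozenset({"AGCTAG"}), 2.0),
            KmerCluster("GCTAGC", frozenset({"GCTAGC"}), 1.0),
        ]
        gc = cemig.build_cluster_digraph(dbg, clusters)
        assert gc.number_of_nodes() == 2
        (u, v, d), = gc.edges(data=True)
        assert d["weight"] == 7

    def test_parallel_member_edges_sum(self):
        dbg = nx.DiGraph()
        dbg.add_edge("AAAAAA", "AAAAAC", weight=3)
        dbg.add_edge("AAAAAT", "AAAACG", weight=4)
        clusters = [
            KmerCluster("AAAAAA", frozenset({"AAAAAA", "AAAAAT"}), 2.0),
            KmerCluster("AAAAAC", frozenset({"AAAAAC", "AAAACG"}), 1.0),
        ]
        gc = cemig.build_cluster_digraph(dbg, clusters)
        (u, v, d), = gc.edges(data=True)
        assert d["weight"] == 3 + 4

    def test_shared_kmer_goes_to_higher_f_cluster(self):
        dbg = nx.DiGraph()
        clusters = [
            KmerCluster("AAA", frozenset({"AAA", "AAT"}), 1.0),
            KmerCluster("ATT", frozenset({"ATT", "AAT"}), 5.0),
        ]
        gc = cemig.build_cluster_digraph(dbg, clusters)
        members = {gc.nodes[n]["seed"]: gc.nodes[n]["members"] for n in gc.nodes}
        assert "AAT" in members["ATT"]
        assert "AAT" not in members["AAA"]

    def test_weights_match_member_pair_oracle(self):
        rng = np.random.default_rng(61)
        ss = random_sequence_set(rng, 10, 60)
        k = 4
        kmers = sorted({km for km, *_ in cemig.iter_kmers(ss, k, both_strands=True)})
        dbg = cemig.build_debruijn_graph(ss, set(kmers), k)
        # partition kmers into random clusters of ~8
        rng.shuffle(kmers)
        clusters = [
            KmerCluster(
                seed=min(chunk), members=frozenset(chunk), score=float(10 - i)
            )
            for i, chunk in enumerate(
                [kmers[j : j + 8] for j in range(0, len(kmers), 8)]
            )
        ]
        gc = cemig.build_cluster_digraph(dbg, clusters)
        for cu, cv, d in gc.edges(data=True):
            expected = sum(
                dbg[u][v]["weight"]
                for u in gc.nodes[cu]["members"]
                for v in gc.nodes[cv]["members"]
                if dbg.has_edge(u, v)
            )
            assert d["weight"] == expected


class TestExtendPaths:
    def test_isolated_vertex_gives_length_one_path(self):
        gc = make_gc({0: (1.0, "AAAAAA", {"AAAAAA"})}, {})
        paths = cemig.extend_paths(gc, k=6)
        assert len(paths) == 1
        assert paths[0].vertices == [0]
        assert paths[0].spelled_length(6) == 6

    def test_chain_takes_three_each_direction(self):
        nodes = {
            i: (10.0 if i == 3 else 1.0, f"S{i}AAAA", {f"S{i}"}) for i in range(7)
        }
        edges = {
            (0, 1): 5, (1, 2): 7, (2, 3): 9, (3, 4): 10, (4, 5): 8, (5, 6): 6,
        }
        gc = make_gc(nodes, edges)
        paths = cemig.extend_paths(gc, k=6)
        assert paths[0].vertices == [0, 1, 2, 3, 4, 5, 6]
        assert paths[0].start_index == 3
        assert paths[0].spelled_length(6) == 12  # 6 edges <= 18 - 6

    def test_direction_cap_of_three(self):
        # a long downstream chain: only 3 vertices may be added downstream
        nodes = {i: (10.0 if i == 0 else 1.0, f"S{i}", {f"S{i}"}) for i in range(6)}
        edges = {(i, i + 1): 10 - i for i in range(5)}
        gc = make_gc(nodes, edges)
        paths = cemig.extend_paths(gc, k=6)
        assert paths[0].vertices == [0, 1, 2, 3]

    def test_total_edge_cap_limits_spelled_length(self):
        # star-free chain with k=4: cap is 18 - 4 = 14 edges, but the
        # 3-per-direction cap binds first (6 edges max)
        nodes = {i: (10.0 if i == 5 else 1.0, f"S{i}", {f"S{i}"}) for i in range(11)}
        edges = {(i, i + 1): 100 - i for i in range(10)}
        gc = make_gc(nodes, edges)
        paths = cemig.extend_paths(gc, k=4)
        assert len(paths[0].vertices) == 7
        assert paths[0].spelled_length(4) <= 18

    def test_all_vertices_covered(self, discovery_result):
        gc = discovery_result.cluster_digraph
        paths = discovery_result.motif_paths
        covered = {v for p in paths for v in p.vertices}
        assert covered == set(gc.nodes)
        assert len(paths) <= gc.number_of_nodes()


class TestCollectOccurrences:
    def test_singleton_direct_match(self):
        gc = make_gc({0: (1.0, "ACGTAC", {"ACGTAC"})}, {})
        ss = cemig.SequenceSet([("s", "TTTACGTACTT")])
        occs = cemig.collect_occurrences([0], gc, ss, 6)
        assert Occurrence("s", 3, 9, "+", "ACGTAC") in occs
        # the reverse complement GTACGT appears on the minus strand
        assert all(o.end - o.start == 6 for o in occs)

    def test_two_cluster_segment_spells_seven_mer(self):
        gc = make_gc(
            {0: (2.0, "AGCTAG", {"AGCTAG"}), 1: (1.0, "GCTAGC", {"GCTAGC"})},
            {(0, 1): 1},
        )
        ss = cemig.SequenceSet([("s", "TTAGCTAGCTT")])
        occs = cemig.collect_occurrences([0, 1], gc, ss, 6)
        plus = [o for o in occs if o.strand == "+"]
        assert plus == [Occurrence("s", 2, 9, "+", "AGCTAGC")]

    def test_matches_exhaustive_window_oracle(self):
        rng = np.random.default_rng(67)
        ss = random_sequence_set(rng, 8, 40)
        k = 3
        kmers = sorted({km for km, *_ in cemig.iter_kmers(ss, k)})
        members = [frozenset(kmers[::3]), frozenset(kmers[1::3])]
        gc = make_gc(
            {0: (2.0, "AAA", members[0]), 1: (1.0, "AAC", members[1])},
            {(0, 1): 1},
        )
        segment = [0, 1]
        L = k + 1
        got = set(cemig.collect_occurrences(segment, gc, ss, k))
        expected = set()
        for sid, seq in ss:
            n = len(seq)
            for off in range(n - L + 1):
                w = seq[off : off + L]
                if w[:k] in members[0] and w[1 : 1 + k] in members[1]:
                    expected.add(Occurrence(sid, off, off + L, "+", w))
                rc = reverse_complement(w)
                if rc[:k] in members[0] and rc[1 : 1 + k] in members[1]:
                    expected.add(Occurrence(sid, off, off + L, "-", rc))
        assert got == expected


def occ_run(seq_ids, start=0, length=6, strand="+"):
    return [
        Occurrence(sid, start, start + length, strand, "A" * length)
        for sid in seq_ids
    ]


class TestRefineMotifs:
    """Branch counts across the three overlap regimes, boundaries included."""

    @staticmethod
    def make_sets(n1, n2, n_shared):
        # shared elements overlap on the same sequences; the rest live on
        # disjoint sequence namespaces
        o1 = occ_run([f"s{i}" for i in range(n1)], length=6)
        o2 = occ_run(
            [f"s{i}" for i in range(n_shared)]
            + [f"t{i}" for i in range(n2 - n_shared)],
            length=7,
        )
        return o1, o2

    @pytest.mark.parametrize(
        "n_shared,expected_count,expected_sources",
        [
            (6, 1, {"full-path"}),            # r = 0.75 > 1/2
            (3, 3, {"O1", "O2", "intersection"}),  # r = 0.375
            (4, 3, {"O1", "O2", "intersection"}),  # boundary r = 1/2
            (2, 2, {"O1", "O2"}),             # boundary r = 1/4
            (1, 2, {"O1", "O2"}),             # r = 0.125
            (0, 2, {"O1", "O2"}),             # disjoint
        ],
    )
    def test_branch_counts(self, n_shared, expected_count, expected_sources):
        o1, o2 = self.make_sets(10, 8, n_shared)
        path = cemig.MotifPath(vertices=[0, 1], start_index=0)
        full = occ_run(["f0", "f1"], length=8)
        motifs = cemig.refine_motifs(path, o1, o2, full)
        assert len(motifs) == expected_count
        assert {m.source for m in motifs} == expected_sources

    def test_empty_side_treated_as_zero_overlap(self):
        o1 = occ_run(["s0", "s1"])
        path = cemig.MotifPath(vertices=[0], start_index=0)
        motifs = cemig.refine_motifs(path, o1, [], o1)
        assert {m.source for m in motifs} == {"O1"}

    def test_overlap_ratio_values(self):
        o1, o2 = self.make_sets(10, 8, 6)
        r, shared = cemig.occurrence_overlap(o1, o2)
        assert r == pytest.approx(6 / 8)
        assert len(shared) == 6
        assert cemig.occurrence_overlap([], o2) == (0.0, [])


class TestBuildPwm:
    def test_indicator_columns(self):
        occs = occ_run(["a", "b", "c", "d"], length=3)
        occs = [o._replace(word="ACG") for o in occs]
        m = cemig.build_pwm(occs, pseudocount=0.0)
        assert m.consensus == "ACG"
        assert np.allclose(m.pwm[:, 0], [1, 0, 0, 0])
        assert np.allclose(m.pwm.sum(axis=0), 1.0)

    def test_tie_breaks_toward_earlier_base(self):
        occs = [
            Occurrence("a", 0, 2, "+", "AA"),
            Occurrence("b", 0, 2, "+", "AC"),
        ]
        m = cemig.build_pwm(occs, pseudocount=0.0)
        assert np.allclose(m.pwm[:, 1], [0.5, 0.5, 0, 0])
        assert m.consensus == "AA"

    def test_matches_hand_tally_with_pseudocount(self):
        rng = np.random.default_rng(71)
        words = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(10)]
        occs = [Occurrence(f"s{i}", 0, 5, "+", w) for i, w in enumerate(words)]
        m = cemig.build_pwm(occs, pseudocount=0.25)
        for j in range(5):
            for bi, b in enumerate("ACGT"):
                cnt = sum(1 for w in words if w[j] == b)
                assert m.pwm[bi, j] == pytest.approx((cnt + 0.25) / (10 + 1.0))
        assert np.allclose(m.pwm.sum(axis=0), 1.0, atol=1e-9)

    def test_empty_occurrences_error(self):
        with pytest.raises(ValueError):
            cemig.build_pwm([])


class TestOutputs:
    def test_meme_format(self, tmp_path, discovery_result):
        out = tmp_path / "m.meme"
        discovery_result.write_meme(out)
        text = out.read_text()
        assert text.startswith("MEME version 4")
        assert "ALPHABET= ACGT" in text
        assert "strands: + -" in text
        assert text.count("MOTIF ") == len(discovery_result.motifs)
        for m in discovery_result.motifs:
            assert f"w= {m.length} nsites= {m.nsites}" in text

    def test_sites_bed_columns(self, tmp_path, discovery_result):
        out = tmp_path / "s.bed"
        discovery_result.write_sites_bed(out)
        for line in out.read_text().splitlines():
            fields = line.split("\t")
            assert len(fields) == 6
            assert int(fields[2]) > int(fields[1])
            assert fields[5] in "+-"

    def test_motif_lengths_bounded(self, discovery_result):
        for m in discovery_result.motifs:
            assert 6 <= m.length <= 18
            assert np.allclose(m.pwm.sum(axis=0), 1.0, atol=1e-9)
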