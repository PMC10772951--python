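"""End-to-end motif discovery pipeline.

Wires the stages together: Markov background estimation and Poisson k-mer
scoring, tier partitioning, Hamming and de Bruijn graph construction,
independent-set seeded clustering, cluster-digraph path extension, and
occurrence-overlap refinement into PWMs and site lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from . import background, clustering, graphs, paths
from .sequences import SequenceSet

log = logging.getLogger(__name__)


@dataclass
class DiscoveryResult:
    """Everything a discovery run produced, from k-mer table to motifs."""

    motifs: list[paths.MotifResult]
    kmer_table: background.KmerTable
    model: background.BackgroundModel
    clusters: list[clustering.KmerCluster]
    motif_paths: list[paths.MotifPath] = field(repr=False)
    cluster_digraph: nx.DiGraph = field(repr=False, default=None)

    def write_meme(self, path) -> None:
        paths.write_meme(self.motifs, path, background=self.model.M1)

    def write_sites_bed(self, path) -> None:
        paths.write_sites_bed(self.motifs, path)

    def write_all(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.write_meme(out_dir / "motifs.meme")
        self.write_sites_bed(out_dir / "sites.bed")
        self.kmer_table.to_tsv(out_dir / "kmers.tsv")
        clustering.clusters_to_tsv(self.clusters, out_dir / "clusters.tsv")


def discover(
    seqs: SequenceSet,
    k: int = 6,
    markov_order: int = 2,
    top_k1: int = 100,
    max_len: int = 18,
    background_pseudocount: float = 0.5,
    pwm_pseudocount: float = 0.25,
) -> DiscoveryResult:
    """Run the full motif discovery pipeline on a sequence set.

    Parameters
    ----------
    seqs : input sequences (footprints or peaks).
    k : word length for enrichment scoring and graph construction.
    markov_order : background Markov order (0-2).
    top_k1 : size of the highly-significant seed tier.
    max_len : maximum spelled motif length in nt; paths stop at
        max_len - k added edges.
    """
    model = background.estimate_background(
        seqs, order=markov_order, pseudocount=background_pseudocount
    )
    table = background.build_kmer_table(seqs, model, k=k, top_k1=top_k1)
    log.info(
        "k-mer table: %d distinct %d-mers (|K1|=%d, |K2|=%d, |K3|=%d)",
        len(table.order), k, len(table.k1), len(table.k2), len(table.k3),
    )

    hg = graphs.build_hamming_graph(table.k2)
    is_set = clustering.greedy_independent_set(hg, table.k1)
    clusters = clustering.cluster_all(hg, is_set, table.pvalue)
    log.info("%d seeds -> %d clusters", len(is_set), len(clusters))

    dbg = graphs.build_debruijn_graph(seqs, set(table.k2) | set(table.k3), k)
    gc = paths.build_cluster_digraph(dbg, clusters)
    motif_paths = paths.extend_paths(gc, k, max_len=max_len)
    log.info("%d cluster vertices -> %d paths", gc.number_of_nodes(), len(motif_paths))

    motifs: list[paths.MotifResult] = []
    for i, mp in enumerate(motif_paths):
        o1 = paths.collect_occurrences(mp.upstream, gc, seqs, k)
        o2 = paths.collect_occurrences(mp.downstream, gc, seqs, k)
        full = (
            o1
            if len(mp.vertices) == 1
            else paths.collect_occurrences(mp.vertices, gc, seqs, k)
        )
        motifs.extend(
            paths.refine_motifs(
                mp, o1, o2, full,
                name_prefix=f"path{i}", pseudocount=pwm_pseudocount,
            )
        )
    log.info("%d motifs reported", len(motifs))
    return DiscoveryResult(
        motifs=motifs,
        kmer_table=table,
        model=model,
        clusters=clusters,
        motif_paths=motif_paths,
        cluster_digraph=gc,
    )
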