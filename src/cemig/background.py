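"""Markov background model, Poisson k-mer enrichment and significance tiers.

The expected count of a k-mer t = a1 a2 ... ak under the background is the
Markov chain product

    lambda(t) = M1(a1) * M2(a2|a1) * M3(a3|a1 a2) * ... * M3(ak|a(k-2) a(k-1))
                * total_positions

where M1/M2/M3 are the mono-, di- and tri-nucleotide frequency matrices
estimated from the input sequences themselves.  Enrichment of the observed
count n(t) over lambda(t) is scored with the Poisson upper tail

    P(t) = Pr[X >= n(t)]  with  X ~ Poisson(lambda(t)).

K-mers ranked by -log10 P(t) are split into three tiers: K1 (the highly
significant top 100), K2 (the significant top half) and K3 (the rest).
K1 seeds the Hamming-graph clustering; K2 forms the Hamming graph's
vertices; K2 and K3 together form the de Bruijn graph's vertices.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sequences import SequenceSet, iter_kmers

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DINUCS = [a + b for a in BASES for b in BASES]
DINUC_INDEX = {d: i for i, d in enumerate(DINUCS)}

# smallest positive normal double; floor for P-values before taking logs
_TINY = np.finfo(np.float64).tiny


@dataclass
class BackgroundModel:
    """Markov background of order 0-2 over {A,C,G,T}.

    M1 : (4,) marginal nucleotide probabilities.
    M2 : (4,4) conditional P(a2 | a1), rows indexed by a1.
    M3 : (16,4) conditional P(a3 | a1 a2), rows indexed by the dinucleotide.

    For order 0, M2 rows equal M1 and M3 rows equal M1; for order 1,
    M3(a3 | a1 a2) collapses to M2(a3 | a2).
    """

    M1: np.ndarray
    M2: np.ndarray
    M3: np.ndarray
    order: int
    pseudocount: float

    def __post_init__(self) -> None:
        assert self.M1.shape == (4,)
        assert self.M2.shape == (4, 4)
        assert self.M3.shape == (16, 4)


def estimate_background(
    seqs: SequenceSet, order: int = 2, pseudocount: float = 0.5
) -> BackgroundModel:
    """Estimate M1/M2/M3 from substring frequencies of lengths 1-3.

    Counts are taken over forward strands; a pseudocount is added to every
    cell before normalization.  Windows containing N are skipped.
    """
    if order not in (0, 1, 2):
        raise ValueError(f"Markov order must be 0, 1 or 2, got {order}")
    if seqs.n == 0:
        raise ValueError("cannot estimate a background from an empty sequence set")

    c1 = np.full(4, pseudocount)
    c2 = np.full((4, 4), pseudocount)
    c3 = np.full((16, 4), pseudocount)
    for _, seq in seqs:
        for i, b in enumerate(seq):
            if b == "N":
                continue
            c1[BASE_INDEX[b]] += 1
            if i + 1 < len(seq) and seq[i + 1] != "N":
                c2[BASE_INDEX[b], BASE_INDEX[seq[i + 1]]] += 1
                if i + 2 < len(seq) and seq[i + 2] != "N":
                    c3[DINUC_INDEX[seq[i : i + 2]], BASE_INDEX[seq[i + 2]]] += 1

    if c1.sum() == 0:
        raise ValueError("no unambiguous nucleotides in input")

    def _normalize_rows(c: np.ndarray) -> np.ndarray:
        sums = c.sum(axis=1, keepdims=True)
        # contexts never observed (possible only at pseudocount 0) get a
        # uniform row rather than 0/0
        out = np.where(sums > 0, c, 0.25)
        return out / out.sum(axis=1, keepdims=True)

    M1 = c1 / c1.sum()
    M2 = _normalize_rows(c2)
    M3 = _normalize_rows(c3)

    if order == 0:
        M2 = np.tile(M1, (4, 1))
        M3 = np.tile(M1, (16, 1))
    elif order == 1:
        # P(a3 | a1 a2) -> P(a3 | a2): row a1a2 becomes the M2 row of a2
        M3 = np.vstack([M2[DINUC_INDEX[d] % 4] for d in DINUCS])
    return BackgroundModel(M1=M1, M2=M2, M3=M3, order=order, pseudocount=pseudocount)


def expected_count(model: BackgroundModel, t: str, total_positions: int) -> float:
    """Expected background count lambda(t) of k-mer t.

    The chain is M1(a1) * M2(a2|a1) * prod_{j>=3} M3(aj | a(j-2) a(j-1)),
    scaled by the number of available positions.  For k = 2 the M3 factors
    are absent.
    """
    k = len(t)
    if k < 2:
        raise ValueError("expected_count requires k >= 2")
    if total_positions < 0:
        raise ValueError("total_positions must be >= 0")
    p = model.M1[BASE_INDEX[t[0]]] * model.M2[BASE_INDEX[t[0]], BASE_INDEX[t[1]]]
    for j in range(2, k):
        p *= model.M3[DINUC_INDEX[t[j - 2 : j]], BASE_INDEX[t[j]]]
    return float(p * total_positions)


def poisson_pvalue(n_t: int, lam: float) -> float:
    """Upper-tail Poisson probability Pr[X >= n_t] at mean lam.

    Equals 1 - sum_{x=0}^{n_t-1} e^{-lam} lam^x / x! (an empty sum for
    n_t = 0, hence P = 1).  Computed with the survival function for
    numerical stability and clipped to [tiny, 1].
    """
    if n_t < 0 or lam < 0:
        raise ValueError("n_t and lam must be non-negative")
    if n_t == 0:
        return 1.0
    p = float(stats.poisson.sf(n_t - 1, lam))
    return float(min(max(p, _TINY), 1.0))


@dataclass
class KmerTable:
    """Per-k-mer counts, expected counts, P-values and tier labels.

    ``order`` lists k-mers by decreasing -log10 P (ties lexicographic);
    K1 is a prefix of K2, which is a prefix of the full ranking.
    """

    k: int
    counts: dict[str, int]
    lam: dict[str, float]
    pvalue: dict[str, float]
    neglogp: dict[str, float]
    order: list[str] = field(repr=False)
    k1: list[str] = field(repr=False)
    k2: list[str] = field(repr=False)
    k3: list[str] = field(repr=False)

    def tier(self, kmer: str) -> str:
        if kmer in self._k1set:
            return "K1"
        if kmer in self._k2set:
            return "K2"
        return "K3"

    def __post_init__(self) -> None:
        self._k1set = frozenset(self.k1)
        self._k2set = frozenset(self.k2)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "kmer": t,
                "count": self.counts[t],
                "lambda": self.lam[t],
                "pvalue": self.pvalue[t],
                "neglog10p": self.neglogp[t],
                "tier": self.tier(t),
            }
            for t in self.order
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def count_kmers(seqs: SequenceSet, k: int, both_strands: bool = True) -> Counter:
    """Count N-free length-k windows, optionally over both strands."""
    counts: Counter = Counter()
    for kmer, _, _, _ in iter_kmers(seqs, k, both_strands=both_strands):
        counts[kmer] += 1
    return counts


def build_kmer_table(
    seqs: SequenceSet, model: BackgroundModel, k: int = 6, top_k1: int = 100
) -> KmerTable:
    """Score every observed k-mer and partition into tiers K1/K2/K3.

    Counts n(t) accumulate over both strands, and the position total in
    lambda(t) is doubled to match, so observed and expected counts are on
    the same two-strand scale.  Ranking is by decreasing -log10 P with
    lexicographic tie-breaks; K2 is the top ceil(total/2) k-mers and K1 the
    top min(top_k1, |K2|).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = count_kmers(seqs, k, both_strands=True)
    if not counts:
        raise ValueError(f"no {k}-mers observed in input")
    total = 2 * seqs.total_positions(k)

    lam: dict[str, float] = {}
    pval: dict[str, float] = {}
    nlp: dict[str, float] = {}
    for t, n_t in counts.items():
        lam[t] = expected_count(model, t, total)
        pval[t] = poisson_pvalue(n_t, lam[t])
        nlp[t] = -math.log10(pval[t])

    order = sorted(counts, key=lambda t: (-nlp[t], t))
    n_k2 = math.ceil(len(order) / 2)
    n_k1 = min(top_k1, n_k2)
    return KmerTable(
        k=k,
        counts=dict(counts),
        lam=lam,
        pvalue=pval,
        neglogp=nlp,
        order=order,
        k1=order[:n_k1],
        k2=order[:n_k2],
        k3=order[n_k2:],
    )
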