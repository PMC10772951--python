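"""Synthetic sequence sets with planted motif instances and known truth.

The generator draws background sequences from a Markov process of order
0-2 and implants a mutated copy of a consensus motif into a random subset
of sequences, recording the exact implanted intervals and strands.  It is
the ground-truth harness for every downstream stage: enrichment scoring,
clustering, path assembly and site-level scoring can all be checked
against the planted sites without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .background import BackgroundModel
from .paths import MotifResult
from .sequences import SequenceSet, VALID_ALPHABET, reverse_complement

BASES = "ACGT"


class TruthSite(NamedTuple):
    seq_id: str
    start: int
    end: int
    strand: str


@dataclass
class PlantSpec:
    """Parameters of a planted-motif dataset.

    motif_consensus : the planted pattern (4-18 nt over ACGT).
    instance_rate : fraction of sequences receiving one instance.
    mutation_rate : per-position probability of substituting the planted
        base with one of the three others (must be < 0.75; at 0.75 the
        implant is indistinguishable from uniform background).
    background_order : Markov order of the background (0-2); transition
        probabilities come from ``background_model`` (uniform if None).
    """

    motif_consensus: str
    instance_rate: float = 0.3
    mutation_rate: float = 0.1
    n_sequences: int = 500
    seq_length: int = 100
    background_order: int = 0
    background_model: BackgroundModel | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.motif_consensus = self.motif_consensus.upper()
        if not 4 <= len(self.motif_consensus) <= 18:
            raise ValueError("motif length must be between 4 and 18 nt")
        if set(self.motif_consensus) - (VALID_ALPHABET - {"N"}):
            raise ValueError("motif consensus must be over {A,C,G,T}")
        if not 0.0 <= self.instance_rate <= 1.0:
            raise ValueError("instance_rate must be in [0, 1]")
        if not 0.0 <= self.mutation_rate < 0.75:
            raise ValueError("mutation_rate must be in [0, 0.75)")
        if len(self.motif_consensus) > self.seq_length:
            raise ValueError("motif longer than sequence length")
        if self.background_order not in (0, 1, 2):
            raise ValueError("background_order must be 0, 1 or 2")
        if self.n_sequences < 1 or self.seq_length < 1:
            raise ValueError("n_sequences and seq_length must be positive")


def _uniform_background() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return np.full(4, 0.25), np.full((4, 4), 0.25), np.full((16, 4), 0.25)


def _draw_background(
    rng: np.random.Generator, length: int, order: int, model: BackgroundModel | None
) -> str:
    if model is None:
        M1, M2, M3 = _uniform_background()
    else:
        M1, M2, M3 = model.M1, model.M2, model.M3
    if order == 0:
        idx = rng.choice(4, size=length, p=M1)
        return "".join(BASES[i] for i in idx)
    out = [int(rng.choice(4, p=M1))]
    if length > 1:
        out.append(int(rng.choice(4, p=M2[out[0]])))
    while len(out) < length:
        if order == 1:
            row = M2[out[-1]]
        else:
            row = M3[out[-2] * 4 + out[-1]]
        out.append(int(rng.choice(4, p=row)))
    return "".join(BASES[i] for i in out)


def _mutate(rng: np.random.Generator, word: str, rate: float) -> str:
    out = []
    for b in word:
        if rng.random() < rate:
            others = [c for c in BASES if c != b]
            out.append(others[int(rng.integers(3))])
        else:
            out.append(b)
    return "".join(out)


def generate_planted_dataset(spec: PlantSpec) -> tuple[SequenceSet, list[TruthSite]]:
    """Draw background sequences and implant mutated motif copies.

    A Bernoulli(instance_rate) subset of sequences receives one instance:
    the consensus is mutated per-position, implanted at a uniform random
    offset on a uniform random strand (minus-strand instances implant the
    reverse complement), overwriting the background bases so sequence
    lengths are unchanged.  Identical seeds give identical outputs.
    """
    rng = np.random.default_rng(spec.rng_seed)
    m = len(spec.motif_consensus)
    records: list[tuple[str, str]] = []
    truth: list[TruthSite] = []
    for i in range(spec.n_sequences):
        seq_id = f"seq{i}"
        seq = _draw_background(
            rng, spec.seq_length, spec.background_order, spec.background_model
        )
        if rng.random() < spec.instance_rate:
            word = _mutate(rng, spec.motif_consensus, spec.mutation_rate)
            offset = int(rng.integers(spec.seq_length - m + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            implant = word if strand == "+" else reverse_complement(word)
            seq = seq[:offset] + implant + seq[offset + m :]
            truth.append(TruthSite(seq_id, offset, offset + m, strand))
        records.append((seq_id, seq))
    return SequenceSet(records), truth


def write_truth_bed(truth: list[TruthSite], path) -> None:
    with open(path, "w") as fh:
        for site in truth:
            fh.write(
                f"{site.seq_id}\t{site.start}\t{site.end}\tplanted\t0\t{site.strand}\n"
            )


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    n_truth: int
    n_reported: int
    precision_defined: bool


def score_recovery(
    reported: list[MotifResult], truth: list[TruthSite], slop: int = 2
) -> RecoveryScore:
    """Site-level precision/recall of reported occurrences against truth.

    A truth site counts as recovered when some reported occurrence (any
    motif, either strand) overlaps it by at least (truth length - slop)
    positions; a reported occurrence is correct under the same overlap
    rule against any truth site.  With no reported occurrences, precision
    is undefined and reported as 0 with ``precision_defined`` False.
    """
    occs = [occ for m in reported for occ in m.occurrences]
    by_seq: dict[str, list[TruthSite]] = {}
    for site in truth:
        by_seq.setdefault(site.seq_id, []).append(site)

    def hits(occ, site) -> bool:
        ov = min(occ.end, site.end) - max(occ.start, site.start)
        return ov >= (site.end - site.start) - slop

    recovered = sum(
        1
        for site in truth
        if any(
            hits(occ, site)
            for occ in occs
            if occ.seq_id == site.seq_id
        )
    )
    recall = recovered / len(truth) if truth else 0.0
    if not occs:
        return RecoveryScore(0.0, recall, len(truth), 0, precision_defined=False)
    correct = sum(
        1
        for occ in occs
        if any(hits(occ, site) for site in by_seq.get(occ.seq_id, ()))
    )
    return RecoveryScore(
        precision=correct / len(occs),
        recall=recall,
        n_truth=len(truth),
        n_reported=len(occs),
        precision_defined=True,
    )
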