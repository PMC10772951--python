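"""Input DNA sequences and k-mer extraction primitives.

The motif-discovery pipeline works on a set of accessible-chromatin
sequences (ATAC-seq footprints or peaks).  This module reads them from
FASTA (or extracts them from a genome given BED intervals), validates the
alphabet, and provides the strand / k-mer window primitives every later
stage counts with.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised when a FASTA record is malformed or uses a bad alphabet."""


class EmptyInputError(ValueError):
    """Raised when an input file yields no sequences."""


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise FastaParseError(f"invalid characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceSet:
    """An ordered collection of named DNA sequences over {A,C,G,T,N}.

    Attributes
    ----------
    records : list of (id, seq) tuples, order preserved from the input.
    """

    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rid, seq in self.records:
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise FastaParseError(
                    f"record {rid!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def lengths(self) -> list[int]:
        return [len(seq) for _, seq in self.records]

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def total_positions(self, k: int) -> int:
        """Number of length-k windows across all sequences, Sigma_i (l_i - k + 1).

        Sequences shorter than k contribute zero (never negative terms):
        the sum is a position count.
        """
        return sum(l - k + 1 for l in self.lengths if l >= k)

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a (optionally gzipped) FASTA file into a SequenceSet.

    Sequences are upper-cased; characters outside {A,C,G,T,N} are rejected
    with an error naming the offending record.
    """
    records: list[tuple[str, str]] = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise FastaParseError(
                    f"record {rec.id!r} contains invalid characters {sorted(bad)}"
                )
            records.append((rec.id, seq))
    if not records:
        raise EmptyInputError(f"no FASTA records found in {path}")
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in seqs:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_bed_sequences(bed_path: str | Path, genome_fasta: str | Path) -> SequenceSet:
    """Extract interval sequences from a genome FASTA given BED intervals.

    BED coordinates are 0-based half-open.  Records are named
    ``chrom:start-end``; minus-strand intervals (BED6 column 6) are
    reverse-complemented.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta), sequence_always_upper=True)
    records: list[tuple[str, str]] = []
    with _open_text(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FastaParseError(f"BED line {lineno}: fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if chrom not in genome:
                raise KeyError(f"BED line {lineno}: unknown chromosome {chrom!r}")
            chrom_len = len(genome[chrom])
            if start < 0 or end > chrom_len or start >= end:
                raise IndexError(
                    f"BED line {lineno}: interval {chrom}:{start}-{end} out of "
                    f"range for chromosome of length {chrom_len}"
                )
            seq = str(genome[chrom][start:end])
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand == "-":
                seq = reverse_complement(seq)
            records.append((f"{chrom}:{start}-{end}", seq))
    if not records:
        raise EmptyInputError(f"no intervals found in {bed_path}")
    return SequenceSet(records)


def iter_kmers(
    seqs: SequenceSet, k: int, both_strands: bool = False
) -> Iterator[tuple[str, int, int, str]]:
    """Yield every length-k window containing no N.

    Yields ``(kmer, sequence_index, offset, strand)``.  Offsets are 0-based
    on the forward sequence.  With ``both_strands``, windows of each
    sequence's reverse complement are also yielded with strand '-'; the
    offset then refers to the position within the reverse-complemented
    sequence.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    any_window = False
    for idx, (_, seq) in enumerate(seqs):
        strands = [("+", seq)]
        if both_strands:
            strands.append(("-", reverse_complement(seq)))
        for strand, s in strands:
            for off in range(len(s) - k + 1):
                kmer = s[off : off + k]
                if "N" in kmer:
                    continue
                any_window = True
                yield kmer, idx, off, strand
    if not any_window:
        log.warning("k=%d produced no windows over %d sequences", k, seqs.n)
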