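"""Genomic intervals and strand-aware sequence extraction.

All coordinates are 0-based half-open (BED convention).  Sequence windows
used elsewhere in the package ("last 100 nt of the upstream intron",
"-75..-35 from the 3' splice site") are defined in transcript orientation,
i.e. after the strand of the hosting gene has been resolved, because splice
signals are positioned relative to the 5'/3' splice sites rather than to the
genomic plus strand.
"""

from __future__ import annotations

from dataclasses import dataclass

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome.

    Strand is ``+`` or ``-``; it affects sequence extraction only, never
    the coordinate arithmetic.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length of the intersection of two intervals; 0 when disjoint or on
    different chromosomes.  Strand is ignored."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def extract_sequence(interval: GenomicInterval, genome) -> str:
    """Transcript-orientation sequence for *interval*.

    *genome* is any mapping of chromosome name to string-like sequence
    (a dict of strings, or a ``pyfaidx.Fasta``).  Minus-strand intervals
    return the reverse complement.  By convention the alphabet is
    {A,C,G,T,N}; T stands for both thymine and uracil.
    """
    if interval.chrom not in genome:
        raise KeyError(f"unknown chromosome {interval.chrom!r}")
    chrom_seq = genome[interval.chrom]
    if interval.end > len(chrom_seq):
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} "
            f"exceeds chromosome length {len(chrom_seq)}"
        )
    seq = str(chrom_seq[interval.start : interval.end]).upper()
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq
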