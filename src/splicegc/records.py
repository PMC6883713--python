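"""Annotation records shared by every pipeline stage.

An :class:`ExonRecord` carries its own flanking-intron intervals so that
splice-site windows can be cut without re-deriving gene structure; the
flanks are stored in genomic coordinates and resolved to transcript
orientation at extraction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from intervaltree import IntervalTree

from .intervals import GenomicInterval


@dataclass
class ExonRecord:
    exon_id: str
    gene_id: str
    index: int  # ordinal within gene, 1-based, in transcript order
    interval: GenomicInterval
    upstream_intron: Optional[GenomicInterval] = None  # transcript orientation
    downstream_intron: Optional[GenomicInterval] = None
    constitutive: bool = True
    coding: bool = True

    @property
    def strand(self) -> str:
        return self.interval.strand


def smallest_flanking_intron(exon: ExonRecord) -> Optional[int]:
    """min(upstream, downstream) intron length, or None for terminal exons.

    Exons missing either flank are excluded from any median over this
    statistic rather than contributing a one-sided value.
    """
    if exon.upstream_intron is None or exon.downstream_intron is None:
        return None
    return min(len(exon.upstream_intron), len(exon.downstream_intron))


@dataclass
class GeneRecord:
    gene_id: str
    interval: GenomicInterval
    exons: list[ExonRecord] = field(default_factory=list)
    gc_percent: Optional[float] = None

    def validate(self) -> None:
        prev_end = None
        for i, exon in enumerate(self.exons, start=1):
            if exon.index != i:
                raise ValueError(f"{self.gene_id}: exon index {exon.index} at slot {i}")
            iv = exon.interval
            if iv.chrom != self.interval.chrom:
                raise ValueError(f"{self.gene_id}: exon on wrong chromosome")
            if iv.start < self.interval.start or iv.end > self.interval.end:
                raise ValueError(f"{self.gene_id}: exon outside gene span")
            # transcript order: genomic order on +, reversed on -
            key = iv.start if self.interval.strand == "+" else -iv.end
            if prev_end is not None and key <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or out of order")
            prev_end = key


@dataclass
class DomainRecord:
    """Isochore, TAD, or LAD interval; GC content may be supplied by the
    annotation source or computed from the genome."""

    domain_id: str
    kind: str  # {"isochore", "TAD", "LAD"}
    interval: GenomicInterval
    gc_percent: Optional[float] = None


@dataclass(frozen=True)
class RegulationRecord:
    factor: str
    sample_id: str
    exon_id: str
    direction: str  # {"activated", "repressed"}

    def __post_init__(self) -> None:
        if self.direction not in ("activated", "repressed"):
            raise ValueError(f"invalid direction {self.direction!r}")


class PeakSet:
    """CLIP/ChIP peak intervals with fast per-chromosome overlap queries."""

    def __init__(self, peaks: list[GenomicInterval], experiment_id: str = ""):
        self.experiment_id = experiment_id
        self.peaks = list(peaks)
        self._trees: dict[str, IntervalTree] = {}
        for p in self.peaks:
            self._trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)

    def __len__(self) -> int:
        return len(self.peaks)

    def overlaps_position(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos))

    def covered_mask(self, interval: GenomicInterval):
        """Boolean array over [start, end): True where >=1 peak overlaps."""
        import numpy as np

        mask = np.zeros(len(interval), dtype=bool)
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return mask
        for hit in tree.overlap(interval.start, interval.end):
            lo = max(hit.begin, interval.start) - interval.start
            hi = min(hit.end, interval.end) - interval.start
            mask[lo:hi] = True
        return mask
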