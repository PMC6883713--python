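"""Coverage metaprofiles and CLIP peak positional maps.

A metaplot length-normalizes a set of gene regions to a fixed number of
bins (default 1000) and averages coverage bin-wise across genes.  For the
"internal exons" and "introns" region kinds, the per-gene region coverages
are concatenated in genomic order before binning, and the first 199 bins
are discarded to suppress promoter-proximal signal.

CLIP maps report, per nucleotide position around a splice site (200 nt
into the intron, 50 nt into the exon), the fraction of exons with at
least one peak overlapping that genomic position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .intervals import GenomicInterval
from .records import ExonRecord, GeneRecord, PeakSet
from .signals import FeatureWindows

REGION_KINDS = ("promoter", "first_exon", "internal_exons", "introns",
                "whole_gene", "exon_center", "ss_window")


@dataclass(frozen=True)
class MetaplotSpec:
    region_kind: str = "whole_gene"
    n_bins: int = 1000
    drop_first: int = 199          # applied to internal_exons and introns only
    promoter_up: int = 1500        # nt upstream of the TSS
    promoter_down: int = 500
    exon_center_flank: int = 100
    ss_intron: int = 500
    ss_exon: int = 50

    def __post_init__(self) -> None:
        if self.region_kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.region_kind!r}")
        if not (self.n_bins > self.drop_first >= 0):
            raise ValueError("need n_bins > drop_first >= 0")

    @property
    def drops_bins(self) -> bool:
        return self.region_kind in ("internal_exons", "introns")

    @property
    def profile_length(self) -> int:
        return self.n_bins - (self.drop_first if self.drops_bins else 0)


@dataclass
class MetaProfile:
    spec: MetaplotSpec
    values: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        offset = self.spec.drop_first if self.spec.drops_bins else 0
        return pd.DataFrame({
            "bin": np.arange(offset, self.spec.n_bins),
            "value": self.values,
            "n": self.n,
        })


def gene_regions(gene: GeneRecord, spec: MetaplotSpec) -> list[GenomicInterval]:
    """Regions contributing to a gene's metaplot row, in transcript order."""
    iv = gene.interval
    plus = iv.strand == "+"
    kind = spec.region_kind
    if kind == "whole_gene":
        return [iv]
    if kind == "promoter":
        tss = iv.start if plus else iv.end
        if plus:
            start, end = tss - spec.promoter_up, tss + spec.promoter_down
        else:
            start, end = tss - spec.promoter_down, tss + spec.promoter_up
        return [GenomicInterval(iv.chrom, max(0, start), end, iv.strand)]
    if kind == "first_exon":
        return [gene.exons[0].interval] if gene.exons else []
    if kind == "internal_exons":
        internal = gene.exons[1:-1]
        regions = [e.interval for e in internal]
    elif kind == "introns":
        regions = [e.downstream_intron for e in gene.exons if e.downstream_intron]
    else:
        raise ValueError(f"region kind {kind!r} is per-exon, not per-gene")
    # transcript order == genomic order on +, reversed genomic order on -
    regions = sorted(regions, key=lambda r: r.start, reverse=not plus)
    return regions


def _resample_to_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Average-resample a length-L vector to n_bins.

    Bin b covers positions [floor(b*L/n), floor((b+1)*L/n)); when L < n_bins
    some bins receive no positions and are filled by linear interpolation
    between neighboring non-empty bins.
    """
    L = len(values)
    edges = (np.arange(n_bins + 1) * L) // n_bins
    counts = np.diff(edges)
    out = np.full(n_bins, np.nan)
    nonempty = counts > 0
    csum = np.concatenate([[0.0], np.cumsum(values)])
    out[nonempty] = (csum[edges[1:][nonempty]] - csum[edges[:-1][nonempty]]) / counts[nonempty]
    if not nonempty.all():
        idx = np.arange(n_bins)
        out[~nonempty] = np.interp(idx[~nonempty], idx[nonempty], out[nonempty])
    return out


def binned_profile(genes: Iterable[GeneRecord], coverage: CoverageTrack,
                   spec: MetaplotSpec = MetaplotSpec()) -> MetaProfile:
    """Per-bin mean coverage across genes for one region kind.

    Each gene contributes one length-normalized row (equal weight per
    gene); genes with no qualifying region are skipped with a warning.
    The drop-first rule removes promoter-influenced bins after per-gene
    binning and before cross-gene averaging.
    """
    rows = []
    for gene in genes:
        regions = gene_regions(gene, spec)
        parts = [coverage.values(r) for r in regions]
        concat = np.concatenate(parts) if parts else np.zeros(0)
        if concat.size == 0:
            warnings.warn(f"{gene.gene_id}: empty region concatenation, skipped")
            continue
        rows.append(_resample_to_bins(concat, spec.n_bins))
    if not rows:
        raise ValueError("no gene contributed a region")
    matrix = np.vstack(rows)
    if spec.drops_bins:
        matrix = matrix[:, spec.drop_first :]
    return MetaProfile(spec=spec, values=matrix.mean(axis=0), n=len(rows))


def exon_center_window(exon: ExonRecord, flank: int = 100) -> GenomicInterval:
    iv = exon.interval
    center = (iv.start + iv.end) // 2
    return GenomicInterval(iv.chrom, max(0, center - flank), center + flank, iv.strand)


def mean_coverage(exons: Iterable[ExonRecord], coverage: CoverageTrack,
                  flank: int = 100) -> tuple[pd.Series, float]:
    """Mean depth over each exon's center window, and the group average.

    Returns (per-exon series indexed by exon_id, group mean); the group
    value is NaN for an empty group.
    """
    per_exon = {}
    for exon in exons:
        win = exon_center_window(exon, flank)
        per_exon[exon.exon_id] = float(coverage.values(win).mean())
    series = pd.Series(per_exon, dtype=float)
    if series.empty:
        warnings.warn("empty exon group for mean coverage")
        return series, float("nan")
    return series, float(series.mean())


def gc_at_ratio(mean_gc: float, mean_at: float) -> float:
    """Normalized coverage contrast (GC - AT) / max(GC, AT), in [-1, 1]."""
    denom = max(mean_gc, mean_at)
    if denom <= 0:
        raise ValueError("need a positive mean coverage in at least one group")
    return (mean_gc - mean_at) / denom


def _ss_window_interval(exon: ExonRecord, anchor: str,
                        intron_flank: int, exon_flank: int) -> Optional[GenomicInterval]:
    """Genomic window spanning the splice site: *intron_flank* intronic
    positions, the boundary, and *exon_flank* exonic positions (inclusive
    of both span ends, hence intron_flank + exon_flank + 1 positions)."""
    iv = exon.interval
    plus = iv.strand == "+"
    if anchor == "3ss":
        anchor_pos = iv.start if plus else iv.end - 1  # first exonic base
        intronward = -1 if plus else +1
    else:
        anchor_pos = iv.end - 1 if plus else iv.start  # last exonic base
        intronward = +1 if plus else -1
    lo = anchor_pos + intronward * intron_flank
    hi = anchor_pos - intronward * exon_flank
    start, end = min(lo, hi), max(lo, hi) + 1
    if start < 0:
        return None
    return GenomicInterval(iv.chrom, start, end, iv.strand)


def clip_positional_proportion(exons: list[ExonRecord], peaks: PeakSet,
                               windows: FeatureWindows = FeatureWindows(),
                               anchor: str = "3ss") -> pd.DataFrame:
    """Fraction of exons with peak signal at each position around a splice
    site.

    Offsets run from -clip_intron to +clip_exon (boundary exonic base at
    0); negative offsets are intronic.  Exons whose flank is truncated by
    a chromosome edge contribute no-signal at the missing positions.
    """
    if not exons:
        raise ValueError("empty exon set")
    n_pos = windows.clip_intron + windows.clip_exon + 1
    hits = np.zeros(n_pos)
    for exon in exons:
        win = _ss_window_interval(exon, anchor, windows.clip_intron, windows.clip_exon)
        if win is None:
            continue
        mask = peaks.covered_mask(win)
        if exon.strand == "-":
            mask = mask[::-1]
        # mask is now intron -> exon regardless of strand
        hits += mask
    offsets = np.arange(-windows.clip_intron, windows.clip_exon + 1)
    return pd.DataFrame({"offset": offsets, "proportion": hits / len(exons)})
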