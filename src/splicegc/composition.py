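"""Nucleotide composition statistics.

The central summary used across every heatmap is the relative frequency

    RFreq(D) = 100 * (median(D_S) - median(D_C)) / median(D_C)

comparing a feature D between a set S of regulated exons and a control set
C of constitutive exons.  Junction profiles are mean base-set frequencies
in a 20-nt window slid 1 nt at a time across splice-site regions: the last
100 nt of the upstream intron plus the first 50 nt of the exon (3' ss), or
the last 50 nt of the exon plus the first 100 nt of the downstream intron
(5' ss).

N bases never enter a frequency denominator: a window that is entirely N
contributes nothing for that exon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, extract_sequence
from .records import ExonRecord

BASES = ("A", "C", "G", "T")
COMPOSITE = {"GC": ("G", "C"), "AT": ("A", "T"), "GA": ("G", "A"), "CT": ("C", "T")}


def base_frequencies(seq: str) -> dict[str, float]:
    """Percentage of each base (and the composite pairs GC/AT/GA/CT) in
    *seq*, with N excluded from the denominator."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in BASES}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence has no unambiguous bases")
    freqs = {b: 100.0 * c / total for b, c in counts.items()}
    for name, (x, y) in COMPOSITE.items():
        freqs[name] = freqs[x] + freqs[y]
    return freqs


def base_set_fraction(seq: str, base_set: str) -> float:
    """Percentage of *base_set* characters in seq (N-excluded); NaN when the
    sequence contains no unambiguous base."""
    seq = seq.upper()
    total = sum(seq.count(b) for b in BASES)
    if total == 0:
        return float("nan")
    hits = sum(seq.count(b) for b in base_set)
    return 100.0 * hits / total


@dataclass
class FeatureSample:
    """Feature values for a regulated set S and its control set C."""

    label: str
    values: list[float]
    control: list[float]

    def __post_init__(self) -> None:
        if len(self.values) == 0 or len(self.control) == 0:
            raise ValueError(f"{self.label}: empty sample or control")


def rfreq(sample: FeatureSample) -> float:
    """Relative median frequency (percent) of the sample vs its control."""
    med_c = float(np.median(sample.control))
    if med_c == 0:
        raise ZeroDivisionError(f"{sample.label}: control median is zero")
    med_s = float(np.median(sample.values))
    return 100.0 * (med_s - med_c) / med_c


def rfreq_mean(sample: FeatureSample) -> float:
    """Same relative statistic with the mean in place of the median (used
    for count-valued features whose medians are small integers)."""
    mean_c = float(np.mean(sample.control))
    if mean_c == 0:
        raise ZeroDivisionError(f"{sample.label}: control mean is zero")
    mean_s = float(np.mean(sample.values))
    return 100.0 * (mean_s - mean_c) / mean_c


@dataclass
class WindowProfile:
    anchor: str                 # {"5ss", "3ss"}
    offsets: np.ndarray         # window-center positions relative to the ss
    values: np.ndarray          # mean % per position
    window: int = 20
    step: int = 1
    n_exons: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "value": self.values})


def _junction_region(exon: ExonRecord, anchor: str,
                     intron_flank: int, exon_flank: int) -> GenomicInterval | None:
    """Genomic interval of the junction region in transcript orientation.

    3' ss: last *intron_flank* nt of the upstream intron + first *exon_flank*
    nt of the exon.  5' ss: last *exon_flank* nt of the exon + first
    *intron_flank* nt of the downstream intron.  None when the required
    flank is missing or too short.
    """
    iv = exon.interval
    if anchor == "3ss":
        intron = exon.upstream_intron
    elif anchor == "5ss":
        intron = exon.downstream_intron
    else:
        raise ValueError(f"anchor must be '5ss' or '3ss', got {anchor!r}")
    if intron is None or len(intron) < intron_flank or len(iv) < exon_flank:
        return None
    plus = iv.strand == "+"
    if anchor == "3ss":
        if plus:
            start, end = iv.start - intron_flank, iv.start + exon_flank
        else:
            start, end = iv.end - exon_flank, iv.end + intron_flank
    else:
        if plus:
            start, end = iv.end - exon_flank, iv.end + intron_flank
        else:
            start, end = iv.start - intron_flank, iv.start + exon_flank
    return GenomicInterval(iv.chrom, start, end, iv.strand)


def junction_sequence(exon: ExonRecord, genome, anchor: str,
                      intron_flank: int = 100, exon_flank: int = 50) -> str | None:
    region = _junction_region(exon, anchor, intron_flank, exon_flank)
    if region is None:
        return None
    return extract_sequence(region, genome)


def junction_profile(exons: list[ExonRecord], genome, anchor: str,
                     base_set: str = "GC", window: int = 20, step: int = 1,
                     intron_flank: int = 100, exon_flank: int = 50) -> WindowProfile:
    """Sliding-window base-set frequency profile around a splice site.

    Each window's value is assigned to its center position; only full
    windows are evaluated, and the profile is the per-position mean over
    exons (exons lacking the full flank are skipped).
    """
    if not exons:
        raise ValueError("empty exon list")
    region_len = intron_flank + exon_flank
    n_windows = (region_len - window) // step + 1
    sums = np.zeros(n_windows)
    counts = np.zeros(n_windows, dtype=int)
    n_used = 0
    for exon in exons:
        seq = junction_sequence(exon, genome, anchor, intron_flank, exon_flank)
        if seq is None:
            continue
        n_used += 1
        for w in range(n_windows):
            frac = base_set_fraction(seq[w * step : w * step + window], base_set)
            if not np.isnan(frac):
                sums[w] += frac
                counts[w] += 1
    if n_used == 0:
        raise ValueError("no exon has the required flanking sequence")
    values = np.full(n_windows, np.nan)
    np.divide(sums, counts, out=values, where=counts > 0)
    # offsets relative to the splice site: intronic positions are negative
    # for the 3' ss region, exonic positions negative for the 5' ss region
    if anchor == "3ss":
        starts = np.arange(n_windows) * step - intron_flank
    else:
        starts = np.arange(n_windows) * step - exon_flank
    offsets = starts + window // 2
    return WindowProfile(anchor=anchor, offsets=offsets, values=values,
                         window=window, step=step, n_exons=n_used)


def heatmap_matrix(sets: dict[str, list[float]], control: list[float],
                   statistic=rfreq) -> pd.Series:
    """One RFreq value per set for a single feature (one heatmap column)."""
    out = {}
    for label, values in sets.items():
        out[label] = statistic(FeatureSample(label, values, control))
    return pd.Series(out)


def heatmap_table(feature_values: dict[str, dict[str, list[float]]],
                  control_values: dict[str, list[float]],
                  statistic=rfreq) -> pd.DataFrame:
    """Full heatmap: rows = factors/sets, columns = features.

    *feature_values* maps feature name -> {set label -> values};
    *control_values* maps feature name -> control values.
    """
    cols = {}
    for feature, sets in feature_values.items():
        cols[feature] = heatmap_matrix(sets, control_values[feature], statistic)
    return pd.DataFrame(cols)
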