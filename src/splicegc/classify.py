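"""GC/AT classification of splicing factors and the exons they activate.

A splicing factor is GC-class when the exons whose inclusion it supports
are, as a set, GC-richer than constitutive control exons (median exon GC
above 49.3%) and embedded in a compact intronic context (median smallest
flanking intron below 691 bp).  AT-class is the symmetric case; factors
meeting only one criterion — e.g. factors activating GC-rich exons flanked
by large introns — stay unclassified.  The two thresholds default to
genome-wide control medians from the human FasterDB annotation and are
deliberately pinned rather than recomputed, so classification is
deterministic for any input; pass ``ClassThresholds.from_control_exons``
to re-derive them from a supplied control set instead.

Exon-level labels are the factor-level classes pushed down: an exon is a
GC exon when at least one GC-class factor activates it and no AT-class
factor does.  Exons claimed by both classes are removed from downstream
analyses rather than arbitrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from .composition import base_set_fraction
from .intervals import extract_sequence
from .records import ExonRecord, RegulationRecord, smallest_flanking_intron

GC_CLASS = "GC-class"
AT_CLASS = "AT-class"
UNCLASSIFIED = "unclassified"

LABEL_GC = "GC"
LABEL_AT = "AT"
LABEL_EXCLUDED = "excluded_overlap"
LABEL_NONE = "none"

#: Spliceosome-core factor groups used to define U1 and U2 exon sets.
U1_FACTOR_GROUP = ("SNRPC", "SNRNP70", "DDX5/17")
U2_FACTOR_GROUP = ("U2AF2", "SF3B4", "SF1", "SF3A3")


@dataclass(frozen=True)
class ClassThresholds:
    gc_threshold: float = 49.3       # % GC over the exon body
    intron_threshold: float = 691.0  # nt, smallest flanking intron
    base_set: str = "GC"             # "GC", or "GA"/"CT" for purine/pyrimidine classes
    use_intron_criterion: bool = True

    def __post_init__(self) -> None:
        if self.gc_threshold <= 0 or self.intron_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.base_set not in ("GC", "GA", "CT"):
            raise ValueError(f"unsupported base set {self.base_set!r}")

    @classmethod
    def from_control_exons(cls, control: Iterable[ExonRecord], genome,
                           base_set: str = "GC",
                           use_intron_criterion: bool = True) -> "ClassThresholds":
        """Derive both thresholds as control-set medians."""
        gcs, introns = [], []
        for exon in control:
            gcs.append(base_set_fraction(extract_sequence(exon.interval, genome), base_set))
            size = smallest_flanking_intron(exon)
            if size is not None:
                introns.append(size)
        return cls(gc_threshold=float(np.median(gcs)),
                   intron_threshold=float(np.median(introns)),
                   base_set=base_set,
                   use_intron_criterion=use_intron_criterion)


@dataclass
class FactorExonSet:
    factor: str
    exon_ids: list[str]
    median_gc: Optional[float] = None
    median_min_intron: Optional[float] = None

    def compute_medians(self, exons: Mapping[str, ExonRecord], genome,
                        base_set: str = "GC") -> "FactorExonSet":
        gcs = [
            base_set_fraction(extract_sequence(exons[e].interval, genome), base_set)
            for e in self.exon_ids if e in exons
        ]
        sizes = [
            s for e in self.exon_ids if e in exons
            if (s := smallest_flanking_intron(exons[e])) is not None
        ]
        self.median_gc = float(np.median(gcs)) if gcs else None
        self.median_min_intron = float(np.median(sizes)) if sizes else None
        return self


def build_activated_sets(records: Iterable[RegulationRecord]) -> dict[str, FactorExonSet]:
    """Per-factor activated exon sets.

    An exon belongs to a factor's set when that factor activates it in at
    least one sample and never represses it in any sample; exons regulated
    in opposite directions by the same factor across samples are dropped.
    The same (factor, sample, exon) triple reported with both directions is
    a corrupt table and raises.
    """
    seen: dict[tuple[str, str, str], str] = {}
    activated: dict[str, set[str]] = {}
    repressed: dict[str, set[str]] = {}
    for rec in records:
        key = (rec.factor, rec.sample_id, rec.exon_id)
        prev = seen.get(key)
        if prev is not None and prev != rec.direction:
            raise ValueError(
                f"conflicting directions for {key} within one sample"
            )
        seen[key] = rec.direction
        bucket = activated if rec.direction == "activated" else repressed
        bucket.setdefault(rec.factor, set()).add(rec.exon_id)
    out = {}
    for factor, exon_ids in activated.items():
        kept = exon_ids - repressed.get(factor, set())
        out[factor] = FactorExonSet(factor=factor, exon_ids=sorted(kept))
    return out


def classify_factor(factor_set: FactorExonSet,
                    thresholds: ClassThresholds = ClassThresholds()) -> str:
    """GC-class / AT-class / unclassified for one factor.

    Both inequalities are strict; a median sitting exactly on a threshold
    leaves the factor unclassified.
    """
    if not factor_set.exon_ids:
        raise ValueError(f"{factor_set.factor}: empty exon set")
    gc = factor_set.median_gc
    intron = factor_set.median_min_intron
    if gc is None or (thresholds.use_intron_criterion and intron is None):
        raise ValueError(f"{factor_set.factor}: medians not computed")
    gc_rich = gc > thresholds.gc_threshold
    gc_poor = gc < thresholds.gc_threshold
    if not thresholds.use_intron_criterion:
        return GC_CLASS if gc_rich else AT_CLASS if gc_poor else UNCLASSIFIED
    if gc_rich and intron < thresholds.intron_threshold:
        return GC_CLASS
    if gc_poor and intron > thresholds.intron_threshold:
        return AT_CLASS
    return UNCLASSIFIED


def assemble_class_exons(factor_classes: Mapping[str, str],
                         activated_sets: Mapping[str, FactorExonSet],
                         universe: Iterable[str] | None = None) -> dict[str, str]:
    """Exon-level labels from factor-level classes.

    Returns exon_id -> one of {GC, AT, excluded_overlap, none}.  The
    *universe* (all exon ids to label) defaults to the union of activated
    sets.
    """
    gc_exons: set[str] = set()
    at_exons: set[str] = set()
    for factor, klass in factor_classes.items():
        ids = set(activated_sets[factor].exon_ids)
        if klass == GC_CLASS:
            gc_exons |= ids
        elif klass == AT_CLASS:
            at_exons |= ids
    if universe is None:
        all_ids = set()
        for fs in activated_sets.values():
            all_ids |= set(fs.exon_ids)
    else:
        all_ids = set(universe)
    labels = {}
    for exon_id in all_ids:
        in_gc, in_at = exon_id in gc_exons, exon_id in at_exons
        if in_gc and in_at:
            labels[exon_id] = LABEL_EXCLUDED
        elif in_gc:
            labels[exon_id] = LABEL_GC
        elif in_at:
            labels[exon_id] = LABEL_AT
        else:
            labels[exon_id] = LABEL_NONE
    return labels


def build_control_set(all_exons: Iterable[ExonRecord],
                      activated_sets: Mapping[str, FactorExonSet]) -> list[ExonRecord]:
    """Control exons: constitutive coding internal exons never activated by
    any analyzed factor."""
    activated: set[str] = set()
    for fs in activated_sets.values():
        activated |= set(fs.exon_ids)
    control = [
        e for e in all_exons
        if e.constitutive and e.coding
        and e.upstream_intron is not None and e.downstream_intron is not None
        and e.exon_id not in activated
    ]
    if not control:
        warnings.warn("control set is empty: every candidate exon is activated")
    return control


def build_u1_u2_sets(activated_sets: Mapping[str, FactorExonSet],
                     u1_factors: Iterable[str] = U1_FACTOR_GROUP,
                     u2_factors: Iterable[str] = U2_FACTOR_GROUP,
                     ) -> tuple[set[str], set[str]]:
    """U1 and U2 exon sets: unions of the exons activated by U1- and
    U2-snRNP-associated factors.  An exon activated by members of both
    groups appears in both sets."""
    def union(group):
        out: set[str] = set()
        for factor in group:
            if factor not in activated_sets:
                raise KeyError(f"factor {factor!r} absent from activated sets")
            out |= set(activated_sets[factor].exon_ids)
        return out

    return union(u1_factors), union(u2_factors)
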