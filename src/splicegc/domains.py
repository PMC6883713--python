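"""Exon-to-domain assignment (isochores, TADs, LADs) and per-domain
composition summaries.

Each exon is assigned to the single domain of a given kind with which it
shares the most sequence; exons overlapping no domain stay unassigned, and
ties break toward the domain with the smaller start coordinate.  Domains
of one kind must be non-overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .classify import LABEL_AT, LABEL_GC
from .composition import base_set_fraction
from .intervals import extract_sequence, overlap_length
from .records import DomainRecord, ExonRecord

UNASSIGNED = "unassigned"


@dataclass
class DomainSummary:
    domain_id: str
    kind: str
    gc_percent: Optional[float]
    n_gc_exons: int
    n_at_exons: int

    @property
    def passes_min_filter(self) -> bool:
        """At least five exons of either class (the display threshold used
        for per-domain scatter summaries)."""
        return self.n_gc_exons >= 5 or self.n_at_exons >= 5


class DomainIndex:
    """Overlap index over the domains of one kind."""

    def __init__(self, domains: Sequence[DomainRecord]):
        kinds = {d.kind for d in domains}
        if len(kinds) > 1:
            raise ValueError(f"mixed domain kinds in one index: {sorted(kinds)}")
        self.kind = next(iter(kinds)) if kinds else ""
        self.domains = {d.domain_id: d for d in domains}
        self._trees: dict[str, IntervalTree] = {}
        for d in domains:
            tree = self._trees.setdefault(d.interval.chrom, IntervalTree())
            if tree.overlaps(d.interval.start, d.interval.end):
                raise ValueError(
                    f"overlapping {d.kind} domains at "
                    f"{d.interval.chrom}:{d.interval.start}-{d.interval.end}"
                )
            tree.addi(d.interval.start, d.interval.end, d.domain_id)

    def assign(self, exon: ExonRecord) -> str:
        """Domain id with maximal overlap, or ``unassigned``."""
        tree = self._trees.get(exon.interval.chrom)
        if tree is None:
            return UNASSIGNED
        best_id, best_key = UNASSIGNED, None
        for hit in tree.overlap(exon.interval.start, exon.interval.end):
            d = self.domains[hit.data]
            ov = overlap_length(exon.interval, d.interval)
            key = (ov, -d.interval.start)  # ties -> smaller start
            if best_key is None or key > best_key:
                best_id, best_key = d.domain_id, key
        return best_id


def assign_domains(exons: Iterable[ExonRecord],
                   domains: Sequence[DomainRecord]) -> dict[str, str]:
    """exon_id -> domain_id (or ``unassigned``) for one domain kind."""
    index = DomainIndex(domains)
    return {e.exon_id: index.assign(e) for e in exons}


def compute_domain_gc(domains: Iterable[DomainRecord], genome) -> None:
    """Fill in gc_percent from the genome where the annotation source did
    not supply it."""
    for d in domains:
        if d.gc_percent is None:
            d.gc_percent = base_set_fraction(extract_sequence(d.interval, genome), "GC")


def domain_exon_counts(labels: Mapping[str, str], assignments: Mapping[str, str],
                       domains: Sequence[DomainRecord]) -> list[DomainSummary]:
    """Per-domain GC/AT exon counts from class labels and assignments."""
    counts: dict[str, dict[str, int]] = {d.domain_id: {LABEL_GC: 0, LABEL_AT: 0}
                                         for d in domains}
    for exon_id, domain_id in assignments.items():
        if domain_id == UNASSIGNED:
            continue
        label = labels.get(exon_id)
        if label in (LABEL_GC, LABEL_AT):
            counts[domain_id][label] += 1
    return [
        DomainSummary(domain_id=d.domain_id, kind=d.kind, gc_percent=d.gc_percent,
                      n_gc_exons=counts[d.domain_id][LABEL_GC],
                      n_at_exons=counts[d.domain_id][LABEL_AT])
        for d in domains
    ]


def class_proportion_in_kind(labels: Mapping[str, str],
                             assignments: Mapping[str, str],
                             classes: Sequence[str] = (LABEL_GC, LABEL_AT),
                             ) -> dict[str, float]:
    """Percent of each exon class falling inside any domain of the kind
    the assignments were computed for."""
    out = {}
    for klass in classes:
        ids = [e for e, lab in labels.items() if lab == klass]
        if not ids:
            raise ValueError(f"no exon carries label {klass!r}")
        inside = sum(1 for e in ids if assignments.get(e, UNASSIGNED) != UNASSIGNED)
        out[klass] = 100.0 * inside / len(ids)
    return out


def exon_domain_gc_correlation(exon_gc: Sequence[float],
                               domain_gc: Sequence[float]) -> float:
    """Pearson r between exon GC and hosting-domain GC."""
    x = np.asarray(exon_gc, dtype=float)
    y = np.asarray(domain_gc, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    return float(stats.pearsonr(x, y).statistic)


def domain_concentration_test(summaries: Sequence[DomainSummary],
                              n_perm: int = 2000, seed: int | None = None,
                              ) -> dict[str, float]:
    """Permutation test for uneven concentration of GC vs AT exons across
    domains (a nonparametric alternative to mixed-model likelihood-ratio
    testing; an addition of this package).

    The statistic is the variance across domains of the per-domain GC
    fraction, compared against refits where exon class labels are permuted
    over domain slots with totals preserved.
    """
    ns = np.array([[s.n_gc_exons, s.n_at_exons] for s in summaries], dtype=int)
    totals = ns.sum(axis=1)
    keep = totals > 0
    ns, totals = ns[keep], totals[keep]
    if len(ns) < 2:
        raise ValueError("need >= 2 non-empty domains")
    frac = ns[:, 0] / totals
    observed = float(np.var(frac))
    pool = np.repeat(np.arange(len(ns)), totals)
    flags = np.concatenate([np.concatenate([np.ones(g), np.zeros(t - g)])
                            for (g, _), t in zip(ns, totals)])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(flags)
        perm_frac = np.bincount(pool, weights=perm, minlength=len(ns)) / totals
        if np.var(perm_frac) >= observed:
            hits += 1
    return {"statistic": observed, "p_perm": (hits + 1) / (n_perm + 1)}


def domain_summary_frame(summaries: Sequence[DomainSummary]) -> pd.DataFrame:
    return pd.DataFrame([
        {"domain_id": s.domain_id, "kind": s.kind, "gc_percent": s.gc_percent,
         "n_gc_exons": s.n_gc_exons, "n_at_exons": s.n_at_exons,
         "passes_min_filter": s.passes_min_filter}
        for s in summaries
    ])
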