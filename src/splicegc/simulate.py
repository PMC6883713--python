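"""Synthetic genome generator with planted composition structure.

The generator emulates, at desk scale, the genomic organization the
analysis stages are designed to detect:

* a chromosome tiled by isochore-like blocks at a few discrete GC levels;
* genes inheriting their isochore's composition, with GC-context genes
  carrying small introns and AT-context genes large introns;
* exon GC correlated with gene and isochore GC (offset upward in GC
  context, downward in AT context);
* splicing factors of two groups, each activating internal exons of its
  own context, emitted as a regulation table (standing in for differential-inclusion calling);
* spliceosome-associated factors (U1-like, U2-like) activating planted
  GC and AT exons at configurable asymmetric rates, emitted separately;
* decoy splicing signals (branch-point consensus sites, TNA motifs,
  T-rich runs) planted upstream of AT-class exons;
* self-complementary G/C-biased 5' splice-site flanks on GC-class exons;
* CLIP-like peaks enriched upstream of AT-class exons;
* nucleosome-like coverage boosted on GC-class exons;
* TAD blocks (isochores split in two) and LADs (the lowest-GC isochores).

Everything is drawn from a single seeded generator, so a configuration
and seed fully determine the bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .coverage import CoverageTrack
from .intervals import GenomicInterval, reverse_complement
from .records import DomainRecord, ExonRecord, GeneRecord, PeakSet, RegulationRecord
from . import io as sio

_BASES = np.frombuffer(b"GCAT", dtype=np.uint8)

#: Default asymmetric activation rates (rate on GC exons, rate on AT exons)
#: for spliceosome-associated factors: U1-like factors prefer GC exons,
#: U2-like factors AT exons.
DEFAULT_SPLICEOSOME_RATES: dict[str, tuple[float, float]] = {
    "SNRPC": (0.30, 0.10), "SNRNP70": (0.30, 0.10), "DDX5/17": (0.30, 0.10),
    "U2AF2": (0.10, 0.30), "SF3B4": (0.10, 0.30),
    "SF1": (0.10, 0.30), "SF3A3": (0.10, 0.30),
}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 1
    chrom: str = "chr1"
    #: odd count: the level cycle gives the AT context one extra isochore,
    #: so the planted AT exon pool is systematically the larger one (as in
    #: human data, where AT exons outnumber GC exons; the V-value
    #: subsampling requires it)
    n_isochores: int = 9
    isochore_gc_levels: tuple[float, ...] = (35.0, 42.0, 48.0, 55.0)
    #: context of each level slot: which exon class the genes there host
    isochore_contexts: tuple[str, ...] = ("AT", "AT", "GC", "GC")
    genes_per_isochore: int = 6
    exons_per_gene: tuple[int, int] = (9, 15)
    exon_length_median: float = 120.0
    exon_length_sigma: float = 0.35
    exon_min_length: int = 55
    intron_length_median_gc: float = 300.0   # GC context: medians below 691
    intron_length_median_at: float = 1500.0  # AT context: medians above 691
    intron_length_sigma: float = 0.45
    intron_min_length: int = 130
    exon_gc_offset_gc: float = 6.0    # exon GC = gene GC + offset (GC context)
    exon_gc_offset_at: float = -4.0
    gene_gc_jitter: float = 1.5
    intergenic_gap: tuple[int, int] = (800, 2500)
    # one more AT factor than GC factor: the AT exon pool is systematically
    # the larger one, which the V-value subsampling (size-|GC| draws from
    # AT exons) relies on
    gc_factor_names: tuple[str, ...] = ("SRSF9", "RBFOX2", "HNRNPF")
    at_factor_names: tuple[str, ...] = ("TRA2A", "PTBP1", "HNRNPA1", "HNRNPM")
    exons_activated_per_factor: int = 120
    samples_per_factor: int = 2
    repressed_per_factor: int = 8
    conflicts_per_factor: int = 2
    spliceosome_rates: tuple[tuple[str, tuple[float, float]], ...] = tuple(
        sorted(DEFAULT_SPLICEOSOME_RATES.items())
    )
    decoy_enrichment: float = 1.0
    decoy_bp_mean: float = 2.5      # planted BP consensus sites per AT exon
    decoy_tna_mean: float = 3.0
    decoy_trich_mean: float = 2.0
    gc_5ss_pairing_len: int = 10    # self-complementary flank on GC exons
    clip_rate_at: float = 0.6
    clip_rate_gc: float = 0.1
    clip_peak_length: int = 30
    coverage_base: float = 1.0
    coverage_noise: float = 0.2
    coverage_exon_boost_gc: float = 3.0

    def __post_init__(self) -> None:
        for rate in (self.clip_rate_at, self.clip_rate_gc):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("clip rates must lie in [0, 1]")
        for level in self.isochore_gc_levels:
            if not 0.0 < level < 100.0:
                raise ValueError("GC levels must lie in (0, 100)")
        if len(self.isochore_contexts) != len(self.isochore_gc_levels):
            raise ValueError("one context per GC level slot")
        if any(c not in ("GC", "AT") for c in self.isochore_contexts):
            raise ValueError("contexts must be 'GC' or 'AT'")
        if self.intron_min_length < 1:
            raise ValueError("introns must be at least 1 nt")


def null_config(seed: int = 1, **overrides) -> SimulationConfig:
    """A no-structure configuration: uniform composition, identical intron
    distributions in both contexts, no planted decoys, pairing, CLIP
    asymmetry, or coverage boost.  Factor groups still activate their
    designated exons, so planted labels exist but carry no signal."""
    base = SimulationConfig(
        seed=seed,
        isochore_gc_levels=(45.0, 45.0, 45.0, 45.0),
        intron_length_median_gc=700.0,
        intron_length_median_at=700.0,
        exon_gc_offset_gc=0.0,
        exon_gc_offset_at=0.0,
        decoy_enrichment=0.0,
        gc_5ss_pairing_len=0,
        clip_rate_at=0.3,
        clip_rate_gc=0.3,
        coverage_exon_boost_gc=1.0,
    )
    return replace(base, **overrides)


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneRecord]
    domains: list[DomainRecord]
    regulation: list[RegulationRecord]
    spliceosome_regulation: list[RegulationRecord]
    peaks: PeakSet
    coverage: CoverageTrack
    truth: dict[str, str]  # exon_id -> {"GC", "AT", "none"}

    @property
    def exons(self) -> dict[str, ExonRecord]:
        return {e.exon_id: e for g in self.genes for e in g.exons}

    def domains_of_kind(self, kind: str) -> list[DomainRecord]:
        return [d for d in self.domains if d.kind == kind]


# -- sequence helpers -------------------------------------------------------


def _draw_sequence(rng: np.random.Generator, length: int, gc_percent: float) -> bytearray:
    p_gc = gc_percent / 100.0
    probs = np.array([p_gc / 2, p_gc / 2, (1 - p_gc) / 2, (1 - p_gc) / 2])
    idx = rng.choice(4, size=length, p=probs)
    return bytearray(_BASES[idx].tobytes())


def _gc_fraction(seq: str) -> float:
    total = sum(seq.count(b) for b in "ACGT")
    return 100.0 * sum(seq.count(b) for b in "GC") / total if total else float("nan")


def _plant(seq: bytearray, pos: int, motif: bytes) -> None:
    if 0 <= pos and pos + len(motif) <= len(seq):
        seq[pos : pos + len(motif)] = motif


def _bp_consensus(rng: np.random.Generator) -> bytes:
    """A YTNAY 5-mer around a branch-point adenine (perfect consensus)."""
    y = b"CT"
    return bytes([y[rng.integers(2)], ord("T"),
                  b"ACGT"[rng.integers(4)], ord("A"), y[rng.integers(2)]])


def _plant_decoys(rng: np.random.Generator, intron: bytearray,
                  cfg: SimulationConfig) -> None:
    """Plant BP/TNA/T-rich decoys in the 3' end of a transcript-oriented
    intron (positions relative to the 3' splice site at the intron end)."""
    n = len(intron)
    rate = cfg.decoy_enrichment
    if rate <= 0:
        return
    n_bp = max(2, int(rng.poisson(cfg.decoy_bp_mean * rate)))
    for _ in range(n_bp):
        off = int(rng.integers(10, 96))  # BP adenine lands within -95..-10
        _plant(intron, n - off - 2, _bp_consensus(rng))
    for _ in range(int(rng.poisson(cfg.decoy_tna_mean * rate))):
        off = int(rng.integers(4, 49))
        motif = bytes([ord("T"), b"ACGT"[rng.integers(4)], ord("A")])
        _plant(intron, n - off - 2, motif)
    for _ in range(int(rng.poisson(cfg.decoy_trich_mean * rate))):
        run = int(rng.integers(5, 9))
        off = int(rng.integers(35, 76))
        _plant(intron, n - off, b"T" * run)


# -- main generator ---------------------------------------------------------


def simulate(config: SimulationConfig = SimulationConfig()) -> SyntheticBundle:
    """Generate a full synthetic bundle; deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    chrom = config.chrom
    lo_exons, hi_exons = config.exons_per_gene

    # ---- plan gene structures and activation before laying out sequence
    plans = []  # per gene: dict with structure + context
    gene_counter = 0
    iso_plan = []  # per isochore: (level, context, [gene plan indices])
    for iso in range(config.n_isochores):
        slot = iso % len(config.isochore_gc_levels)
        level = config.isochore_gc_levels[slot]
        context = config.isochore_contexts[slot]
        members = []
        for _ in range(config.genes_per_isochore):
            gene_counter += 1
            n_exons = int(rng.integers(lo_exons, hi_exons + 1))
            exon_lens = np.maximum(
                config.exon_min_length,
                np.round(rng.lognormal(math.log(config.exon_length_median),
                                       config.exon_length_sigma, n_exons)),
            ).astype(int)
            med = (config.intron_length_median_gc if context == "GC"
                   else config.intron_length_median_at)
            intron_lens = np.maximum(
                config.intron_min_length,
                np.round(rng.lognormal(math.log(med), config.intron_length_sigma,
                                       n_exons - 1)),
            ).astype(int)
            offset = (config.exon_gc_offset_gc if context == "GC"
                      else config.exon_gc_offset_at)
            gene_gc = float(np.clip(level + rng.normal(0, config.gene_gc_jitter), 5, 95))
            exon_gc = float(np.clip(gene_gc + offset, 5, 95))
            strand = "+" if rng.random() < 0.5 else "-"
            plans.append({
                "gene_id": f"G{gene_counter:03d}", "context": context,
                "n_exons": n_exons, "exon_lens": exon_lens,
                "intron_lens": intron_lens, "gene_gc": gene_gc,
                "exon_gc": exon_gc, "strand": strand,
            })
            members.append(len(plans) - 1)
        iso_plan.append((level, context, members))

    # ---- factor activation on internal exons, per context group
    def exon_id(plan, t_index):  # transcript-order, 1-based
        return f"{plan['gene_id']}_{t_index}"

    candidates = {"GC": [], "AT": []}
    for plan in plans:
        for t in range(2, plan["n_exons"]):  # internal exons only
            candidates[plan["context"]].append(exon_id(plan, t))

    regulation: list[RegulationRecord] = []
    factor_final_sets: dict[str, set[str]] = {}
    for context, names in (("GC", config.gc_factor_names),
                           ("AT", config.at_factor_names)):
        pool = candidates[context]
        for factor in names:
            n_act = min(config.exons_activated_per_factor, len(pool))
            chosen = rng.choice(len(pool), size=n_act, replace=False)
            activated = {pool[i] for i in chosen}
            rest = [e for e in pool if e not in activated]
            rng.shuffle(rest)
            repressed = set(rest[: config.repressed_per_factor])
            conflict_pick = rng.choice(sorted(activated),
                                       size=min(config.conflicts_per_factor,
                                                len(activated)),
                                       replace=False)
            conflicted = set(conflict_pick.tolist())
            for eid in sorted(activated):
                sample = f"{factor}_s{1 + int(rng.integers(config.samples_per_factor))}"
                regulation.append(RegulationRecord(factor, sample, eid, "activated"))
            for eid in sorted(conflicted):
                regulation.append(RegulationRecord(factor, f"{factor}_sX", eid, "repressed"))
            for eid in sorted(repressed):
                regulation.append(RegulationRecord(factor, f"{factor}_s1", eid, "repressed"))
            factor_final_sets[factor] = activated - conflicted

    truth: dict[str, str] = {}
    planted = {"GC": set(), "AT": set()}
    for context, names in (("GC", config.gc_factor_names),
                           ("AT", config.at_factor_names)):
        for factor in names:
            planted[context] |= factor_final_sets[factor]

    # ---- spliceosome-associated factors over planted classes
    spliceosome_regulation: list[RegulationRecord] = []
    for factor, (rate_gc, rate_at) in config.spliceosome_rates:
        for context, rate in (("GC", rate_gc), ("AT", rate_at)):
            for eid in sorted(planted[context]):
                if rng.random() < rate:
                    spliceosome_regulation.append(
                        RegulationRecord(factor, f"{factor}_s1", eid, "activated"))

    # ---- lay out sequence: isochores tile the chromosome contiguously
    genome_parts: list[str] = []
    cursor = 0
    genes: list[GeneRecord] = []
    isochores: list[DomainRecord] = []
    tads: list[DomainRecord] = []
    lads: list[DomainRecord] = []
    min_level = min(config.isochore_gc_levels)
    gap_lo, gap_hi = config.intergenic_gap

    for iso_i, (level, context, members) in enumerate(iso_plan):
        iso_start = cursor
        for plan_i in members:
            plan = plans[plan_i]
            gap = int(rng.integers(gap_lo, gap_hi))
            genome_parts.append(_draw_sequence(rng, gap, level).decode())
            cursor += gap

            # transcript-orientation assembly
            parts: list[bytearray] = []
            exon_offsets: list[tuple[int, int]] = []
            intron_offsets: list[tuple[int, int]] = []
            pos = 0
            n_exons = plan["n_exons"]
            for t in range(1, n_exons + 1):
                e_len = int(plan["exon_lens"][t - 1])
                e_seq = _draw_sequence(rng, e_len, plan["exon_gc"])
                parts.append(e_seq)
                exon_offsets.append((pos, pos + e_len))
                pos += e_len
                if t < n_exons:
                    i_len = int(plan["intron_lens"][t - 1])
                    i_seq = _draw_sequence(rng, i_len, plan["gene_gc"])
                    parts.append(i_seq)
                    intron_offsets.append((pos, pos + i_len))
                    pos += i_len
            # planted features, in transcript orientation
            for t in range(1, n_exons + 1):
                eid = exon_id(plan, t)
                if eid in planted["AT"] and t >= 2:
                    _plant_decoys(rng, parts[2 * (t - 1) - 1], config)
                if (eid in planted["GC"] and t < n_exons
                        and config.gc_5ss_pairing_len > 0):
                    k = config.gc_5ss_pairing_len
                    exon_part = parts[2 * (t - 1)]
                    intron_part = parts[2 * (t - 1) + 1]
                    stem = _draw_sequence(rng, k, 85.0)
                    exon_part[-k:] = stem
                    intron_part[:k] = reverse_complement(stem.decode()).encode()

            tx_seq = "".join(p.decode() for p in parts)
            L = len(tx_seq)
            g_start = cursor
            strand = plan["strand"]
            placed = tx_seq if strand == "+" else reverse_complement(tx_seq)
            genome_parts.append(placed)
            cursor += L

            def to_genomic(off: tuple[int, int]) -> GenomicInterval:
                o0, o1 = off
                if strand == "+":
                    return GenomicInterval(chrom, g_start + o0, g_start + o1, strand)
                return GenomicInterval(chrom, g_start + L - o1, g_start + L - o0, strand)

            exon_records = []
            for t in range(1, n_exons + 1):
                up = to_genomic(intron_offsets[t - 2]) if t >= 2 else None
                down = to_genomic(intron_offsets[t - 1]) if t < n_exons else None
                eid = exon_id(plan, t)
                exon_records.append(ExonRecord(
                    exon_id=eid, gene_id=plan["gene_id"], index=t,
                    interval=to_genomic(exon_offsets[t - 1]),
                    upstream_intron=up, downstream_intron=down,
                    constitutive=eid not in planted["GC"] | planted["AT"],
                    coding=True,
                ))
                if eid in planted["GC"]:
                    truth[eid] = "GC"
                elif eid in planted["AT"]:
                    truth[eid] = "AT"
                else:
                    truth[eid] = "none"
            gene = GeneRecord(
                gene_id=plan["gene_id"],
                interval=GenomicInterval(chrom, g_start, g_start + L, strand),
                exons=exon_records,
                gc_percent=_gc_fraction(tx_seq),
            )
            gene.validate()
            genes.append(gene)

        tail_gap = int(rng.integers(gap_lo, gap_hi))
        genome_parts.append(_draw_sequence(rng, tail_gap, level).decode())
        cursor += tail_gap

        iso_iv = GenomicInterval(chrom, iso_start, cursor)
        isochores.append(DomainRecord(f"iso_{iso_i:02d}", "isochore", iso_iv))
        mid = (iso_start + cursor) // 2
        tads.append(DomainRecord(f"tad_{iso_i:02d}a", "TAD",
                                 GenomicInterval(chrom, iso_start, mid)))
        tads.append(DomainRecord(f"tad_{iso_i:02d}b", "TAD",
                                 GenomicInterval(chrom, mid, cursor)))
        if level == min_level:
            lads.append(DomainRecord(f"lad_{iso_i:02d}", "LAD", iso_iv))

    genome = {chrom: "".join(genome_parts)}
    for dom in isochores + tads + lads:
        dom.gc_percent = _gc_fraction(
            genome[chrom][dom.interval.start : dom.interval.end])

    # ---- CLIP-like peaks upstream of 3' splice sites
    peak_intervals: list[GenomicInterval] = []
    all_exons = [e for g in genes for e in g.exons]
    for exon in all_exons:
        label = truth[exon.exon_id]
        rate = (config.clip_rate_at if label == "AT"
                else config.clip_rate_gc if label == "GC" else 0.0)
        if rate <= 0 or exon.upstream_intron is None or rng.random() >= rate:
            continue
        intron = exon.upstream_intron
        span = min(len(intron), 190)
        plen = min(config.clip_peak_length, span - 10) if span > 10 else 0
        if plen < 5:
            continue
        off = int(rng.integers(5, span - plen))  # nt upstream of the 3' ss
        if exon.strand == "+":
            end = exon.interval.start - off
            peak_intervals.append(GenomicInterval(chrom, end - plen, end))
        else:
            start = exon.interval.end + off
            peak_intervals.append(GenomicInterval(chrom, start, start + plen))
    peaks = PeakSet(peak_intervals, experiment_id="synthetic_clip")

    # ---- nucleosome-like coverage
    size = len(genome[chrom])
    n_blocks = size // 100 + 1
    block_noise = 1.0 + config.coverage_noise * (rng.random(n_blocks) * 2 - 1)
    cov = np.repeat(np.round(config.coverage_base * block_noise, 4), 100)[:size]
    for exon in all_exons:
        if truth[exon.exon_id] == "GC":
            iv = exon.interval
            cov[iv.start : iv.end] = np.round(
                cov[iv.start : iv.end] * config.coverage_exon_boost_gc, 4)
    coverage = CoverageTrack({chrom: cov})

    return SyntheticBundle(
        config=config, genome=genome, genes=genes,
        domains=isochores + tads + lads,
        regulation=regulation,
        spliceosome_regulation=spliceosome_regulation,
        peaks=peaks, coverage=coverage, truth=truth,
    )


# -- bundle persistence -----------------------------------------------------

BUNDLE_FILES = {
    "genome": "genome.fa", "genes": "genes.tsv", "exons": "exons.tsv",
    "regulation": "regulation.tsv",
    "spliceosome_regulation": "spliceosome_regulation.tsv",
    "peaks": "peaks.bed", "coverage": "coverage.bedgraph",
    "domains": "domains.tsv", "truth": "truth.tsv",
}


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {key: outdir / name for key, name in BUNDLE_FILES.items()}
    sio.write_fasta(paths["genome"], bundle.genome)
    sio.write_genes(paths["genes"], bundle.genes)
    sio.write_exons(paths["exons"], bundle.genes)
    sio.write_regulation(paths["regulation"], bundle.regulation)
    sio.write_regulation(paths["spliceosome_regulation"], bundle.spliceosome_regulation)
    sio.write_peaks_bed(paths["peaks"], bundle.peaks)
    bundle.coverage.to_bedgraph(paths["coverage"])
    sio.write_domains(paths["domains"], bundle.domains)
    sio.write_truth(paths["truth"], bundle.truth)
    return paths
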