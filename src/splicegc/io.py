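"""Readers and writers for the plain-text formats the pipeline touches.

FASTA for genomes (pyfaidx on read), BED6 for peaks, TSV with header for
gene/exon/regulation/domain tables.  All tables use 0-based half-open
coordinates; convert 1-based inputs before loading.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from pyfaidx import Fasta

from .intervals import GenomicInterval
from .records import DomainRecord, ExonRecord, GeneRecord, PeakSet, RegulationRecord

# -- FASTA ------------------------------------------------------------------


def write_fasta(path, genome: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path, as_dict: bool = False):
    """Open a genome FASTA.  ``as_dict=True`` loads everything into plain
    strings (fine for the small genomes this package targets); otherwise a
    lazily-indexed ``pyfaidx.Fasta`` is returned."""
    fa = Fasta(str(path), sequence_always_upper=True)
    if as_dict:
        return {name: str(fa[name][:]) for name in fa.keys()}
    return fa


# -- gene / exon tables -----------------------------------------------------

EXON_COLUMNS = [
    "exon_id", "gene_id", "index", "chrom", "start", "end", "strand",
    "up_intron_start", "up_intron_end", "down_intron_start", "down_intron_end",
    "constitutive", "coding",
]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "gc_percent"]


def write_genes(path, genes: Iterable[GeneRecord]) -> None:
    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.gene_id, "chrom": g.interval.chrom,
            "start": g.interval.start, "end": g.interval.end,
            "strand": g.interval.strand,
            "gc_percent": "" if g.gc_percent is None else f"{g.gc_percent:.6g}",
        })
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_exons(path, genes: Iterable[GeneRecord]) -> None:
    rows = []
    for g in genes:
        for e in g.exons:
            row = {
                "exon_id": e.exon_id, "gene_id": e.gene_id, "index": e.index,
                "chrom": e.interval.chrom, "start": e.interval.start,
                "end": e.interval.end, "strand": e.interval.strand,
                "constitutive": int(e.constitutive), "coding": int(e.coding),
            }
            for name, iv in (("up_intron", e.upstream_intron),
                             ("down_intron", e.downstream_intron)):
                row[f"{name}_start"] = "" if iv is None else iv.start
                row[f"{name}_end"] = "" if iv is None else iv.end
            rows.append(row)
    pd.DataFrame(rows, columns=EXON_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genes(gene_path, exon_path) -> list[GeneRecord]:
    gdf = pd.read_csv(gene_path, sep="\t", dtype={"gene_id": str})
    edf = pd.read_csv(exon_path, sep="\t", dtype={"exon_id": str, "gene_id": str})
    genes: dict[str, GeneRecord] = {}
    for row in gdf.itertuples():
        gc = None if pd.isna(row.gc_percent) else float(row.gc_percent)
        genes[row.gene_id] = GeneRecord(
            gene_id=row.gene_id,
            interval=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
            gc_percent=gc,
        )
    for row in edf.itertuples():
        def _iv(start, end, strand=row.strand, chrom=row.chrom):
            if pd.isna(start):
                return None
            return GenomicInterval(chrom, int(start), int(end), strand)

        exon = ExonRecord(
            exon_id=row.exon_id, gene_id=row.gene_id, index=int(row.index),
            interval=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
            upstream_intron=_iv(row.up_intron_start, row.up_intron_end),
            downstream_intron=_iv(row.down_intron_start, row.down_intron_end),
            constitutive=bool(row.constitutive), coding=bool(row.coding),
        )
        genes[row.gene_id].exons.append(exon)
    for g in genes.values():
        g.exons.sort(key=lambda e: e.index)
        g.validate()
    return list(genes.values())


# -- regulation tables ------------------------------------------------------

REGULATION_COLUMNS = ["factor", "sample_id", "exon_id", "direction"]


def write_regulation(path, records: Iterable[RegulationRecord]) -> None:
    rows = [
        {"factor": r.factor, "sample_id": r.sample_id,
         "exon_id": r.exon_id, "direction": r.direction}
        for r in records
    ]
    pd.DataFrame(rows, columns=REGULATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_regulation(path) -> list[RegulationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        RegulationRecord(row.factor, row.sample_id, row.exon_id, row.direction)
        for row in df.itertuples()
    ]


# -- domains ----------------------------------------------------------------

DOMAIN_COLUMNS = ["domain_id", "kind", "chrom", "start", "end", "gc_percent"]


def write_domains(path, domains: Iterable[DomainRecord]) -> None:
    rows = [
        {"domain_id": d.domain_id, "kind": d.kind, "chrom": d.interval.chrom,
         "start": d.interval.start, "end": d.interval.end,
         "gc_percent": "" if d.gc_percent is None else f"{d.gc_percent:.6g}"}
        for d in domains
    ]
    pd.DataFrame(rows, columns=DOMAIN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_domains(path) -> list[DomainRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"domain_id": str, "kind": str})
    out = []
    for row in df.itertuples():
        gc = None if pd.isna(row.gc_percent) else float(row.gc_percent)
        out.append(DomainRecord(
            domain_id=row.domain_id, kind=row.kind,
            interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
            gc_percent=gc,
        ))
    return out


# -- peaks (BED6) -----------------------------------------------------------


def write_peaks_bed(path, peaks: PeakSet) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks.peaks):
            name = f"{peaks.experiment_id or 'peak'}_{i}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t0\t{p.strand}\n")


def read_peaks_bed(path, experiment_id: str = "") -> PeakSet:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return PeakSet(intervals, experiment_id=experiment_id or os.path.basename(str(path)))


# -- truth labels (synthetic bundles) ---------------------------------------


def write_truth(path, truth: dict[str, str]) -> None:
    df = pd.DataFrame(sorted(truth.items()), columns=["exon_id", "class"])
    df.to_csv(path, sep="\t", index=False)


def read_truth(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["exon_id"], df["class"]))
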