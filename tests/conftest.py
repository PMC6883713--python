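import pytest

from splicegc import SimulationConfig, simulate
from splicegc.intervals import GenomicInterval
from splicegc.records import ExonRecord


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle, shared read-only across the suite."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def bundle_exons(bundle):
    return bundle.exons


def make_exon(genome: dict[str, str], exon_start: int, exon_len: int,
              up_len: int, down_len: int, strand: str = "+",
              chrom: str = "chrT", exon_id: str = "e1") -> ExonRecord:
    """Internal exon with flanking introns at explicit plus-strand
    coordinates; on the minus strand the genomic upstream/downstream roles
    swap."""
    e = GenomicInterval(chrom, exon_start, exon_start + exon_len, strand)
    left = GenomicInterval(chrom, exon_start - up_len, exon_start, strand)
    right = GenomicInterval(chrom, e.end, e.end + down_len, strand)
    up, down = (left, right) if strand == "+" else (right, left)
    return ExonRecord(exon_id=exon_id, gene_id="g1", index=2, interval=e,
                      upstream_intron=up, downstream_intron=down)
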