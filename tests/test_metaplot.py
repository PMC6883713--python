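"""Metaplot binning, mean-coverage statistics, and CLIP maps."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from splicegc.coverage import CoverageTrack
from splicegc.intervals import GenomicInterval
from splicegc.metaplot import (MetaplotSpec, _resample_to_bins, binned_profile,
                               clip_positional_proportion, gc_at_ratio,
                               mean_coverage)
from splicegc.records import GeneRecord, PeakSet
from tests.conftest import make_exon


def constant_track(bundle, value):
    chrom = bundle.config.chrom
    size = len(bundle.genome[chrom])
    return CoverageTrack({chrom: np.full(size, value)})


class TestBinnedProfile:
    @pytest.mark.parametrize("kind", ["whole_gene", "promoter", "first_exon",
                                      "internal_exons", "introns"])
    def test_constant_coverage_gives_flat_profile(self, bundle, kind):
        prof = binned_profile(bundle.genes, constant_track(bundle, 3.0),
                              MetaplotSpec(region_kind=kind))
        assert np.allclose(prof.values, 3.0)

    def test_drop_first_rule_lengths(self, bundle):
        track = constant_track(bundle, 1.0)
        internal = binned_profile(bundle.genes, track,
                                  MetaplotSpec(region_kind="internal_exons"))
        assert len(internal.values) == 801
        whole = binned_profile(bundle.genes, track, MetaplotSpec())
        assert len(whole.values) == 1000
        assert internal.to_frame()["bin"].iloc[0] == 199

    def test_two_genes_average_equally(self):
        genome_size = 3000
        track = CoverageTrack({"chrT": np.concatenate([
            np.full(1500, 2.0), np.full(1500, 4.0)])})
        g1 = GeneRecord("g1", GenomicInterval("chrT", 100, 1100))
        g2 = GeneRecord("g2", GenomicInterval("chrT", 1600, 2600))
        prof = binned_profile([g1, g2], track, MetaplotSpec())
        assert np.allclose(prof.values, 3.0)
        assert prof.n == 2

    def test_short_region_interpolation_preserves_constant(self):
        out = _resample_to_bins(np.full(37, 5.0), 1000)
        assert np.allclose(out, 5.0)

    def test_resample_averages_within_bins(self):
        out = _resample_to_bins(np.array([1.0, 2.0, 3.0, 4.0]), 2)
        assert np.allclose(out, [1.5, 3.5])

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            binned_profile([], CoverageTrack(), MetaplotSpec())

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            MetaplotSpec(n_bins=100, drop_first=199)


class TestMeanCoverage:
    def test_constant_depth(self):
        genome = {"chrT": "A" * 1000}
        exon = make_exon(genome, 400, 100, 200, 200)
        track = CoverageTrack({"chrT": np.full(1000, 5.0)})
        per_exon, group = mean_coverage([exon], track)
        assert per_exon["e1"] == 5.0 and group == 5.0

    def test_half_covered_window(self):
        genome = {"chrT": "A" * 1000}
        exon = make_exon(genome, 400, 100, 200, 200)  # center 450, window 350..550
        depth = np.zeros(1000)
        depth[350:450] = 10.0
        _, group = mean_coverage([exon], CoverageTrack({"chrT": depth}))
        assert group == pytest.approx(5.0)

    def test_empty_group_warns(self):
        with pytest.warns(UserWarning):
            per_exon, group = mean_coverage([], CoverageTrack())
        assert np.isnan(group)


class TestGcAtRatio:
    @pytest.mark.parametrize("gc,at,expected", [
        (4.0, 2.0, 0.5), (2.0, 4.0, -0.5), (3.0, 3.0, 0.0),
    ])
    def test_examples(self, gc, at, expected):
        assert gc_at_ratio(gc, at) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            gc_at_ratio(0.0, 0.0)

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    def test_antisymmetric_and_bounded(self, a, b):
        r = gc_at_ratio(a, b)
        assert r == pytest.approx(-gc_at_ratio(b, a))
        assert -1.0 <= r <= 1.0


class TestClipProportions:
    def _setup(self):
        genome = {"chrT": "A" * 4000}
        exons = [make_exon(genome, 500 + 800 * i, 100, 300, 300,
                           exon_id=f"e{i}") for i in range(4)]
        return genome, exons

    def test_half_the_exons_with_a_peak_at_one_offset(self):
        _, exons = self._setup()
        peaks = PeakSet([
            GenomicInterval("chrT", exons[0].interval.start - 10,
                            exons[0].interval.start - 9),
            GenomicInterval("chrT", exons[1].interval.start - 10,
                            exons[1].interval.start - 9),
        ])
        df = clip_positional_proportion(exons, peaks)
        assert df.loc[df.offset == -10, "proportion"].item() == 0.5
        assert df.loc[df.offset == -11, "proportion"].item() == 0.0
        assert len(df) == 251

    def test_no_peaks_gives_zeros(self):
        _, exons = self._setup()
        df = clip_positional_proportion(exons, PeakSet([]))
        assert (df.proportion == 0).all()

    def test_everything_covered_gives_ones(self):
        _, exons = self._setup()
        peaks = PeakSet([GenomicInterval("chrT", 0, 4000)])
        df = clip_positional_proportion(exons, peaks)
        assert (df.proportion == 1.0).all()

    def test_minus_strand_offsets_are_transcript_oriented(self):
        genome = {"chrT": "A" * 2000}
        exon = make_exon(genome, 800, 100, 300, 300, strand="-")
        # 3' ss of a minus-strand exon is its genomic end; 10 nt upstream
        # in transcript orientation lies at larger genomic coordinates
        peaks = PeakSet([GenomicInterval("chrT", 909, 910)])
        df = clip_positional_proportion([exon], peaks)
        assert df.loc[df.offset == -10, "proportion"].item() == 1.0

    def test_empty_exon_set_rejected(self):
        with pytest.raises(ValueError):
            clip_positional_proportion([], PeakSet([]))
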