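"""Exon-to-domain assignment and per-domain summaries."""

import numpy as np
import pytest

from splicegc.domains import (DomainIndex, DomainSummary, UNASSIGNED,
                              assign_domains, class_proportion_in_kind,
                              domain_concentration_test, domain_exon_counts,
                              exon_domain_gc_correlation)
from splicegc.intervals import GenomicInterval, overlap_length
from splicegc.records import DomainRecord
from tests.conftest import make_exon

GENOME = {"chrT": "A" * 10_000}


def dom(domain_id, start, end, kind="isochore"):
    return DomainRecord(domain_id, kind, GenomicInterval("chrT", start, end))


class TestAssignment:
    def test_exon_fully_inside(self):
        exon = make_exon(GENOME, 500, 100, 200, 200)
        assert assign_domains([exon], [dom("D", 0, 1000)]) == {"e1": "D"}

    def test_maximal_overlap_wins(self):
        exon = make_exon(GENOME, 500, 100, 200, 200)  # exon [500, 600)
        domains = [dom("D1", 0, 580), dom("D2", 580, 1000)]  # 80 vs 20 nt
        assert assign_domains([exon], domains)["e1"] == "D1"

    def test_no_domains_on_chromosome(self):
        exon = make_exon(GENOME, 500, 100, 200, 200)
        domains = [DomainRecord("D", "isochore", GenomicInterval("chrZ", 0, 9))]
        assert assign_domains([exon], domains)["e1"] == UNASSIGNED

    def test_overlapping_domains_rejected_at_load(self):
        with pytest.raises(ValueError):
            DomainIndex([dom("D1", 0, 600), dom("D2", 500, 900)])

    def test_mixed_kinds_rejected(self):
        with pytest.raises(ValueError):
            DomainIndex([dom("D1", 0, 10), dom("D2", 20, 30, kind="TAD")])

    def test_agrees_with_naive_scan_on_bundle(self, bundle):
        for kind in ("isochore", "TAD", "LAD"):
            domains = bundle.domains_of_kind(kind)
            assignments = assign_domains(bundle.exons.values(), domains)
            for exon in bundle.exons.values():
                best, best_key = UNASSIGNED, (0, None)
                for d in domains:
                    ov = overlap_length(exon.interval, d.interval)
                    if ov > best_key[0] or (ov == best_key[0] and ov > 0
                                            and d.interval.start < best_key[1]):
                        best, best_key = d.domain_id, (ov, d.interval.start)
                assert assignments[exon.exon_id] == best


class TestCounts:
    LABELS = {"e1": "GC", "e2": "GC", "e3": "AT", "e4": "none", "e5": "AT"}

    def test_per_domain_counts_and_filter(self):
        domains = [dom("D1", 0, 100), dom("D2", 100, 200), dom("D3", 200, 300)]
        assignments = {"e1": "D1", "e2": "D1", "e3": "D1",
                       "e4": "D2", "e5": UNASSIGNED}
        summaries = domain_exon_counts(self.LABELS, assignments, domains)
        by_id = {s.domain_id: s for s in summaries}
        assert (by_id["D1"].n_gc_exons, by_id["D1"].n_at_exons) == (2, 1)
        assert (by_id["D2"].n_gc_exons, by_id["D2"].n_at_exons) == (0, 0)
        assert not by_id["D1"].passes_min_filter
        assert DomainSummary("x", "isochore", None, 6, 0).passes_min_filter
        assert DomainSummary("x", "isochore", None, 0, 5).passes_min_filter
        assert not DomainSummary("x", "isochore", None, 4, 4).passes_min_filter

    def test_class_proportions(self):
        assignments = {"e1": "D1", "e2": UNASSIGNED, "e3": "D1",
                       "e5": UNASSIGNED}
        props = class_proportion_in_kind(self.LABELS, assignments)
        assert props["GC"] == pytest.approx(50.0)
        assert props["AT"] == pytest.approx(50.0)

    def test_all_or_none_inside(self):
        props = class_proportion_in_kind(
            {"e1": "GC", "e3": "AT"}, {"e1": "D", "e3": UNASSIGNED})
        assert props == {"GC": 100.0, "AT": 0.0}

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            class_proportion_in_kind({"e1": "GC"}, {"e1": "D"})

    def test_counts_bounded_by_class_totals(self, bundle):
        labels = bundle.truth
        for kind in ("isochore", "LAD"):
            domains = bundle.domains_of_kind(kind)
            assignments = assign_domains(bundle.exons.values(), domains)
            summaries = domain_exon_counts(labels, assignments, domains)
            assert sum(s.n_gc_exons for s in summaries) <= \
                sum(1 for t in labels.values() if t == "GC")
            assert sum(s.n_at_exons for s in summaries) <= \
                sum(1 for t in labels.values() if t == "AT")


class TestCorrelation:
    def test_perfect_correlation(self):
        gc = [35.0, 42.0, 55.0, 61.0]
        assert exon_domain_gc_correlation(gc, gc) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        gc = [35.0, 42.0, 55.0, 61.0]
        flipped = [100 - x for x in gc]
        assert exon_domain_gc_correlation(gc, flipped) == pytest.approx(-1.0)

    def test_permuted_pairing_decorrelates(self):
        rng = np.random.default_rng(0)
        x = rng.normal(50, 8, 1000)
        y = x + rng.normal(0, 1, 1000)
        assert exon_domain_gc_correlation(x, y) > 0.9
        assert abs(exon_domain_gc_correlation(x, rng.permutation(y))) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            exon_domain_gc_correlation([50, 50, 50], [40, 45, 50])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            exon_domain_gc_correlation([1, 2], [1, 2])


class TestConcentration:
    def test_concentrated_labels_detected(self):
        summaries = [DomainSummary(f"D{i}", "TAD", None, 20, 0) for i in range(5)]
        summaries += [DomainSummary(f"E{i}", "TAD", None, 0, 20) for i in range(5)]
        res = domain_concentration_test(summaries, n_perm=500, seed=1)
        assert res["p_perm"] < 0.01

    def test_uniform_labels_not_detected(self):
        summaries = [DomainSummary(f"D{i}", "TAD", None, 10, 10) for i in range(10)]
        res = domain_concentration_test(summaries, n_perm=500, seed=1)
        assert res["p_perm"] > 0.05
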