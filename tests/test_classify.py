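"""Activated-set assembly, factor classification, and exon labels."""

import pytest
from hypothesis import given, strategies as st

from splicegc.classify import (AT_CLASS, GC_CLASS, LABEL_AT, LABEL_EXCLUDED,
                               LABEL_GC, LABEL_NONE, UNCLASSIFIED,
                               ClassThresholds, FactorExonSet,
                               assemble_class_exons, build_activated_sets,
                               build_control_set, build_u1_u2_sets,
                               classify_factor)
from splicegc.records import RegulationRecord


def rec(factor, sample, exon, direction="activated"):
    return RegulationRecord(factor, sample, exon, direction)


class TestBuildActivatedSets:
    def test_activated_in_one_sample_is_included(self):
        sets = build_activated_sets([rec("F", "s1", "e1")])
        assert sets["F"].exon_ids == ["e1"]

    def test_opposite_regulation_across_samples_is_eliminated(self):
        sets = build_activated_sets([
            rec("F", "s1", "e1"), rec("F", "s2", "e1", "repressed"),
            rec("F", "s1", "e2"),
        ])
        assert sets["F"].exon_ids == ["e2"]

    def test_other_factors_unaffected_by_elimination(self):
        sets = build_activated_sets([
            rec("F", "s1", "e1"), rec("F", "s2", "e1", "repressed"),
            rec("G", "s1", "e1"),
        ])
        assert sets["G"].exon_ids == ["e1"]

    def test_conflicting_duplicate_in_same_sample_rejected(self):
        with pytest.raises(ValueError):
            build_activated_sets([
                rec("F", "s1", "e1"), rec("F", "s1", "e1", "repressed"),
            ])

    def test_empty_records(self):
        assert build_activated_sets([]) == {}


class TestClassifyFactor:
    def _set(self, gc, intron):
        return FactorExonSet("F", ["e1"], median_gc=gc, median_min_intron=intron)

    @pytest.mark.parametrize("gc,intron,expected", [
        (55.0, 300, GC_CLASS),
        (40.0, 2500, AT_CLASS),
        (55.0, 2500, UNCLASSIFIED),   # GC-rich but large introns
        (40.0, 300, UNCLASSIFIED),
        (49.3, 300, UNCLASSIFIED),    # threshold equality is strict
        (55.0, 691, UNCLASSIFIED),
    ])
    def test_two_criteria_rule(self, gc, intron, expected):
        assert classify_factor(self._set(gc, intron)) == expected

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            classify_factor(FactorExonSet("F", [], 50.0, 100.0))

    @given(st.floats(5, 95), st.floats(5, 95), st.floats(10, 5000))
    def test_monotone_in_gc(self, gc_low, gc_high, intron):
        """Raising the GC median can never move a factor GC -> AT."""
        lo, hi = sorted((gc_low, gc_high))
        rank = {AT_CLASS: 0, UNCLASSIFIED: 1, GC_CLASS: 2}
        a = classify_factor(self._set(lo, intron))
        b = classify_factor(self._set(hi, intron))
        assert rank[b] >= rank[a]

    def test_intron_criterion_can_be_disabled(self):
        thr = ClassThresholds(use_intron_criterion=False, base_set="GA")
        fs = self._set(55.0, 2500)
        assert classify_factor(fs, thr) == GC_CLASS


class TestAssembleClassExons:
    SETS = {
        "F_gc1": FactorExonSet("F_gc1", ["e1", "e3"]),
        "F_gc2": FactorExonSet("F_gc2", ["e1"]),
        "F_at": FactorExonSet("F_at", ["e2", "e3"]),
        "F_un": FactorExonSet("F_un", ["e4"]),
    }
    CLASSES = {"F_gc1": GC_CLASS, "F_gc2": GC_CLASS,
               "F_at": AT_CLASS, "F_un": UNCLASSIFIED}

    def test_labels(self):
        labels = assemble_class_exons(self.CLASSES, self.SETS,
                                      universe=["e1", "e2", "e3", "e4", "e5"])
        assert labels == {
            "e1": LABEL_GC,          # two GC-class factors
            "e2": LABEL_AT,
            "e3": LABEL_EXCLUDED,    # claimed by both classes
            "e4": LABEL_NONE,        # only an unclassified factor
            "e5": LABEL_NONE,
        }

    def test_partition_on_bundle(self, bundle):
        from splicegc.classify import classify_factor as cf
        sets = build_activated_sets(bundle.regulation)
        for fs in sets.values():
            fs.compute_medians(bundle.exons, bundle.genome)
        classes = {f: cf(fs) for f, fs in sets.items()}
        labels = assemble_class_exons(classes, sets, universe=bundle.exons)
        assert set(labels) == set(bundle.exons)
        assert set(labels.values()) <= {LABEL_GC, LABEL_AT, LABEL_EXCLUDED, LABEL_NONE}


class TestControlAndSnrnpSets:
    def test_control_excludes_activated_and_terminal(self, bundle):
        sets = build_activated_sets(bundle.regulation)
        control = build_control_set(bundle.exons.values(), sets)
        activated = set().union(*(fs.exon_ids for fs in sets.values()))
        ids = {e.exon_id for e in control}
        assert not ids & activated
        assert all(e.upstream_intron and e.downstream_intron for e in control)
        assert ids  # non-empty on the default bundle

    def test_everything_activated_warns(self):
        sets = {"F": FactorExonSet("F", ["e1"])}
        with pytest.warns(UserWarning):
            assert build_control_set([], sets) == []

    def test_u1_u2_unions_and_overlap(self):
        sets = {
            "SNRPC": FactorExonSet("SNRPC", ["e1", "e2"]),
            "SNRNP70": FactorExonSet("SNRNP70", ["e2"]),
            "DDX5/17": FactorExonSet("DDX5/17", []),
            "U2AF2": FactorExonSet("U2AF2", ["e3"]),
            "SF3B4": FactorExonSet("SF3B4", []),
            "SF1": FactorExonSet("SF1", ["e1"]),
            "SF3A3": FactorExonSet("SF3A3", []),
        }
        u1, u2 = build_u1_u2_sets(sets)
        assert u1 == {"e1", "e2"}
        assert u2 == {"e1", "e3"}
        assert "e1" in u1 & u2  # membership in both groups is allowed

    def test_unknown_factor_in_group_rejected(self):
        with pytest.raises(KeyError):
            build_u1_u2_sets({}, u1_factors=("NOPE",), u2_factors=())

    def test_empty_groups_give_empty_sets(self):
        assert build_u1_u2_sets({}, u1_factors=(), u2_factors=()) == (set(), set())


class TestRecoveryOnBundle:
    def test_planted_labels_recovered(self, bundle):
        sets = build_activated_sets(bundle.regulation)
        for fs in sets.values():
            fs.compute_medians(bundle.exons, bundle.genome)
        classes = {f: classify_factor(fs) for f, fs in sets.items()}
        labels = assemble_class_exons(classes, sets, universe=bundle.exons)
        planted = {e: t for e, t in bundle.truth.items() if t in ("GC", "AT")}
        correct = sum(labels[e] == t for e, t in planted.items())
        swaps = sum(labels[e] in ("GC", "AT") and labels[e] != t
                    for e, t in planted.items())
        assert correct / len(planted) >= 0.95
        assert swaps == 0
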