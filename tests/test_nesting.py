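"""Nested-insertion detection, pattern classification, and stripping."""

import pytest

from mulescan.io_formats import TeAnnotation
from mulescan.nesting import (
    NestedInsertion,
    classify_insertion_pattern,
    detect_nested_insertions,
    insertion_disrupts_coding,
    insertion_preference,
    merge_for_strip,
    strip_nested,
)
from mulescan.simulate import SimConfig, insert_nested_te, plant_mule


def _ins(start, end, te_class="RNA", family="fam", tsd_len=0):
    return NestedInsertion("h", start, end, family, te_class, tsd_len)


class TestDetect:
    def test_planted_insertions_recovered(self, nested_sim):
        _, genome, annos, truth = nested_sim
        for eid, el in truth.elements.items():
            s, e = el.genome_span
            tirs = (
                (s + el.tir_spans[0][0], s + el.tir_spans[0][1]),
                (s + el.tir_spans[1][0], s + el.tir_spans[1][1]),
            )
            ins = detect_nested_insertions(
                eid, (s, e), tirs, annos, own_families={f"MULE_{eid}"}
            )
            assert len(ins) == len(el.nested)
            got = sorted((n.start, n.end, n.te_class) for n in ins)
            want = sorted((n.interval[0], n.interval[1], n.te_class) for n in el.nested)
            assert got == want

    def test_fragments_of_one_family_merge(self):
        annos = [
            TeAnnotation("g", 1000, 1400, "CopiaX", "RNA", "+"),
            TeAnnotation("g", 1430, 1800, "CopiaX", "RNA", "+"),  # 30 bp gap
            TeAnnotation("g", 2500, 2800, "CopiaX", "RNA", "+"),  # separate event
        ]
        ins = detect_nested_insertions(
            "h", (500, 5000), ((500, 700), (4800, 5000)), annos
        )
        assert [(n.start, n.end) for n in ins] == [(500, 1300), (2000, 2300)]

    def test_duplicated_target_site_inferred_and_stripped(self, rng, reference):
        """Annotation intervals cover the TE only; the duplicated target
        site next to it is found by direct comparison, so stripping from
        annotations restores the pre-insertion sequence exactly."""
        el = plant_mule(SimConfig(seed=7), set(), rng, reference=reference)
        el2 = insert_nested_te(el, "MITE", rng)
        nt = el2.nested[0]
        annos = [
            TeAnnotation("g", 100 + nt.interval[0], 100 + nt.interval[1],
                         nt.family, nt.te_class, "+")
        ]
        span = (100, 100 + len(el2.seq))
        tirs = (
            (100 + el2.tir_spans[0][0], 100 + el2.tir_spans[0][1]),
            (100 + el2.tir_spans[1][0], 100 + el2.tir_spans[1][1]),
        )
        ins = detect_nested_insertions(
            "h", span, tirs, annos, element_seq=el2.seq
        )
        assert len(ins) == 1 and ins[0].tsd_len == nt.tsd_len
        stripped, _ = strip_nested(el2.seq, ins)
        assert stripped == el.seq

    def test_annotations_overlapping_tirs_excluded(self):
        annos = [TeAnnotation("g", 550, 900, "X", "DNA", "+")]
        ins = detect_nested_insertions(
            "h", (500, 5000), ((500, 700), (4800, 5000)), annos
        )
        assert ins == []


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "classes,expected",
        [
            (["RNA"], "RNA-TE"),
            (["DNA", "DNA"], "DNA-TE"),
            (["RNA", "DNA"], "RNA-DNA-TE"),
            ([], "none"),
        ],
    )
    def test_categories(self, classes, expected):
        ins = [_ins(100 * i, 100 * i + 50, c) for i, c in enumerate(classes, 1)]
        assert classify_insertion_pattern("h", ins).category == expected


class TestDisruptsCoding:
    def test_inside_cds(self):
        assert insertion_disrupts_coding(_ins(1200, 1500), (1000, 3000))

    def test_straddling_edge_counts(self):
        assert insertion_disrupts_coding(_ins(900, 1100), (1000, 3000))

    def test_outside_cds(self):
        # e.g. an insertion well downstream of the transposase stop codon
        assert not insertion_disrupts_coding(_ins(5500, 5800), (1000, 3000))

    def test_missing_coding_region(self):
        assert not insertion_disrupts_coding(_ins(10, 20), None)


class TestStrip:
    def test_no_insertions_identity(self):
        seq = "ACGT" * 100
        stripped, cmap = strip_nested(seq, [])
        assert stripped == seq
        assert cmap.to_original(17) == 17
        assert cmap.to_stripped(17) == 17

    def test_length_conservation(self):
        seq = "A" * 6000
        ins = [_ins(1000, 2000), _ins(3000, 3500, tsd_len=5)]
        stripped, _ = strip_nested(seq, ins)
        assert len(stripped) == 6000 - 1000 - 505

    def test_round_trip_restores_planted_sequence(self, rng, reference):
        el = plant_mule(SimConfig(seed=7), set(), rng, reference=reference)
        el2 = insert_nested_te(el, "LTR_retro", rng, target_age_myr=1.0)
        el2 = insert_nested_te(el2, "MITE", rng)
        ins = [
            NestedInsertion(
                "h", n.interval[0], n.interval[1], n.family, n.te_class, n.tsd_len
            )
            for n in el2.nested
        ]
        stripped, _ = strip_nested(el2.seq, merge_for_strip(ins))
        assert stripped == el.seq

    def test_detect_strip_detect_is_empty(self, nested_sim):
        _, genome, annos, truth = nested_sim
        for eid, el in truth.elements.items():
            if not el.nested:
                continue
            s, e = el.genome_span
            tirs = (
                (s + el.tir_spans[0][0], s + el.tir_spans[0][1]),
                (s + el.tir_spans[1][0], s + el.tir_spans[1][1]),
            )
            ins = detect_nested_insertions(
                eid, (s, e), tirs, annos, own_families={f"MULE_{eid}"}
            )
            # after stripping, the excised intervals are gone: re-detection
            # against annotations shifted through the map finds nothing
            stripped, cmap = strip_nested(
                genome.seq[s:e], merge_for_strip(ins)
            )
            for n in ins:
                assert cmap.to_stripped(n.start) is None

    def test_overlap_without_merge_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            strip_nested("A" * 1000, [_ins(100, 400), _ins(300, 600)])


class TestInsertionPreference:
    def test_element_inside_ltr_counted(self):
        annos = [TeAnnotation("g", 100, 20_000, "hostLTR", "RNA", "+")]
        df = insertion_preference(
            {"e1": (5000, 11_000)}, {"e1": 9}, annos, {"e1": []}
        )
        row = df[df.event == "element_into_te"].iloc[0]
        assert row.rna_te == 1 and row.dna_te == 0

    def test_standalone_element_not_counted(self):
        annos = [TeAnnotation("g", 100, 500, "X", "RNA", "+")]
        df = insertion_preference({"e1": (5000, 11_000)}, {"e1": 9}, annos, {"e1": []})
        row = df[df.event == "element_into_te"].iloc[0]
        assert row.rna_te == 0 and row.dna_te == 0

    def test_ratio_na_when_dna_zero(self):
        df = insertion_preference({}, {}, [], {})
        assert df.rna_dna_ratio.isna().all()
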