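"""Generator contracts: determinism, planted-feature geometry, and the
statistical structure of divergence and nesting."""

import numpy as np
import pytest

from mulescan.alignment import revcomp
from mulescan.discovery import validate_tsd
from mulescan.simulate import (
    LTR_SUB_RATE,
    SimConfig,
    insert_nested_te,
    make_reference_transposase,
    mutate_homolog,
    plant_mule,
    simulate_est_records,
    simulate_genome,
)


class TestReferenceTransposase:
    def test_deterministic(self):
        assert make_reference_transposase(1) == make_reference_transposase(1)
        assert (
            make_reference_transposase(1).protein
            != make_reference_transposase(2).protein
        )

    def test_dde_span_exceeds_100_aa(self):
        ref = make_reference_transposase(1)
        d1, d2, e = ref.dde_positions
        assert e - d1 > 100
        assert ref.protein[d1] == ref.protein[d2] == "D"
        assert ref.protein[e] == "E"

    def test_hth_segment_length(self):
        ref = make_reference_transposase(1)
        assert 20 <= ref.hth_span[1] - ref.hth_span[0] <= 60


class TestPlantMule:
    def test_element_anatomy(self, rng, reference):
        cfg = SimConfig(seed=7)
        el = plant_mule(cfg, set(), rng, reference=reference)
        # TIR pair in inverted orientation at the planted identity
        left = el.seq[: el.tir_len]
        right = el.seq[-el.tir_len :]
        matches = sum(a == b for a, b in zip(left, revcomp(right)))
        assert abs(matches / el.tir_len - cfg.tir_identity) <= 0.02
        assert 2000 <= len(el.seq) <= 30000
        assert validate_tsd(el.tsd, el.tsd).valid
        # CDS lies strictly between the TIRs
        assert el.tir_spans[0][1] <= el.cds_span[0] < el.cds_span[1] <= el.tir_spans[1][0]

    def test_intact_has_no_defects(self, rng, reference):
        el = plant_mule(SimConfig(seed=7), set(), rng, reference=reference)
        assert el.defects == {}

    def test_premature_stop_planted_in_frame(self, rng, reference):
        el = plant_mule(
            SimConfig(seed=7), {"premature_stop"}, rng, reference=reference
        )
        codon = el.defects["premature_stop"]["codon"]
        s = el.cds_span[0] + 3 * codon
        assert el.seq[s : s + 3] == "TAA"

    def test_combined_defects_recorded(self, rng, reference):
        el = plant_mule(
            SimConfig(seed=7), {"frameshift", "deletion"}, rng, reference=reference
        )
        assert set(el.defects) == {"frameshift", "deletion"}

    def test_unknown_label_rejected(self, rng, reference):
        with pytest.raises(ValueError):
            plant_mule(SimConfig(seed=7), {"inversion"}, rng, reference=reference)


class TestInsertNestedTe:
    def test_age_zero_gives_identical_ltrs(self, rng, reference):
        el = plant_mule(SimConfig(seed=7), set(), rng, reference=reference)
        el2 = insert_nested_te(el, "LTR_retro", rng, target_age_myr=0.0)
        n = el2.nested[0]
        (a5, b5), (a3, b3) = n.ltr_spans
        assert el2.seq[a5:b5] == el2.seq[a3:b3]

    def test_expected_divergence_tracks_age(self, rng, reference):
        """At 1 Myr the pairwise LTR divergence, pooled over 150 replicates,
        is within 10% of 2*r*T = 0.026."""
        el = plant_mule(SimConfig(seed=7), set(), rng, reference=reference)
        diff = cols = 0
        for _ in range(150):
            el2 = insert_nested_te(el, "LTR_retro", rng, target_age_myr=1.0)
            n = el2.nested[0]
            (a5, b5), (a3, b3) = n.ltr_spans
            l5, l3 = el2.seq[a5:b5], el2.seq[a3:b3]
            diff += sum(a != b for a, b in zip(l5, l3))
            cols += len(l5)
        expected = 2 * LTR_SUB_RATE * 1e6
        assert abs(diff / cols - expected) <= 0.1 * expected

    def test_mite_length_274(self, rng, reference):
        el = plant_mule(SimConfig(seed=7), set(), rng, reference=reference)
        el2 = insert_nested_te(el, "MITE", rng)
        assert el2.nested[0].length == 274
        assert el2.nested[0].te_class == "DNA"

    def test_strip_round_trip(self, rng, reference):
        el = plant_mule(SimConfig(seed=7), set(), rng, reference=reference)
        el2 = insert_nested_te(el, "DNA_TE", rng)
        n = el2.nested[0]
        restored = el2.seq[: n.interval[0]] + el2.seq[n.interval[1] + n.tsd_len :]
        assert restored == el.seq


class TestSimulateGenome:
    def test_bit_identical_under_fixed_seed(self):
        cfg = SimConfig(seed=13, genome_len=60_000, n_elements=3)
        g1, a1, t1 = simulate_genome(cfg)
        g2, a2, t2 = simulate_genome(cfg)
        assert g1.seq == g2.seq
        assert a1 == a2
        assert set(t1.elements) == set(t2.elements)

    def test_no_elements(self):
        g, annos, truth = simulate_genome(
            SimConfig(seed=1, genome_len=10_000, n_elements=0)
        )
        assert len(g.seq) == 10_000
        assert annos == [] and truth.elements == {}

    def test_planted_coordinates_validate(self, small_sim):
        _, genome, _, truth = small_sim
        for el in truth.elements.values():
            s, e = el.genome_span
            assert 0 <= s < e <= len(genome.seq)
            assert genome.seq[s:e] == el.seq
            # flanking TSD copies are present in the genome
            assert genome.seq[s - len(el.tsd) : s] == el.tsd
            assert genome.seq[e : e + len(el.tsd)] == el.tsd

    def test_genome_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_genome(SimConfig(seed=1, genome_len=5_000, n_elements=10))

    def test_defect_spectrum_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(defect_spectrum={"intact": 0.5, "deletion": 0.4})


class TestMutateHomolog:
    def test_zero_rates_identity(self, rng):
        seq = "ACGT" * 500
        out, truth = mutate_homolog(seq, 0.0, 0.0, 0.3, rng)
        assert out == seq
        assert truth.n_indels == truth.n_substitutions == 0

    def test_substitution_count_binomial(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        _, truth = mutate_homolog(seq, 0.02, 0.0, 0.3, rng)
        mean, sd = 200, np.sqrt(10_000 * 0.02 * 0.98)
        assert abs(truth.n_substitutions - mean) <= 3 * sd

    def test_indel_count_poisson_mean(self, rng):
        """Realized indel events average L/1000 * rate over replicates."""
        seq = "".join(rng.choice(list("ACGT"), size=5_000))
        counts = [
            mutate_homolog(seq, 0.0, 2.0, 0.3, rng)[1].n_indels for _ in range(200)
        ]
        assert abs(np.mean(counts) - 10.0) <= 3 * np.sqrt(10.0 / 200)


class TestSimulateEsts:
    def test_substring_structure_and_truth(self, rng):
        elements = [("e1", "".join(rng.choice(list("ACGT"), size=3000)))]
        ests, sources = simulate_est_records(elements, 5, rng)
        assert len(ests) == 5
        for est_id, seq in ests:
            assert 300 <= len(seq) <= 1500
            assert seq in elements[0][1]
            assert sources[est_id] == "e1"
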