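"""Indel counting, NIK/LIK normalisation, homolog pairing, and NG86 Ks."""

import itertools
import math

import numpy as np
import pytest

from mulescan.alignment import CODON_TABLE
from mulescan.indel_evolution import (
    IndelPairStat,
    align_count_indels,
    best_homolog_pairs,
    bin_pairs,
    compute_ks,
    compute_nik_lik,
)
from mulescan.simulate import mutate_homolog, random_dna


class TestAlignCountIndels:
    def test_identical_sequences(self, rng):
        seq = random_dna(2000, 0.44, rng)
        st = align_count_indels(seq, seq)
        assert (st.n_indels, st.indel_len_total, st.identity) == (0, 0, 1.0)
        assert st.aligned_cols == 2000

    def test_single_insertion_is_one_indel(self, rng):
        a = random_dna(2000, 0.44, rng)
        b = a[:1000] + "ACGTACGTAC" + a[1000:]
        st = align_count_indels(a, b)
        assert st.n_indels == 1
        assert st.indel_len_total == 10
        assert st.identity == 1.0

    def test_symmetry(self, rng):
        a = random_dna(1500, 0.44, rng)
        b, _ = mutate_homolog(a, 0.02, 2.0, 0.3, rng)
        s1, s2 = align_count_indels(a, b), align_count_indels(b, a)
        assert (s1.n_indels, s1.indel_len_total, s1.identity, s1.aligned_cols) == (
            s2.n_indels, s2.indel_len_total, s2.identity, s2.aligned_cols,
        )

    def test_planted_indel_count_recovered(self, rng):
        """Mean estimated indel count tracks the planted Poisson truth."""
        est, true = [], []
        for _ in range(30):
            a = random_dna(2000, 0.44, rng)
            b, tr = mutate_homolog(a, 0.01, 2.0, 0.3, rng)
            est.append(align_count_indels(a, b).n_indels)
            true.append(tr.n_indels)
        assert abs(np.mean(est) - np.mean(true)) <= 0.15 * max(np.mean(true), 1)

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError):
            align_count_indels("ACGT" * 10, "ACGT" * 10)


class TestNikLik:
    def test_arithmetic(self):
        st = IndelPairStat("a", "b", 2000, 2000, 2000, 0.99, 3, 30)
        nik, lik = compute_nik_lik(st)
        assert nik == pytest.approx(0.75)
        assert lik == pytest.approx(7.5)

    def test_zero_indels(self):
        st = IndelPairStat("a", "b", 1000, 1000, 1000, 1.0, 0, 0)
        assert compute_nik_lik(st) == (0.0, 0.0)

    def test_duplicating_pairs_leaves_bin_means_unchanged(self):
        stats = [
            IndelPairStat("a", "b", 2000, 2000, 2000, 0.955, 3, 30),
            IndelPairStat("c", "d", 2000, 2000, 2000, 0.958, 5, 50),
        ]
        one = bin_pairs(stats, "identity")
        two = bin_pairs(stats + stats, "identity")
        assert one.mean_nik.equals(two.mean_nik)


class TestBestHomologPairs:
    def test_identical_pair(self, rng):
        seq = random_dna(2000, 0.44, rng)
        pairs = best_homolog_pairs({"a": seq, "b": seq})
        assert len(pairs) == 1 and pairs[0].identity == 1.0

    def test_low_identity_pair_excluded(self, rng):
        a = random_dna(2000, 0.44, rng)
        b, _ = mutate_homolog(a, 0.10, 1.0, 0.3, rng)  # ~90% identity
        assert best_homolog_pairs({"a": a, "b": b}) == []

    def test_true_siblings_paired(self, rng):
        elements = {}
        for i in range(5):
            base = random_dna(2200, 0.44, rng)
            elements[f"x{i}"] = base
            elements[f"y{i}"], _ = mutate_homolog(base, 0.02, 1.0, 0.3, rng)
        pairs = best_homolog_pairs(elements)
        ok = sum(1 for p in pairs if p.id_a.lstrip("xy") == p.id_b.lstrip("xy"))
        assert ok >= 0.9 * len(pairs) and len(pairs) == 5

    def test_singleton_skipped(self, rng):
        assert best_homolog_pairs({"a": random_dna(2000, 0.44, rng)}) == []


# ---------------------------------------------------------------------------
# Ks
# ---------------------------------------------------------------------------

def _oracle_ng86_single_diff(cds_a: str, cds_b: str) -> float:
    """Independent NG86 for pairs differing in exactly one position.

    Sites are counted by full enumeration per codon; the single difference
    needs no pathway averaging.  Jukes-Cantor correction applied at the end.
    """
    S = sd = 0.0
    for i in range(0, len(cds_a), 3):
        c1, c2 = cds_a[i : i + 3], cds_b[i : i + 3]
        for codon in (c1, c2):
            syn = 0.0
            for pos, base in itertools.product(range(3), "ACGT"):
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1 :]
                if CODON_TABLE[alt] == CODON_TABLE[codon]:
                    syn += 1
            S += syn / 3.0 / 2.0
        if c1 != c2:
            assert sum(a != b for a, b in zip(c1, c2)) == 1
            if CODON_TABLE[c1] == CODON_TABLE[c2]:
                sd += 1
    ps = sd / S
    return -0.75 * math.log(1 - 4 * ps / 3)


class TestComputeKs:
    def test_identical_cds(self, rng, reference):
        from mulescan.simulate import back_translate

        cds = back_translate(reference.protein[:120], rng)
        assert compute_ks(cds, cds) == 0.0

    def test_single_synonymous_change_matches_oracle(self, rng, reference):
        from mulescan.simulate import back_translate

        cds = back_translate(reference.protein[:100], rng)
        mutant = None
        for i in range(0, len(cds), 3):
            c = cds[i : i + 3]
            for b in "ACGT":
                alt = c[:2] + b
                if b != c[2] and CODON_TABLE[alt] == CODON_TABLE[c]:
                    mutant = cds[:i] + alt + cds[i + 3 :]
                    break
            if mutant:
                break
        ks = compute_ks(cds, mutant)
        assert ks == pytest.approx(_oracle_ng86_single_diff(cds, mutant), abs=1e-6)

    def test_too_few_codons_gives_none(self, rng, reference):
        from mulescan.simulate import back_translate

        cds = back_translate(reference.protein[:20], rng)
        assert compute_ks(cds, cds) is None

    def test_monotone_in_substitution_rate(self, rng, reference):
        from mulescan.simulate import back_translate

        cds = back_translate(reference.protein[:250], rng)
        ks_values = []
        for rate in (0.005, 0.01, 0.02, 0.04, 0.08):
            reps = []
            for _ in range(5):
                mut, _ = mutate_homolog(cds, rate, 0.0, 0.3, rng)
                k = compute_ks(cds, mut[: len(cds)])
                if k is not None:
                    reps.append(k)
            ks_values.append(np.mean(reps))
        assert all(b > a for a, b in zip(ks_values, ks_values[1:]))


class TestBinPairs:
    def test_identity_bin_assignment(self):
        st = IndelPairStat("a", "b", 2000, 2000, 1950, 0.955, 2, 20)
        df = bin_pairs([st], "identity")
        assert df.loc[df.bin == "95-96", "n_pairs"].item() == 1

    def test_identical_pairs_land_in_top_bin(self):
        st = IndelPairStat("a", "b", 2000, 2000, 2000, 1.0, 0, 0)
        df = bin_pairs([st], "identity")
        assert df.loc[df.bin == "99-100", "n_pairs"].item() == 1
        assert df.loc[df.bin == "99-100", "mean_nik"].item() == 0.0

    def test_empty_bins_are_nan(self):
        df = bin_pairs([], "identity")
        assert df.mean_nik.isna().all()
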