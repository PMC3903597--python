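"""Element discovery: TSD rules, TIR pairing, translated search, calling."""

import numpy as np
import pytest

from mulescan.alignment import revcomp, translated_search
from mulescan.discovery import (
    brute_force_tir_pairs,
    call_candidate_elements,
    cluster_representatives,
    find_tir_pairs,
    size_profile,
    translated_homology_scan,
    validate_tsd,
)
from mulescan.simulate import (
    SimConfig,
    back_translate,
    make_reference_transposase,
    plant_mule,
    random_dna,
    simulate_genome,
)


# ---------------------------------------------------------------------------
# TSD validation
# ---------------------------------------------------------------------------

def _mutate(s: str, positions, alphabet="ACGT") -> str:
    out = list(s)
    for p in positions:
        out[p] = next(c for c in alphabet if c != out[p])
    return "".join(out)


class TestValidateTsd:
    def test_identical_pair(self):
        call = validate_tsd("ACGTACGTA", "ACGTACGTA")
        assert call.valid and call.mismatches == 0 and call.length == 9

    @pytest.mark.parametrize(
        "length,n_mm,expected",
        [
            (8, 0, True),
            (8, 1, True),
            (8, 2, False),
            (9, 2, True),
            (9, 3, False),
            (10, 2, True),
            (11, 2, True),
            (11, 3, False),
        ],
    )
    def test_mismatch_tolerance_by_length(self, length, n_mm, expected):
        left = ("ACGTACGTACG")[:length]
        right = _mutate(left, range(n_mm))
        assert validate_tsd(left, right).valid is expected

    @pytest.mark.parametrize(
        "length,n_mm,expected",
        [(8, 0, True), (8, 1, False), (9, 0, True), (9, 1, True), (9, 2, False)],
    )
    def test_indel_tolerance_by_length(self, length, n_mm, expected):
        # one-nucleotide indel: right copy loses its middle base
        left = ("ACGTACGTACG")[:length]
        right = left[: length // 2] + left[length // 2 + 1 :]
        right = _mutate(right, range(n_mm))
        assert validate_tsd(left, right).valid is expected

    def test_length_outside_range_invalid_not_error(self):
        assert not validate_tsd("ACGTACG", "ACGTACG").valid  # 7 bp
        assert not validate_tsd("ACGTACGTACGT", "ACGTACGTACGT").valid  # 12 bp

    def test_symmetric(self):
        a, b = "ACGTACGTA", "ACGTACCTA"
        ca, cb = validate_tsd(a, b), validate_tsd(b, a)
        assert (ca.valid, ca.mismatches) == (cb.valid, cb.mismatches)


def _oracle_tsd_valid(left: str, right: str) -> bool:
    """Independent enumeration of the per-length tolerance rules.

    Tries every alignment with zero gaps or exactly one single-base gap and
    applies: length 8 -> at most one mismatch-or-indel in total; length 9-11
    -> at most 2 mismatches gapless, or at most 1 mismatch with one gap.
    """
    length = max(len(left), len(right))
    if not 8 <= length <= 11:
        return False
    if len(left) == len(right):
        mm = sum(a != b for a, b in zip(left, right))
        gapless_ok = mm <= (1 if length == 8 else 2)
        if gapless_ok:
            return True
    if abs(len(left) - len(right)) == 1:
        short, long_ = sorted((left, right), key=len)
        best = min(
            sum(a != b for a, b in zip(short[:g], long_[:g]))
            + sum(a != b for a, b in zip(short[g:], long_[g + 1 :]))
            for g in range(len(short) + 1)
        )
        return best <= (0 if length == 8 else 1)
    return False


def test_tsd_rules_match_bruteforce_oracle():
    """Exhaustive mismatch/indel configurations for lengths 8-11 agree with
    an independent enumeration of the tolerance rules."""
    rng = np.random.default_rng(0)
    for length in (8, 9, 10, 11):
        base = "".join(rng.choice(list("ACGT"), size=length))
        cases = []
        # all mismatch configurations up to 3 mismatches
        import itertools

        for n_mm in range(0, 4):
            for pos in itertools.combinations(range(length), n_mm):
                cases.append(_mutate(base, pos))
        # one-base deletions, with up to 2 extra mismatches
        for i in range(length):
            dele = base[:i] + base[i + 1 :]
            cases.append(dele)
            for p in range(len(dele)):
                cases.append(_mutate(dele, [p]))
        for right in cases:
            got = validate_tsd(base, right).valid
            want = _oracle_tsd_valid(base, right)
            assert got == want, (base, right)


# ---------------------------------------------------------------------------
# TIR pairs
# ---------------------------------------------------------------------------

class TestFindTirPairs:
    def test_planted_pair_recovered_with_identity(self, rng):
        cfg = SimConfig(seed=7, tir_identity=0.85)
        ref = make_reference_transposase(7)
        hits = 0
        for _ in range(10):
            el = plant_mule(cfg, set(), rng, reference=ref)
            seq = random_dna(1000, 0.44, rng) + el.seq + random_dna(1000, 0.44, rng)
            pairs = find_tir_pairs(seq)
            match = [
                p
                for p in pairs
                if abs(p.left[0] - 1000) < 100
                and abs(p.right[1] - (1000 + len(el.seq))) < 100
            ]
            if match and abs(match[0].identity - el.tir_identity) <= 0.03:
                hits += 1
        assert hits >= 9

    def test_direct_repeats_not_reported(self, rng):
        block = random_dna(300, 0.44, rng)
        seq = block + random_dna(3000, 0.44, rng) + block  # direct, not inverted
        assert find_tir_pairs(seq) == []

    def test_short_span_rejected(self, rng):
        tir = random_dna(200, 0.44, rng)
        seq = (
            random_dna(500, 0.44, rng)
            + tir
            + random_dna(600, 0.44, rng)  # span ~1 kb < 2 kb
            + revcomp(tir)
            + random_dna(500, 0.44, rng)
        )
        assert find_tir_pairs(seq) == []

    def test_agrees_with_bruteforce_on_small_window(self, rng):
        """Seeded search and the exhaustive fixed-length oracle find the
        same planted pair on a small window."""
        tir = random_dna(80, 0.44, rng)
        seq = (
            random_dna(300, 0.44, rng)
            + tir
            + random_dna(2400, 0.44, rng)
            + revcomp(tir)
            + random_dna(300, 0.44, rng)
        )
        fast = find_tir_pairs(seq, tir_len_range=(50, 200))
        brute = brute_force_tir_pairs(seq, 80)
        assert fast and brute
        best_brute = max(brute, key=lambda p: p.identity)
        assert abs(fast[0].left[0] - best_brute.left[0]) <= 5
        assert abs(fast[0].right[1] - best_brute.right[1]) <= 5


# ---------------------------------------------------------------------------
# Translated homology search
# ---------------------------------------------------------------------------

class TestTranslatedScan:
    def test_exact_backtranslation_found(self, rng, reference):
        cds = back_translate(reference.protein[100:300], rng)
        seq = random_dna(2000, 0.44, rng) + cds + random_dna(2000, 0.44, rng)
        hits = translated_search("t", seq, {"q": reference.protein})
        assert hits
        best = max(hits, key=lambda h: h.score)
        assert best.start <= 2000 + 10 and best.end >= 2000 + len(cds) - 10

    def test_null_rate_on_random_sequence(self, rng):
        """Random 100 kb yields no hit at the default threshold for nearly
        all seeds."""
        ref = make_reference_transposase(99)
        n_hit = 0
        for seed in range(8):
            seq = random_dna(100_000, 0.44, np.random.default_rng(seed))
            if translated_search("t", seq, {"q": ref.protein}):
                n_hit += 1
        assert n_hit == 0

    def test_frameshift_splits_hit_across_frames(self, rng, reference):
        cfg = SimConfig(seed=7)
        el = plant_mule(cfg, {"frameshift"}, rng, reference=reference)
        hits = translated_search("t", el.seq, {"q": reference.protein})
        plus_frames = {h.frame for h in hits if h.strand == "+"}
        assert len(plus_frames) >= 2


# ---------------------------------------------------------------------------
# Candidate calling
# ---------------------------------------------------------------------------

class TestCallCandidates:
    def test_recovery_on_simulated_genome(self, small_sim):
        _, genome, _, truth = small_sim
        ref = make_reference_transposase(7)
        hits = translated_homology_scan(genome, {ref.id: ref.protein})
        calls = call_candidate_elements(genome, hits)
        true_spans = [el.genome_span for el in truth.elements.values()]
        matched = sum(
            any(
                abs(c.span[0] - t[0]) <= 20 and abs(c.span[1] - t[1]) <= 20
                for t in true_spans
            )
            for c in calls
        )
        assert matched / len(calls) >= 0.9
        assert matched / len(true_spans) >= 0.9

    def test_scrambled_tsd_not_called(self, rng, reference):
        """An element whose flanks share no direct repeat fails criterion 3."""
        cfg = SimConfig(seed=7)
        el = plant_mule(cfg, set(), rng, reference=reference)
        # flanks deliberately unrelated: no TSD copies at all
        seq = random_dna(3000, 0.44, rng) + el.seq + random_dna(3000, 0.44, rng)
        from mulescan.io_formats import GenomeRecord

        genome = GenomeRecord("t", seq)
        hits = translated_homology_scan(genome, {reference.id: reference.protein})
        calls = call_candidate_elements(genome, hits)
        assert calls == []

    def test_low_tir_identity_not_called(self, rng, reference):
        cfg = SimConfig(seed=7, tir_identity=0.76)
        el = plant_mule(cfg, set(), rng, reference=reference)
        # degrade the TIR pair to ~60% identity
        tir_len = el.tir_len
        n_extra = int(0.3 * tir_len)
        left = _mutate(el.seq[:tir_len], range(0, 2 * n_extra, 2))
        seq = (
            random_dna(2500, 0.44, rng)
            + el.tsd + left + el.seq[tir_len:] + el.tsd
            + random_dna(2500, 0.44, rng)
        )
        from mulescan.io_formats import GenomeRecord

        genome = GenomeRecord("t", seq)
        hits = translated_homology_scan(genome, {reference.id: reference.protein})
        calls = call_candidate_elements(genome, hits)
        for c in calls:
            assert c.tir.identity > 0.75  # anything still called re-validates

    def test_strand_symmetry(self, rng, reference):
        """Reverse-complementing the genome mirrors the calls."""
        cfg = SimConfig(seed=7)
        el = plant_mule(cfg, set(), rng, reference=reference)
        seq = (
            random_dna(2500, 0.44, rng)
            + el.tsd + el.seq + el.tsd
            + random_dna(2500, 0.44, rng)
        )
        from mulescan.io_formats import GenomeRecord

        fwd = GenomeRecord("t", seq)
        rev = GenomeRecord("t", revcomp(seq))
        prot = {reference.id: reference.protein}
        calls_f = call_candidate_elements(fwd, translated_homology_scan(fwd, prot))
        calls_r = call_candidate_elements(rev, translated_homology_scan(rev, prot))
        assert len(calls_f) == len(calls_r) == 1
        n = len(seq)
        mirrored = (n - calls_r[0].span[1], n - calls_r[0].span[0])
        assert abs(mirrored[0] - calls_f[0].span[0]) <= 10
        assert abs(mirrored[1] - calls_f[0].span[1]) <= 10


# ---------------------------------------------------------------------------
# Representatives and size profile
# ---------------------------------------------------------------------------

class TestClusterRepresentatives:
    def test_identical_elements_collapse(self, rng):
        seq = random_dna(2000, 0.44, rng)
        assert cluster_representatives([("a", seq), ("b", seq)]) == ["a"]

    def test_distant_elements_retained(self, rng):
        a = random_dna(2000, 0.44, rng)
        b = random_dna(2000, 0.44, rng)  # unrelated, ~25% identity
        assert len(cluster_representatives([("a", a), ("b", b)])) == 2

    def test_large_family_collapses_to_few(self, rng):
        base = random_dna(2000, 0.44, rng)
        members = []
        for i in range(20):
            mutated = _mutate(base, rng.choice(2000, size=100, replace=False))
            members.append((f"m{i}", mutated))  # ~95% identity family
        reps = cluster_representatives(members)
        assert len(reps) < len(members)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cluster_representatives([])


class TestSizeProfile:
    def test_binning_and_fractions(self):
        prof = size_profile({"a": 3000, "b": 5000, "c": 9000, "d": 4000})
        assert prof["2-3.5kb"]["count"] == 1
        assert prof["3.5-8kb"]["count"] == 2
        assert prof[">8kb"]["count"] == 1
        assert sum(v["fraction"] for v in prof.values()) == pytest.approx(1.0)

    def test_sub2kb_kept_in_smallest_bin(self):
        prof = size_profile({"tiny": 1500})
        assert prof["2-3.5kb"]["count"] == 1
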