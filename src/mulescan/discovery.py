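"""Candidate coding-MULE discovery.

An element call requires three things, checked in order around each
transposase homology hit: a pair of terminal inverted repeats (TIRs) above
75% identity in inverted orientation spanning 2-30 kb, the homology hit
located between the TIRs, and a valid 8-11 bp target site duplication (TSD)
immediately flanking the TIRs.  TSD validity follows per-length tolerance
rules: at 8 bp one mismatch or one single-nucleotide indel is allowed; at
9-11 bp up to two mismatches, or one mismatch plus one indel.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import edlib

from .alignment import (
    NucScoring,
    TranslatedHit,
    cluster_seeds,
    make_nuc_aligner,
    revcomp,
    translated_search,
)
from .io_formats import GenomeRecord

logger = logging.getLogger(__name__)

SPAN_RANGE = (2000, 30000)  # TIR-start to TIR-end, nested insertions included
TSD_LEN_RANGE = (8, 11)


# ---------------------------------------------------------------------------
# TSD validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TsdCall:
    left_seq: str
    right_seq: str
    length: int  # scored at the longer of the two copies
    mismatches: int
    indels: int
    valid: bool


def _best_one_gap_alignment(short: str, long: str) -> int:
    """Minimum mismatches aligning ``short`` to ``long`` with one gap."""
    best = len(long)
    for g in range(len(short) + 1):
        mm = sum(a != b for a, b in zip(short[:g], long[:g]))
        mm += sum(a != b for a, b in zip(short[g:], long[g + 1 :]))
        best = min(best, mm)
    return best


def validate_tsd(left: str, right: str) -> TsdCall:
    """Score a putative TSD pair under the per-length tolerance rules."""
    left, right = left.upper(), right.upper()
    ll, lr = len(left), len(right)
    length = max(ll, lr)
    if ll == lr:
        mismatches = sum(a != b for a, b in zip(left, right))
        indels = 0
    elif abs(ll - lr) == 1:
        short, long_ = (left, right) if ll < lr else (right, left)
        mismatches = _best_one_gap_alignment(short, long_)
        indels = 1
    else:
        return TsdCall(left, right, length, -1, -1, False)
    if not (TSD_LEN_RANGE[0] <= length <= TSD_LEN_RANGE[1]):
        return TsdCall(left, right, length, mismatches, indels, False)
    if length == 8:
        valid = (mismatches + indels) <= 1
    else:
        valid = (indels == 0 and mismatches <= 2) or (
            indels == 1 and mismatches <= 1
        )
    return TsdCall(left, right, length, mismatches, indels, valid)


# ---------------------------------------------------------------------------
# TIR pair search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TirPair:
    """A left/right inverted-repeat pair (window-absolute coordinates)."""

    left: tuple[int, int]
    right: tuple[int, int]
    identity: float

    @property
    def span(self) -> tuple[int, int]:
        return (self.left[0], self.right[1])

    @property
    def span_len(self) -> int:
        return self.right[1] - self.left[0]


def _refine_tir_pair(
    seq: str,
    left_est: tuple[int, int],
    right_est: tuple[int, int],
    margin: int,
    aligner,
) -> TirPair | None:
    """Polish seed-cluster intervals by local alignment of L vs revcomp(R).

    Local alignment trims the flanking background off both arms; identity is
    matches over the aligned columns of the local core.
    """
    n = len(seq)
    la = max(0, left_est[0] - margin)
    lb = min(n, left_est[1] + margin)
    ra = max(0, right_est[0] - margin)
    rb = min(n, right_est[1] + margin)
    if lb <= la or rb <= ra:
        return None
    L = seq[la:lb]
    R = revcomp(seq[ra:rb])
    aln = aligner.align(L, R)[0]
    blocks_l, blocks_r = aln.aligned
    if len(blocks_l) == 0:
        return None
    # trim to the aligned core (terminal gaps are free in this aligner)
    l_lo, l_hi = blocks_l[0][0], blocks_l[-1][1]
    r_lo, r_hi = blocks_r[0][0], blocks_r[-1][1]
    matches = 0
    cols = 0
    for (sa, ea), (sb, eb) in zip(blocks_l, blocks_r):
        cols += ea - sa
        matches += sum(x == y for x, y in zip(L[sa:ea], R[sb:eb]))
    if cols == 0:
        return None
    identity = matches / cols
    left_iv = (la + l_lo, la + l_hi)
    # revcomp coordinate flip back into seq space
    right_iv = (rb - r_hi, rb - r_lo)
    return TirPair(left_iv, right_iv, identity)


def find_tir_pairs(
    seq: str,
    *,
    offset: int = 0,
    tir_len_range: tuple[int, int] = (50, 800),
    min_identity: float = 0.75,
    span_range: tuple[int, int] = SPAN_RANGE,
    seed_k: int = 12,
    diag_band: int = 60,
    max_seed_gap: int = 400,
    margin: int = 40,
) -> list[TirPair]:
    """Find inverted-repeat pairs by seed clustering plus alignment polish.

    Seeds are exact ``seed_k``-mer matches between the window and its reverse
    complement; clusters on near-constant diagonals propose (left, right)
    intervals that are refined by a free-end-gap global alignment of the left
    arm against the reverse complement of the right arm.  Identity is
    matches over aligned columns with terminal gaps excluded.  Coordinates
    are reported shifted by ``offset``.
    """
    n = len(seq)
    if n < span_range[0]:
        return []
    rc = revcomp(seq)
    kmer_pos: dict[str, list[int]] = {}
    for j in range(n - seed_k + 1):
        kmer_pos.setdefault(rc[j : j + seed_k], []).append(j)
    seeds: list[tuple[int, int]] = []  # (diagonal, i)
    seed_diag: dict[tuple[int, int], int] = {}
    for i in range(n - seed_k + 1):
        for j in kmer_pos.get(seq[i : i + seed_k], ()):
            # left arm candidate at i, right arm at [n-j-k, n-j)
            right_end = n - j
            if right_end - i < span_range[0] - diag_band:
                continue  # too close (includes palindromic self-matches)
            seeds.append((j - i, i))
    if not seeds:
        return []
    max_extent = tir_len_range[1] + 2 * margin
    clusters = cluster_seeds(seeds, seed_k, diag_band, max_seed_gap, 1, max_extent)

    # mild mismatch penalty: noisy (but real) TIR ends stay in the local
    # alignment instead of being trimmed tens of bp short of the boundary
    aligner = make_nuc_aligner(
        NucScoring(match=1, mismatch=-0.75, gap_open=-4, gap_extend=-1), mode="local"
    )
    pairs: list[TirPair] = []
    for i_lo, i_hi in clusters:
        members = [d for (d, i) in seeds if i_lo <= i < i_hi]
        d_med = sorted(members)[len(members) // 2]
        j_lo = i_lo + d_med
        j_hi = i_hi + d_med
        right_est = (n - j_hi, n - j_lo)
        left_est = (i_lo, i_hi)
        if left_est[0] > right_est[0]:  # mirrored cluster of the same pair
            left_est, right_est = right_est, left_est
        pair = _refine_tir_pair(seq, left_est, right_est, margin, aligner)
        if pair is None:
            continue
        tir_len = min(pair.left[1] - pair.left[0], pair.right[1] - pair.right[0])
        if not (tir_len_range[0] <= tir_len <= tir_len_range[1]):
            continue
        if pair.identity <= min_identity:
            continue
        if not (span_range[0] <= pair.span_len <= span_range[1]):
            continue
        if pair.left[1] > pair.right[0]:
            continue  # arms overlap
        pairs.append(pair)
    # dedupe near-identical pairs from mirrored seed clusters
    uniq: list[TirPair] = []
    for p in sorted(pairs, key=lambda p: (-p.identity, p.span_len)):
        if any(
            abs(p.left[0] - q.left[0]) < 30 and abs(p.right[1] - q.right[1]) < 30
            for q in uniq
        ):
            continue
        uniq.append(p)
    if offset:
        uniq = [
            TirPair(
                (p.left[0] + offset, p.left[1] + offset),
                (p.right[0] + offset, p.right[1] + offset),
                p.identity,
            )
            for p in uniq
        ]
    uniq.sort(key=lambda p: p.left)
    return uniq


def brute_force_tir_pairs(
    seq: str,
    tir_len: int,
    *,
    min_identity: float = 0.75,
    span_range: tuple[int, int] = SPAN_RANGE,
) -> list[TirPair]:
    """Exhaustive fixed-length inverted-repeat search (test oracle).

    Quadratic in the window length; only sensible on small windows.
    Identity here is ungapped (Hamming) over the fixed-length arms.
    """
    n = len(seq)
    out = []
    for a in range(n - tir_len + 1):
        left = seq[a : a + tir_len]
        for c in range(a + 1, n - tir_len + 1):
            span = c + tir_len - a
            if not (span_range[0] <= span <= span_range[1]):
                continue
            if c < a + tir_len:
                continue
            right_rc = revcomp(seq[c : c + tir_len])
            ident = sum(x == y for x, y in zip(left, right_rc)) / tir_len
            if ident > min_identity:
                out.append(TirPair((a, a + tir_len), (c, c + tir_len), ident))
    return out


# ---------------------------------------------------------------------------
# Candidate calling
# ---------------------------------------------------------------------------

@dataclass
class CandidateMule:
    id: str
    seq_id: str
    span: tuple[int, int]  # genome coordinates, TIR start to TIR end
    tir: TirPair
    tsd: TsdCall
    strand: str
    internal_hit: TranslatedHit

    @property
    def span_len(self) -> int:
        return self.span[1] - self.span[0]


def translated_homology_scan(
    genome: GenomeRecord,
    proteins: dict[str, str],
    min_score: float = 80.0,
) -> list[TranslatedHit]:
    """Six-frame translated homology search of reference transposases."""
    if not proteins:
        raise ValueError("no query proteins")
    return translated_search(genome.id, genome.seq, proteins, min_score=min_score)


def _try_tsds(
    genome_seq: str, pair: TirPair, max_extension: int = 160
) -> tuple[TsdCall, int, int] | None:
    """Best valid TSD flanking a TIR pair, with boundary adjustments.

    The aligned TIR core can be off by a few bp (mismatched terminal
    columns), occasionally trimmed deep where mutations cluster at a TIR
    end, or over-extended where the flanks happen to align; the true
    element boundary is defined by the TSD itself.  Within +-3 bp of the
    aligned boundary the full per-length tolerance rules apply; farther out
    (to ``max_extension`` bp either way) only an exact direct repeat is
    accepted, and the two boundary shifts must be near-opposite, because
    the trim or overshoot depth is shared by the two ends of one local
    alignment.  Candidates from both ranges are ranked by fewest TSD edits,
    then longest TSD, then smallest boundary adjustment.  Returns the call
    and the chosen (dl, dr) boundary offsets.
    """
    len_combos = [
        (len_l, len_r)
        for len_l, len_r in itertools.product(range(7, 12), repeat=2)
        if abs(len_l - len_r) <= 1
        and TSD_LEN_RANGE[0] <= max(len_l, len_r) <= TSD_LEN_RANGE[1]
    ]

    def scan(offsets, exact_only: bool):
        best: tuple[tuple, TsdCall, int, int] | None = None
        for dl, dr in offsets:
            ls = pair.left[0] + dl
            re = pair.right[1] + dr
            if ls < TSD_LEN_RANGE[1] or re + TSD_LEN_RANGE[1] > len(genome_seq):
                continue
            if re - ls < SPAN_RANGE[0]:
                continue
            for len_l, len_r in len_combos:
                call = validate_tsd(
                    genome_seq[ls - len_l : ls], genome_seq[re : re + len_r]
                )
                if not call.valid:
                    continue
                edits = call.mismatches + call.indels
                if exact_only and edits > 0:
                    continue
                key = (edits, -call.length, abs(dl) + abs(dr))
                if best is None or key < best[0]:
                    best = (key, call, dl, dr)
        return best

    near = scan(itertools.product(range(-3, 4), repeat=2), exact_only=False)
    if near is not None and near[0][0] == 0:
        return near[1], near[2], near[3]  # exact repeat at the boundary
    # outward shifts (alignment trimmed short of the boundary) can be deep;
    # inward shifts (alignment overshoot past the boundary) are bounded by
    # the overshoot dynamics of the local alignment, so they stay shallow
    max_inward = 45
    far_offsets = [
        (dl, dr)
        for dl in range(-max_extension, max_inward + 1)
        for dr in range(-dl - 6, -dl + 7)
        if max(abs(dl), abs(dr)) > 3 and -max_inward <= dr <= max_extension
    ]
    far = scan(far_offsets, exact_only=True)
    best = min(
        (c for c in (near, far) if c is not None),
        key=lambda c: c[0],
        default=None,
    )
    return None if best is None else (best[1], best[2], best[3])


def call_candidate_elements(
    genome: GenomeRecord,
    hits: list[TranslatedHit],
    *,
    window: int = 50_000,
    tir_len_range: tuple[int, int] = (50, 800),
    min_identity: float = 0.75,
    span_range: tuple[int, int] = SPAN_RANGE,
) -> list[CandidateMule]:
    """Combine homology hits, TIR pairs, and TSD checks into element calls.

    For each hit the surrounding +/- ``window`` bp are scanned for TIR pairs;
    a candidate is emitted when the hit lies between the TIRs and a valid
    TSD flanks them.  When several pairs explain one hit the pair with a
    valid TSD, then highest TIR identity, then smallest span wins.  Each
    genomic span is reported once.
    """
    seen_spans: dict[tuple[int, int], CandidateMule] = {}
    tir_cache: dict[tuple[int, int], list[TirPair]] = {}
    for hit in sorted(hits, key=lambda h: (h.start, -h.score)):
        w_lo = max(0, hit.start - window)
        w_hi = min(len(genome.seq), hit.end + window)
        cache_key = (w_lo, w_hi)
        if cache_key not in tir_cache:
            tir_cache[cache_key] = find_tir_pairs(
                genome.seq[w_lo:w_hi],
                offset=w_lo,
                tir_len_range=tir_len_range,
                min_identity=min_identity,
                span_range=span_range,
            )
        candidates: list[tuple[tuple, TirPair, TsdCall, int, int]] = []
        for pair in tir_cache[cache_key]:
            if not (pair.left[1] - 30 <= hit.start and hit.end <= pair.right[0] + 30):
                continue
            found = _try_tsds(genome.seq, pair)
            if found is None:
                continue
            tsd, dl, dr = found
            candidates.append(((-pair.identity, pair.span_len), pair, tsd, dl, dr))
        if not candidates:
            continue
        candidates.sort(key=lambda c: c[0])
        _, pair, tsd, dl, dr = candidates[0]
        # the TSD defines the element boundary; extend the aligned TIR core
        span = (pair.left[0] + dl, pair.right[1] + dr)
        if not (span_range[0] <= span[1] - span[0] <= span_range[1]):
            continue
        pair = TirPair((span[0], pair.left[1]), (pair.right[0], span[1]), pair.identity)
        if span in seen_spans:
            continue
        cm = CandidateMule(
            id=f"CM_{genome.id}_{span[0]}",
            seq_id=genome.id,
            span=span,
            tir=pair,
            tsd=tsd,
            strand=hit.strand,
            internal_hit=hit,
        )
        seen_spans[span] = cm
    calls = sorted(seen_spans.values(), key=lambda c: c.span)
    # drop calls nested inside an identical larger call footprint
    return calls


# ---------------------------------------------------------------------------
# Representative clustering and size profile
# ---------------------------------------------------------------------------

def cluster_representatives(
    elements: list[tuple[str, str]],
    id_thresh: float = 0.80,
    cov_thresh: float = 0.80,
) -> list[str]:
    """Greedy representative selection: one element per >=80%/80% cluster.

    ``elements`` are (id, sequence) tuples.  The longest element of each
    cluster (ties broken by lexicographically smallest id) represents it.
    """
    if not elements:
        raise ValueError("no elements to cluster")
    ordered = sorted(elements, key=lambda e: (-len(e[1]), e[0]))
    reps: list[tuple[str, str]] = []
    for eid, seq in ordered:
        assigned = False
        for rid, rseq in reps:
            short, long_ = (seq, rseq) if len(seq) <= len(rseq) else (rseq, seq)
            res = edlib.align(short, long_, mode="HW", task="locations")
            dist = res["editDistance"]
            aligned_len = len(short)
            identity = max(0.0, 1.0 - dist / aligned_len)
            coverage = aligned_len / len(short)
            if identity >= id_thresh and coverage >= cov_thresh:
                assigned = True
                break
        if not assigned:
            reps.append((eid, seq))
    return [rid for rid, _ in reps]


SIZE_BINS = ((2000, 3500), (3500, 8000), (8000, 30000))
SIZE_BIN_LABELS = ("2-3.5kb", "3.5-8kb", ">8kb")


def size_profile(lengths: dict[str, int]) -> dict[str, dict[str, float]]:
    """Histogram of element lengths (after nested-TE removal) over the
    standard bins [2,3.5), [3.5,8), [8,30] kb.

    Elements under 2 kb after stripping are kept in the smallest bin with a
    warning.
    """
    counts = dict.fromkeys(SIZE_BIN_LABELS, 0)
    for eid, ln in lengths.items():
        if ln < 2000:
            logger.warning("element %s is %d bp (<2 kb) after stripping", eid, ln)
            counts[SIZE_BIN_LABELS[0]] += 1
            continue
        for (lo, hi), label in zip(SIZE_BINS, SIZE_BIN_LABELS):
            if lo <= ln < hi or (label == SIZE_BIN_LABELS[-1] and ln >= lo):
                counts[label] += 1
                break
    total = sum(counts.values())
    return {
        label: {
            "count": counts[label],
            "fraction": counts[label] / total if total else 0.0,
        }
        for label in SIZE_BIN_LABELS
    }
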