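"""Pairwise-alignment utilities shared across the pipeline.

Global nucleotide alignment uses GCG-``gap``-like affine scoring (match +1,
mismatch -2, gap open -8, gap extend -1) unless overridden.  Protein local
alignment uses BLOSUM62 with affine gaps (open -11, extend -1).  The
translated homology search is a small seed-and-extend scheme: exact amino
acid k-mer seeds are clustered by diagonal per reading frame and each cluster
is refined by local alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a DNA string; stops are '*', ambiguous codons 'X'."""
    n = len(seq) - len(seq) % 3
    return "".join(CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, n, 3))


@dataclass(frozen=True)
class NucScoring:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -8.0
    gap_extend: float = -1.0


def make_nuc_aligner(scoring: NucScoring = NucScoring(), mode: str = "global") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    if mode == "global":
        # terminal gaps are free: identity and indel counts ignore overhangs
        aligner.end_gap_score = 0.0
    return aligner


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def make_protein_aligner(open_gap: float = -11.0, extend_gap: float = -1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


@dataclass
class GlobalAlignmentStats:
    """Summary of one global nucleotide alignment.

    ``n_indels`` counts maximal internal gap runs (one run = one indel
    regardless of length); terminal overhangs are excluded from everything.
    ``identity`` is matches over non-gap aligned columns.
    """

    aligned_cols: int
    matches: int
    mismatches: int
    n_indels: int
    indel_len_total: int
    transitions: int = 0
    transversions: int = 0

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_cols if self.aligned_cols else 0.0


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def global_alignment_stats(
    a: str, b: str, scoring: NucScoring = NucScoring()
) -> GlobalAlignmentStats:
    """Globally align two nucleotide sequences and summarise the alignment."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = make_nuc_aligner(scoring)
    aln = aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    matches = mismatches = 0
    ts = tv = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        for ca, cb in zip(a[sa:ea], b[sb:eb]):
            if ca == cb:
                matches += 1
            else:
                mismatches += 1
                if (ca, cb) in _TRANSITIONS:
                    ts += 1
                else:
                    tv += 1
    n_indels = 0
    indel_len_total = 0
    for i in range(len(blocks_a) - 1):
        gap_a = blocks_a[i + 1][0] - blocks_a[i][1]
        gap_b = blocks_b[i + 1][0] - blocks_b[i][1]
        if gap_a > 0:
            n_indels += 1
            indel_len_total += gap_a
        if gap_b > 0:
            n_indels += 1
            indel_len_total += gap_b
    aligned_cols = matches + mismatches
    return GlobalAlignmentStats(
        aligned_cols=aligned_cols,
        matches=matches,
        mismatches=mismatches,
        n_indels=n_indels,
        indel_len_total=indel_len_total,
        transitions=ts,
        transversions=tv,
    )


# ---------------------------------------------------------------------------
# Translated homology search (seed-and-extend)
# ---------------------------------------------------------------------------

@dataclass
class TranslatedHit:
    """A local translated-alignment hit of a protein query on a genome."""

    seq_id: str
    start: int  # genome nt coordinates, 0-based half-open, plus strand
    end: int
    strand: str
    frame: int  # 0-2 forward, 3-5 reverse
    query_id: str
    query_start: int  # aa coordinates on the query
    query_end: int
    score: float

    @property
    def query_coverage_len(self) -> int:
        return self.query_end - self.query_start


def cluster_seeds(
    seeds: list[tuple[int, int]],
    k: int,
    diag_band: int,
    max_gap: int,
    min_seeds: int,
    max_extent: int,
) -> list[tuple[int, int]]:
    """Group (diagonal, position) seeds into position intervals.

    Seeds are bucketed into diagonal bands; within a band they chain while
    consecutive positions are within ``max_gap``.  Overlapping intervals from
    adjacent bands merge, and any interval longer than ``max_extent`` is
    discarded as a repeat artefact rather than aligned.
    """
    if not seeds:
        return []
    buckets: dict[int, list[int]] = {}
    for d, t in seeds:
        buckets.setdefault(d // diag_band, []).append(t)
    intervals: list[tuple[int, int]] = []
    for band in sorted(buckets):
        pts = sorted(buckets[band])
        runs: list[list[int]] = [[pts[0]]]
        for t in pts[1:]:
            if t - runs[-1][-1] <= max_gap:
                runs[-1].append(t)
            else:
                runs.append([t])
        for run in runs:
            if len(run) >= min_seeds:
                intervals.append((run[0], run[-1] + k))
    intervals.sort()
    merged: list[list[int]] = []
    for lo, hi in intervals:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged if hi - lo <= max_extent]


def _seed_clusters(
    frame_prot: str,
    query_kmers: dict[str, list[int]],
    k: int,
    diag_band: int,
    max_gap: int,
    min_seeds: int,
    max_extent: int,
) -> list[tuple[int, int]]:
    """Cluster exact k-mer seeds by diagonal; return target aa intervals."""
    seeds: list[tuple[int, int]] = []  # (diagonal, target_pos)
    for t in range(len(frame_prot) - k + 1):
        for q in query_kmers.get(frame_prot[t : t + k], ()):
            seeds.append((t - q, t))
    return cluster_seeds(seeds, k, diag_band, max_gap, min_seeds, max_extent)


def translated_search(
    seq_id: str,
    dna: str,
    proteins: dict[str, str],
    *,
    min_score: float = 80.0,
    k: int = 4,
    diag_band: int = 20,
    max_gap: int = 120,
    min_seeds: int = 2,
    margin: int = 60,
    both_strands: bool = True,
) -> list[TranslatedHit]:
    """Six-frame translated local search of ``proteins`` against ``dna``.

    Returns hits with score >= ``min_score``; overlapping hits on the same
    frame are merged (best score kept).
    """
    aligner = make_protein_aligner()
    n = len(dna)
    hits: list[TranslatedHit] = []
    strands = [("+", dna)]
    if both_strands:
        strands.append(("-", revcomp(dna)))
    for query_id, prot_query in proteins.items():
        query_kmers: dict[str, list[int]] = {}
        for q in range(len(prot_query) - k + 1):
            query_kmers.setdefault(prot_query[q : q + k], []).append(q)
        for strand, s in strands:
            for frame in range(3):
                frame_prot = translate(s[frame:])
                if not frame_prot:
                    continue
                max_extent = int(1.5 * len(prot_query)) + 100
                for lo, hi in _seed_clusters(
                    frame_prot, query_kmers, k, diag_band, max_gap, min_seeds,
                    max_extent,
                ):
                    w_lo = max(0, lo - margin)
                    w_hi = min(len(frame_prot), hi + margin)
                    target = frame_prot[w_lo:w_hi]
                    alns = aligner.align(target, prot_query)
                    if alns.score < min_score:
                        continue
                    aln = alns[0]
                    (t_blocks, q_blocks) = aln.aligned
                    t_start = w_lo + t_blocks[0][0]
                    t_end = w_lo + t_blocks[-1][1]
                    q_start = q_blocks[0][0]
                    q_end = q_blocks[-1][1]
                    if strand == "+":
                        g_start = frame + 3 * t_start
                        g_end = frame + 3 * t_end
                        frame_id = frame
                    else:
                        g_start = n - (frame + 3 * t_end)
                        g_end = n - (frame + 3 * t_start)
                        frame_id = frame + 3
                    hits.append(
                        TranslatedHit(
                            seq_id=seq_id,
                            start=g_start,
                            end=g_end,
                            strand=strand,
                            frame=frame_id,
                            query_id=query_id,
                            query_start=q_start,
                            query_end=q_end,
                            score=float(alns.score),
                        )
                    )
    return merge_hits(hits)


def merge_hits(hits: Sequence[TranslatedHit]) -> list[TranslatedHit]:
    """Merge genome-overlapping hits on the same frame, keeping the best."""
    out: list[TranslatedHit] = []
    for hit in sorted(hits, key=lambda h: (h.frame, h.query_id, h.start, -h.score)):
        prev = out[-1] if out else None
        if (
            prev is not None
            and prev.frame == hit.frame
            and prev.query_id == hit.query_id
            and hit.start < prev.end
        ):
            if hit.score > prev.score:
                out[-1] = hit
        else:
            out.append(hit)
    out.sort(key=lambda h: (h.start, h.frame))
    return out
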