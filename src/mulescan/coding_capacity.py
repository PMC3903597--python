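"""Transposase coding-region mapping and defect classification.

Each (nested-TE-stripped) element is aligned in translated frames to the
reference transposase.  The union of alignment blocks defines the coding
region; block structure and per-column alignment detail drive the defect
calls:

* frameshift      - consecutive blocks in different reading frames;
* premature stop  - an in-frame stop aligned before 95% of the aligned
                    reference span;
* deletion        - a reference-coverage gap of at least 30 aa (internal or
                    terminal, so lost HTH/DDE regions count);
* DDE/start loss  - a mutated catalytic residue, or no Met within 30 codons
                    of the aligned reference start.

A transposase is intact when the HTH DNA-binding segment and the DDE
catalytic triad are present (first-D-to-E span over 100 aa, clean of stops
and frameshifts) and no defect is recorded.  Elements are then placed into
six groups: I intact; II DDE/start mutation; III frameshift; IV premature
stop; V frameshift + premature stop; VI deletions — once redundantly (an
element may satisfy several groups) and once uniquely, with deletion
subtypes keyed by the co-occurring defects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment import (
    _seed_clusters,
    make_protein_aligner,
    revcomp,
    translate,
)
from .simulate import ReferenceTransposase

logger = logging.getLogger(__name__)

DELETION_MIN_AA = 30  # reference-coverage gap that counts as a deletion
PREMATURE_FRACTION = 0.95  # stop before this fraction of the aligned span
START_SCAN_CODONS = 30
HTH_MIN_COVERAGE = 0.80
HTH_MIN_IDENTITY = 0.40
MIN_BLOCK_SCORE = 60.0

DEFECT_NAMES = ("dde_or_start_mutation", "frameshift", "premature_stop", "deletion")


@dataclass
class CodingBlock:
    """One translated-alignment block between element and reference."""

    frame: int  # 0-2 forward, 3-5 reverse strand of the element
    score: float
    ref_cols: list[int]  # aligned reference aa columns
    elem_aas: str  # element residue per aligned column ('*' = stop)
    elem_nt_starts: list[int]  # element nt coordinate of each codon (plus strand)

    @property
    def ref_span(self) -> tuple[int, int]:
        return (self.ref_cols[0], self.ref_cols[-1] + 1)

    @property
    def elem_nt_span(self) -> tuple[int, int]:
        lo = min(self.elem_nt_starts)
        hi = max(self.elem_nt_starts) + 3
        return (lo, hi)


@dataclass
class TransposaseAnnotation:
    element_id: str
    coding_interval: tuple[int, int] | None  # element nt coordinates
    blocks: list[CodingBlock] = field(default_factory=list)
    hth_present: bool = False
    dde_present: bool = False
    defects: set[str] = field(default_factory=set)

    @property
    def intact(self) -> bool:
        return self.hth_present and self.dde_present and not self.defects

    @property
    def frame_segments(self) -> list[tuple[tuple[int, int], int]]:
        return [(b.elem_nt_span, b.frame) for b in self.blocks]


# ---------------------------------------------------------------------------
# Block extraction
# ---------------------------------------------------------------------------

def _blocks_for_strand(
    seq: str,
    strand: str,
    reference: ReferenceTransposase,
    min_score: float,
) -> list[CodingBlock]:
    aligner = make_protein_aligner()
    prot_query = reference.protein
    k = 4
    query_kmers: dict[str, list[int]] = {}
    for q in range(len(prot_query) - k + 1):
        query_kmers.setdefault(prot_query[q : q + k], []).append(q)
    s = seq if strand == "+" else revcomp(seq)
    n = len(seq)
    blocks: list[CodingBlock] = []
    for frame in range(3):
        frame_prot = translate(s[frame:])
        if not frame_prot:
            continue
        clusters = _seed_clusters(
            frame_prot, query_kmers, k, 20, 120, 2, int(1.5 * len(prot_query)) + 100
        )
        for lo, hi in clusters:
            w_lo = max(0, lo - 60)
            w_hi = min(len(frame_prot), hi + 60)
            target = frame_prot[w_lo:w_hi]
            alns = aligner.align(target, prot_query)
            if alns.score < min_score:
                continue
            aln = alns[0]
            t_blocks, q_blocks = aln.aligned
            ref_cols: list[int] = []
            elem_aas: list[str] = []
            elem_nt: list[int] = []
            for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
                for o in range(te - ts):
                    aa_pos = w_lo + ts + o
                    ref_cols.append(qs + o)
                    elem_aas.append(frame_prot[aa_pos])
                    if strand == "+":
                        elem_nt.append(frame + 3 * aa_pos)
                    else:
                        elem_nt.append(n - (frame + 3 * aa_pos) - 3)
            frame_id = frame if strand == "+" else frame + 3
            blocks.append(
                CodingBlock(
                    frame=frame_id,
                    score=float(alns.score),
                    ref_cols=ref_cols,
                    elem_aas="".join(elem_aas),
                    elem_nt_starts=elem_nt,
                )
            )
    return blocks


def _dedupe_blocks(blocks: list[CodingBlock]) -> list[CodingBlock]:
    """Greedy by score; drop blocks mostly covering already-claimed columns."""
    accepted: list[CodingBlock] = []
    claimed: set[int] = set()
    for b in sorted(blocks, key=lambda b: -b.score):
        cols = set(b.ref_cols)
        if len(cols & claimed) > 0.5 * len(cols):
            continue
        accepted.append(b)
        claimed |= cols
    accepted.sort(key=lambda b: b.ref_cols[0])
    return accepted


def map_coding_region(
    stripped_element: str,
    reference: ReferenceTransposase,
    min_score: float = MIN_BLOCK_SCORE,
) -> TransposaseAnnotation | None:
    """Locate the transposase coding region of a stripped element.

    Both strands are scanned; the strand with the higher total block score
    wins.  Returns None (flagged upstream) when no alignment reaches the
    score threshold.
    """
    fwd = _blocks_for_strand(stripped_element, "+", reference, min_score)
    rev = _blocks_for_strand(stripped_element, "-", reference, min_score)
    blocks = fwd if sum(b.score for b in fwd) >= sum(b.score for b in rev) else rev
    blocks = _dedupe_blocks(blocks)
    if not blocks:
        logger.info("no coding region found (score threshold %.0f)", min_score)
        return None
    lo = min(b.elem_nt_span[0] for b in blocks)
    hi = max(b.elem_nt_span[1] for b in blocks)
    return TransposaseAnnotation(
        element_id="", coding_interval=(lo, hi), blocks=blocks
    )


# ---------------------------------------------------------------------------
# Domain and defect detection
# ---------------------------------------------------------------------------

def _aligned_residue(blocks: list[CodingBlock], ref_col: int) -> tuple[str, int] | None:
    """(element residue, element nt) aligned to a reference column."""
    for b in blocks:
        try:
            i = b.ref_cols.index(ref_col)
        except ValueError:
            continue
        return b.elem_aas[i], b.elem_nt_starts[i]
    return None


def _covered_ref_cols(blocks: list[CodingBlock]) -> set[int]:
    cols: set[int] = set()
    for b in blocks:
        cols.update(b.ref_cols)
    return cols


def _frameshift_in_ref_range(
    blocks: list[CodingBlock], lo: int, hi: int
) -> bool:
    frames = {
        b.frame
        for b in blocks
        if b.ref_cols[0] < hi and lo < b.ref_cols[-1] + 1
    }
    return len(frames) > 1


def _stop_in_ref_range(blocks: list[CodingBlock], lo: int, hi: int) -> bool:
    for b in blocks:
        for aa, col in zip(b.elem_aas, b.ref_cols):
            if aa == "*" and lo <= col < hi:
                return True
    return False


def detect_catalytic_domain(
    blocks: list[CodingBlock], reference: ReferenceTransposase
) -> tuple[tuple[int, int, int] | None, bool]:
    """(element nt positions of D,D,E or None, residues-mutated flag).

    The domain is present when all three catalytic residues align as D,D,E,
    the element-side first-D-to-E span exceeds 100 aa, and that span is free
    of stops and frameshifts.  The flag reports an aligned-but-mutated
    catalytic residue (a point-mutation defect, distinct from absence
    through deletion).
    """
    hits = [_aligned_residue(blocks, c) for c in reference.dde_positions]
    if any(h is None for h in hits):
        return None, False
    aas = [h[0] for h in hits]  # type: ignore[index]
    nts = [h[1] for h in hits]  # type: ignore[index]
    d1_col, _, e_col = reference.dde_positions
    if aas != ["D", "D", "E"]:
        # a point mutation is only called when the span is frameshift-free;
        # otherwise the residues sit in misaligned wrong-frame sequence
        mutated = not _frameshift_in_ref_range(blocks, d1_col, e_col + 1)
        return None, mutated
    span_aa = abs(nts[2] - nts[0]) / 3.0
    if span_aa <= 100:
        return None, False
    if _stop_in_ref_range(blocks, d1_col, e_col + 1):
        return None, False
    if _frameshift_in_ref_range(blocks, d1_col, e_col + 1):
        return None, False
    return (nts[0], nts[1], nts[2]), False


def detect_dna_binding_domain(
    blocks: list[CodingBlock], reference: ReferenceTransposase
) -> tuple[int, int] | None:
    """Element nt span of the HTH segment, or None.

    Present iff the element covers >=80% of the reference HTH at >=40% aa
    identity with no stop or frameshift inside the covered part.
    """
    h0, h1 = reference.hth_span
    pairs: list[tuple[str, str, int]] = []  # (elem aa, ref aa, elem nt)
    for b in blocks:
        for aa, col, nt in zip(b.elem_aas, b.ref_cols, b.elem_nt_starts):
            if h0 <= col < h1:
                pairs.append((aa, reference.protein[col], nt))
    if len(pairs) < HTH_MIN_COVERAGE * (h1 - h0):
        return None
    ident = sum(a == r for a, r, _ in pairs) / len(pairs)
    if ident < HTH_MIN_IDENTITY:
        return None
    if any(a == "*" for a, _, _ in pairs):
        return None
    if _frameshift_in_ref_range(blocks, h0, h1):
        return None
    nts = [nt for _, _, nt in pairs]
    return (min(nts), max(nts) + 3)


def detect_orf_defects(
    blocks: list[CodingBlock],
    reference: ReferenceTransposase,
) -> set[str]:
    """Frameshift, premature stop, deletion, and start-mutation calls."""
    defects: set[str] = set()
    covered = sorted(_covered_ref_cols(blocks))
    c0, c_last = covered[0], covered[-1]

    # deletions: uncovered reference runs >= 30 aa, termini included
    cov = set(covered)
    run = 0
    for c in range(len(reference.protein)):
        if c in cov:
            if run >= DELETION_MIN_AA:
                defects.add("deletion")
            run = 0
        else:
            run += 1
    if run >= DELETION_MIN_AA:
        defects.add("deletion")

    # frameshift: different frames among blocks, anywhere
    if len({b.frame for b in blocks}) > 1:
        defects.add("frameshift")

    # premature stop: '*' aligned before 95% of the aligned reference span
    cutoff = c0 + PREMATURE_FRACTION * (c_last - c0)
    for b in blocks:
        for aa, col in zip(b.elem_aas, b.ref_cols):
            if aa == "*" and col < cutoff:
                defects.add("premature_stop")
                break

    # start mutation: no Met within 30 codons of the aligned reference start
    # (only assessable when the reference start itself is covered)
    if c0 <= 1:
        window = [
            aa
            for b in blocks
            for aa, col in zip(b.elem_aas, b.ref_cols)
            if c0 <= col < c0 + START_SCAN_CODONS
        ]
        if window and "M" not in window:
            defects.add("dde_or_start_mutation")
    return defects


def annotate_transposase(
    element_id: str,
    stripped_element: str,
    reference: ReferenceTransposase,
    min_score: float = MIN_BLOCK_SCORE,
) -> TransposaseAnnotation | None:
    """Full coding-capacity annotation of one stripped element."""
    ann = map_coding_region(stripped_element, reference, min_score)
    if ann is None:
        return None
    ann.element_id = element_id
    ann.defects = detect_orf_defects(ann.blocks, reference)
    dde_nts, dde_mutated = detect_catalytic_domain(ann.blocks, reference)
    if dde_mutated:
        ann.defects.add("dde_or_start_mutation")
    ann.dde_present = dde_nts is not None
    ann.hth_present = detect_dna_binding_domain(ann.blocks, reference) is not None
    return ann


# ---------------------------------------------------------------------------
# Group classification
# ---------------------------------------------------------------------------

REDUNDANT_GROUPS = ("I", "II", "III", "IV", "V", "VI")
NON_REDUNDANT_GROUPS = (
    "I",
    "II",
    "III",
    "IV",
    "V",
    "VI.deletion_only",
    "VI.with_dde_or_start",
    "VI.with_frameshift",
    "VI.with_premature_stop",
    "VI.with_both",
)


@dataclass(frozen=True)
class GroupLabel:
    redundant: frozenset[str]
    non_redundant: str


def classify_groups(annotation: TransposaseAnnotation) -> GroupLabel:
    """Assign the six-group labels (redundant and unique schemes)."""
    d = annotation.defects
    if annotation.intact and d:
        raise ValueError("inconsistent annotation: intact with defects")
    red: set[str] = set()
    if annotation.intact:
        red.add("I")
    if "dde_or_start_mutation" in d:
        red.add("II")
    if "frameshift" in d:
        red.add("III")
    if "premature_stop" in d:
        red.add("IV")
    if "frameshift" in d and "premature_stop" in d:
        red.add("V")
    if "deletion" in d:
        red.add("VI")

    fs = "frameshift" in d
    stop = "premature_stop" in d
    mut = "dde_or_start_mutation" in d
    if annotation.intact:
        nr = "I"
    elif "deletion" in d:
        if fs and stop:
            nr = "VI.with_both"
        elif fs:
            nr = "VI.with_frameshift"
        elif stop:
            nr = "VI.with_premature_stop"
        elif mut:
            nr = "VI.with_dde_or_start"
        else:
            nr = "VI.deletion_only"
    elif fs and stop:
        nr = "V"
    elif fs:
        nr = "III"
    elif stop:
        nr = "IV"
    elif mut:
        nr = "II"
    else:
        # no recorded defect yet not intact (domain evidence missing):
        # treated as a deletion-type loss of domain sequence
        nr = "VI.deletion_only"
        red.add("VI")
    return GroupLabel(frozenset(red), nr)


def catalytic_domain_peptide(
    annotation: TransposaseAnnotation, reference: ReferenceTransposase
) -> str | None:
    """Element peptide aligned over the reference catalytic region.

    Used for export to external phylogenetics; stops are written as 'X'.
    """
    lo, hi = reference.catalytic_region
    out = []
    for col in range(lo, hi):
        hit = _aligned_residue(annotation.blocks, col)
        out.append("-" if hit is None else (hit[0] if hit[0] != "*" else "X"))
    pep = "".join(out)
    return pep if pep.strip("-") else None
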