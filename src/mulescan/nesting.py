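"""Nested TE insertions inside candidate elements.

Annotated TE intervals that fall strictly inside an element (excluding its
own TIRs and its own family) are insertion events; adjacent fragments of one
family within a merge window are a single event, mirroring how masking
output fragments one insertion.  Stripping excises the insertion together
with its duplicated target-site copy and returns a coordinate map between
stripped and original space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import TeAnnotation

logger = logging.getLogger(__name__)

MERGE_WINDOW = 50  # bp between fragments of one family merged into one event


@dataclass
class NestedInsertion:
    host_id: str
    start: int  # host-element coordinates
    end: int
    family: str
    te_class: str  # RNA | DNA
    tsd_len: int = 0  # duplicated target-site copy just 3' of the interval
    disrupts_coding: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InsertionPattern:
    host_id: str
    category: str  # RNA-TE | DNA-TE | RNA-DNA-TE | none
    n_insertions: int


def _infer_dup_len(element_seq: str, start: int, end: int, max_len: int = 11) -> int:
    """Length of the duplicated target site right after an insertion.

    A TE creates a short direct repeat of host sequence on insertion; the
    annotation interval covers the TE only, so the extra copy sits
    immediately 3' of it and duplicates the bases just 5' of it.  The
    longest exact duplicate (>= 3 bp) is credited to the insertion so that
    stripping restores the pre-insertion host sequence.
    """
    for length in range(max_len, 2, -1):
        if start - length < 0 or end + length > len(element_seq):
            continue
        if element_seq[end : end + length] == element_seq[start - length : start]:
            return length
    return 0


def detect_nested_insertions(
    host_id: str,
    host_span: tuple[int, int],
    tir_spans: tuple[tuple[int, int], tuple[int, int]],
    te_annotations: Sequence[TeAnnotation],
    *,
    own_families: Iterable[str] = (),
    merge_window: int = MERGE_WINDOW,
    element_seq: str | None = None,
) -> list[NestedInsertion]:
    """Call nested insertions from an annotation table.

    ``host_span`` and ``tir_spans`` are genome coordinates; returned
    insertions are in host-element coordinates.  Fragments of one family on
    one strand within ``merge_window`` bp merge into one event.  When
    ``element_seq`` (the host sequence) is given, each insertion's
    duplicated target-site copy is located by direct comparison and recorded
    so stripping can excise it.
    """
    own = set(own_families)
    s0, _ = host_span
    inside: list[TeAnnotation] = []
    for a in te_annotations:
        if a.family in own:
            continue
        if not (host_span[0] < a.start and a.end < host_span[1]):
            continue
        if a.start < tir_spans[0][1] or a.end > tir_spans[1][0]:
            continue  # overlaps a host TIR
        inside.append(a)
    inside.sort(key=lambda a: (a.family, a.strand, a.start))
    merged: list[list] = []
    for a in inside:
        if (
            merged
            and merged[-1][0] == a.family
            and merged[-1][1] == a.strand
            and a.start - merged[-1][3] <= merge_window
        ):
            merged[-1][3] = max(merged[-1][3], a.end)
        else:
            merged.append([a.family, a.strand, a.start, a.end, a.te_class])
    out = []
    for family, _strand, start, end, te_class in merged:
        tsd_len = (
            _infer_dup_len(element_seq, start - s0, end - s0)
            if element_seq is not None
            else 0
        )
        out.append(
            NestedInsertion(
                host_id=host_id,
                start=start - s0,
                end=end - s0,
                family=family,
                te_class=te_class,
                tsd_len=tsd_len,
            )
        )
    out.sort(key=lambda n: n.start)
    return out


def classify_insertion_pattern(
    host_id: str, insertions: Sequence[NestedInsertion]
) -> InsertionPattern:
    """RNA-TE / DNA-TE / RNA-DNA-TE / none, from member classes."""
    classes = {n.te_class for n in insertions}
    if not classes:
        category = "none"
    elif classes == {"RNA"}:
        category = "RNA-TE"
    elif classes == {"DNA"}:
        category = "DNA-TE"
    else:
        category = "RNA-DNA-TE"
    return InsertionPattern(host_id, category, len(insertions))


def insertion_disrupts_coding(
    insertion: NestedInsertion, coding_interval: tuple[int, int] | None
) -> bool:
    """True iff the insertion overlaps the coding interval.

    Overlap (not full containment) is used: a TE straddling a coding-region
    edge still breaks the reading frame.
    """
    if coding_interval is None:
        logger.warning(
            "element %s has no coding region; disruption set to False",
            insertion.host_id,
        )
        return False
    lo, hi = coding_interval
    return insertion.start < hi and lo < insertion.end


class CoordinateMap:
    """Bijection between stripped and original element coordinates."""

    def __init__(self, excised: Sequence[tuple[int, int]], original_len: int):
        self.excised = sorted(excised)
        self.original_len = original_len

    def to_original(self, pos: int) -> int:
        off = 0
        for a, b in self.excised:
            if a - off <= pos:
                off += b - a
            else:
                break
        return pos + off

    def to_stripped(self, pos: int) -> int | None:
        """Original -> stripped; None if the position was excised."""
        off = 0
        for a, b in self.excised:
            if pos >= b:
                off += b - a
            elif pos >= a:
                return None
            else:
                break
        return pos - off


def merge_for_strip(insertions: Sequence[NestedInsertion]) -> list[NestedInsertion]:
    """Union overlapping excision intervals (TEs inserted into nested TEs)
    into single strippable blocks; counting still uses the raw events."""
    if not insertions:
        return []
    spans = sorted((n.start, n.end + n.tsd_len, n) for n in insertions)
    merged: list[NestedInsertion] = []
    for start, end, n in spans:
        if merged and start <= merged[-1].end:
            last = merged[-1]
            last.end = max(last.end, end)
        else:
            merged.append(
                NestedInsertion(
                    host_id=n.host_id,
                    start=start,
                    end=end,
                    family=n.family,
                    te_class=n.te_class,
                    tsd_len=0,
                )
            )
    return merged


def strip_nested(
    element_seq: str, insertions: Sequence[NestedInsertion]
) -> tuple[str, CoordinateMap]:
    """Excise insertion intervals (plus their duplicated TSD copies).

    Insertions must be non-overlapping (merge first); the returned map
    translates coordinates between stripped and original space.
    """
    cuts = sorted(
        (n.start, min(len(element_seq), n.end + n.tsd_len)) for n in insertions
    )
    for (a1, b1), (a2, b2) in zip(cuts, cuts[1:]):
        if a2 < b1:
            raise ValueError(f"overlapping insertions [{a1},{b1}) and [{a2},{b2})")
    parts = []
    prev = 0
    for a, b in cuts:
        parts.append(element_seq[prev:a])
        prev = b
    parts.append(element_seq[prev:])
    return "".join(parts), CoordinateMap(cuts, len(element_seq))


def insertion_preference(
    element_spans: dict[str, tuple[int, int]],
    tsd_lens: dict[str, int],
    te_annotations: Sequence[TeAnnotation],
    element_insertions: dict[str, Sequence[NestedInsertion]],
    *,
    flank_tolerance: int = 20,
    exclude_hosts: Iterable[str] = (),
    high_copy_correction: int = 0,
) -> pd.DataFrame:
    """Two-way insertion accounting in the style of an RNA/DNA ratio table.

    Row 1: nested TE insertion events inside the elements, by class.
    Row 2: element-into-TE events: an element counts as inserted into an
    annotated TE when both its flanks (element span plus TSD, within
    ``flank_tolerance`` bp) lie inside one TE feature.  ``exclude_hosts``
    drops the element's own annotation rows.  ``high_copy_correction``
    subtracts shared-origin copies from the denominator (the corrected
    total is reported alongside).
    """
    excluded = set(exclude_hosts)
    n_total = len(element_spans)
    nested_rna = sum(
        sum(1 for n in ins if n.te_class == "RNA")
        for ins in element_insertions.values()
    )
    nested_dna = sum(
        sum(1 for n in ins if n.te_class == "DNA")
        for ins in element_insertions.values()
    )
    into_rna = into_dna = 0
    for eid, (s, e) in element_spans.items():
        tsd = tsd_lens.get(eid, 0)
        lo = s - tsd - flank_tolerance
        hi = e + tsd + flank_tolerance
        host = next(
            (
                a
                for a in te_annotations
                if a.family not in excluded
                and a.start <= lo
                and hi <= a.end
            ),
            None,
        )
        if host is not None:
            if host.te_class == "RNA":
                into_rna += 1
            else:
                into_dna += 1

    denom = n_total - high_copy_correction + (1 if high_copy_correction else 0)

    def ratio(r: int, d: int) -> float | None:
        return r / d if d else None

    rows = [
        {
            "event": "nested_te_in_element",
            "rna_te": nested_rna,
            "dna_te": nested_dna,
            "rna_dna_ratio": ratio(nested_rna, nested_dna),
            "n_elements": denom,
        },
        {
            "event": "element_into_te",
            "rna_te": into_rna,
            "dna_te": into_dna,
            "rna_dna_ratio": ratio(into_rna, into_dna),
            "n_elements": denom,
        },
    ]
    return pd.DataFrame(rows)


def nested_length_summary(
    element_insertions: dict[str, Sequence[NestedInsertion]]
) -> pd.DataFrame:
    """Counts and mean lengths of nested TEs by class (Table-1-style)."""
    rows = []
    for te_class in ("RNA", "DNA"):
        lens = [
            n.length
            for ins in element_insertions.values()
            for n in ins
            if n.te_class == te_class
        ]
        rows.append(
            {
                "te_class": te_class,
                "n_insertions": len(lens),
                "mean_length": sum(lens) / len(lens) if lens else None,
            }
        )
    total = sum(r["n_insertions"] for r in rows)
    rows.append({"te_class": "total", "n_insertions": total, "mean_length": None})
    return pd.DataFrame(rows)
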