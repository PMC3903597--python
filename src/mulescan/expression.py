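"""Expression evidence for elements from EST/flcDNA collections.

An element has expression evidence when an EST or full-length cDNA matches
it at >= 99.5% identity over (nearly) the whole EST, with at least 300 bp
matched.  Matching runs an exact-k-mer prefilter and then a unit-cost
semi-global alignment of the EST into the element.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
import pandas as pd

from .alignment import revcomp

MIN_IDENTITY = 0.995
MIN_MATCH_LEN = 300
MIN_EST_COVERAGE = 0.99
_PREFILTER_K = 16


@dataclass(frozen=True)
class ExpressionHit:
    element_id: str
    est_id: str
    identity: float
    matched_len: int
    est_coverage: float
    evidence: bool


def _align_est(element_seq: str, est_seq: str) -> tuple[float, int, float] | None:
    """(identity, matched_len, est_coverage) for the best fit, or None."""
    best = None
    for query in (est_seq, revcomp(est_seq)):
        res = edlib.align(query, element_seq, mode="HW", task="locations")
        if res["editDistance"] < 0:
            continue
        dist = res["editDistance"]
        loc = res["locations"][0]
        matched_len = loc[1] - loc[0] + 1
        # edits include indels, so identity over the aligned span
        identity = max(0.0, 1.0 - dist / max(matched_len, len(query)))
        coverage = 1.0  # HW mode aligns the full query (infix of the target)
        cand = (identity, matched_len, coverage)
        if best is None or cand > best:
            best = cand
    return best


def match_expression(
    elements: dict[str, str],
    est_records: Sequence[tuple[str, str]],
    *,
    min_identity: float = MIN_IDENTITY,
    min_match_len: int = MIN_MATCH_LEN,
    min_est_coverage: float = MIN_EST_COVERAGE,
) -> list[ExpressionHit]:
    """Score every EST against every element.

    A 16-mer prefilter skips element/EST pairs sharing no exact seed (an EST
    at 99.5% identity is guaranteed long exact stretches).  ESTs matching
    several elements credit each of them.
    """
    hits: list[ExpressionHit] = []
    elem_kmers: dict[str, set[str]] = {}
    for eid, seq in elements.items():
        kmers = set()
        for i in range(0, len(seq) - _PREFILTER_K + 1, _PREFILTER_K // 2):
            kmers.add(seq[i : i + _PREFILTER_K])
        elem_kmers[eid] = kmers
    for est_id, est_seq in est_records:
        est_fwd = {
            est_seq[i : i + _PREFILTER_K]
            for i in range(len(est_seq) - _PREFILTER_K + 1)
        }
        est_rev = {
            revcomp(est_seq)[i : i + _PREFILTER_K]
            for i in range(len(est_seq) - _PREFILTER_K + 1)
        }
        for eid, seq in elements.items():
            if not (elem_kmers[eid] & est_fwd) and not (elem_kmers[eid] & est_rev):
                continue
            res = _align_est(seq, est_seq)
            if res is None:
                continue
            identity, matched_len, coverage = res
            evidence = (
                identity >= min_identity
                and matched_len >= min_match_len
                and coverage >= min_est_coverage
            )
            hits.append(
                ExpressionHit(eid, est_id, identity, matched_len, coverage, evidence)
            )
    return hits


def element_expression(hits: Sequence[ExpressionHit]) -> dict[str, bool]:
    """Per-element evidence: any supporting hit."""
    out: dict[str, bool] = {}
    for h in hits:
        out[h.element_id] = out.get(h.element_id, False) or h.evidence
    return out


def expression_summary(
    expressed: dict[str, bool],
    intact: dict[str, bool],
) -> pd.DataFrame:
    """Expressed/unexpressed counts split by transposase status (Table-4B
    style); percentages recompute from the counts."""
    rows = []
    for label, want_intact in (("intact_transposase", True), ("defective_transposase", False)):
        ids = [e for e, i in intact.items() if i == want_intact]
        n_exp = sum(1 for e in ids if expressed.get(e, False))
        total = len(ids)
        rows.append(
            {
                "transposase": label,
                "with_evidence": n_exp,
                "without_evidence": total - n_exp,
                "total": total,
                "pct_with_evidence": round(100.0 * n_exp / total, 2) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)
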