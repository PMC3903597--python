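"""Insertion ages of intact LTR retroelements from LTR-pair divergence.

The two long terminal repeats of a retroelement are identical on insertion
and diverge neutrally afterwards, so the substitution distance d between
them dates the insertion: T = d / (2r) with r = 1.3e-8 substitutions per
site per year (the grass neutral rate).  The divergence model defaults to
Kimura two-parameter; p-distance and Jukes-Cantor are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .alignment import NucScoring, global_alignment_stats

SUBSTITUTION_RATE = 1.3e-8  # per site per year
MODELS = ("p_distance", "JC69", "K2P")


@dataclass(frozen=True)
class LtrAge:
    insertion_id: str
    d: float
    model: str
    age_myr: float


def ltr_divergence(ltr5: str, ltr3: str, model: str = "K2P") -> float:
    """Substitutions per site between the two LTRs of one element.

    Computed on a global alignment with gap columns excluded.  An alignment
    identity under 50% means the pair is not a genuine LTR pair and raises.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if min(len(ltr5), len(ltr3)) < 50:
        raise ValueError("LTRs shorter than 50 bp cannot be dated reliably")
    stats = global_alignment_stats(ltr5, ltr3, NucScoring())
    coverage = stats.aligned_cols / min(len(ltr5), len(ltr3))
    if stats.identity < 0.5 or coverage < 0.5:
        raise ValueError(
            f"alignment identity {stats.identity:.2f} / coverage {coverage:.2f}"
            " below 0.5: not an LTR pair"
        )
    n = stats.aligned_cols
    p = stats.mismatches / n
    if model == "p_distance":
        return p
    if model == "JC69":
        x = 1.0 - 4.0 * p / 3.0
        if x <= 0:
            raise ValueError("JC69 distance undefined for p >= 0.75")
        return -0.75 * math.log(x)
    # K2P
    P = stats.transitions / n
    Q = stats.transversions / n
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        raise ValueError("K2P distance undefined for this divergence")
    return -0.5 * math.log(a) - 0.25 * math.log(b)


def estimate_age(d: float, rate: float = SUBSTITUTION_RATE) -> float:
    """Age in Myr: T = d / (2 r), converted from years to Myr."""
    if d < 0:
        raise ValueError("divergence must be >= 0")
    return d / (2.0 * rate) / 1e6


def date_ltr_pair(
    insertion_id: str, ltr5: str, ltr3: str, model: str = "K2P"
) -> LtrAge:
    d = ltr_divergence(ltr5, ltr3, model)
    return LtrAge(insertion_id, d, model, estimate_age(d))


AGE_BINS = ((0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, math.inf))
AGE_BIN_LABELS = ("0-1", "1-2", "2-3", ">3")


def age_histogram(ages_myr: list[float]) -> dict[str, dict[str, float]]:
    """Counts and fractions per [0,1), [1,2), [2,3), [3,inf) Myr bin."""
    counts = dict.fromkeys(AGE_BIN_LABELS, 0)
    for age in ages_myr:
        for (lo, hi), label in zip(AGE_BINS, AGE_BIN_LABELS):
            if lo <= age < hi:
                counts[label] += 1
                break
    total = sum(counts.values())
    return {
        label: {
            "count": counts[label],
            "fraction": counts[label] / total if total else 0.0,
        }
        for label in AGE_BIN_LABELS
    }
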