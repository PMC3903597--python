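"""Contingency-table and two-sample tests, plus report-table assembly.

The chi-square test on 2x2 count tables is Pearson's statistic with
expected counts from the margins, df = 1, and no continuity correction
(the uncorrected statistic is what comparative TE studies print).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows = species/condition, columns = trait present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p: float


def chi2_2x2(table: ContingencyTable2x2) -> TestResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    arr = table.as_array
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    stat, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return TestResult(float(stat), int(df), float(p))


def two_sample_t(
    xs: Sequence[float], ys: Sequence[float], equal_var: bool = False
) -> TestResult:
    """Two-sample t-test; Welch by default, Student when ``equal_var``."""
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.std(xs) == 0 and np.std(ys) == 0 and np.mean(xs) == np.mean(ys):
        return TestResult(0.0, len(xs) + len(ys) - 2, 1.0)
    res = sps.ttest_ind(xs, ys, equal_var=equal_var)
    df = getattr(res, "df", len(xs) + len(ys) - 2)
    return TestResult(float(res.statistic), int(round(float(df))), float(res.pvalue))


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

def group_count_table(
    labels: dict[str, str],
    with_te: dict[str, bool],
    groups: Sequence[str],
) -> pd.DataFrame:
    """Group x {with TE, without TE, total} counts with percentages.

    ``labels`` maps element id -> group label; percentages are recomputed
    from the counts (column-wise over the respective totals).
    """
    ids = sorted(labels)
    n_with = sum(1 for e in ids if with_te.get(e, False))
    n_without = len(ids) - n_with
    rows = []
    for g in groups:
        cw = sum(1 for e in ids if labels[e] == g and with_te.get(e, False))
        cwo = sum(1 for e in ids if labels[e] == g and not with_te.get(e, False))
        rows.append(
            {
                "group": g,
                "with_te": cw,
                "with_te_pct": round(100.0 * cw / n_with, 2) if n_with else 0.0,
                "without_te": cwo,
                "without_te_pct": round(100.0 * cwo / n_without, 2) if n_without else 0.0,
                "total": cw + cwo,
                "total_pct": round(100.0 * (cw + cwo) / len(ids), 2) if ids else 0.0,
            }
        )
    return pd.DataFrame(rows)


def histogram_table(hist: dict[str, dict[str, float]]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"bin": k, "count": v["count"], "fraction": v["fraction"]} for k, v in hist.items()]
    )


def build_reports(
    out_dir: str | Path,
    *,
    size_profile: dict | None = None,
    nested_summary: pd.DataFrame | None = None,
    insertion_preference: pd.DataFrame | None = None,
    group_counts_redundant: pd.DataFrame | None = None,
    group_counts_non_redundant: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    indel_bins: pd.DataFrame | None = None,
    age_bins: dict | None = None,
) -> dict[str, str]:
    """Write the TSV report bundle; absent stages are noted in a manifest.

    Returns the manifest (table name -> file or "missing").
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame | None) -> None:
        if df is None:
            manifest[name] = "missing"
            return
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        manifest[name] = path.name

    emit("size_profile", histogram_table(size_profile) if size_profile else None)
    emit("nested_summary", nested_summary)
    emit("insertion_preference", insertion_preference)
    emit("group_counts_redundant", group_counts_redundant)
    emit("group_counts_non_redundant", group_counts_non_redundant)
    emit("expression", expression)
    emit("indel_bins", indel_bins)
    emit("age_bins", histogram_table(age_bins) if age_bins else None)
    pd.Series(manifest).to_csv(out_dir / "manifest.tsv", sep="\t", header=False)
    return manifest
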