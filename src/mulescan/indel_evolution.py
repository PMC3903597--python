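"""Indel accumulation between homologous element pairs.

Each element is paired with the relative giving the longest alignment; the
pair's indels are counted on an affine-gap global alignment (one maximal gap
run = one indel, terminal runs excluded) and normalised by the summed length
of the two elements: NIK = indels per kb, LIK = indel bp per kb.  Pairs are
grouped either by nucleotide identity or by synonymous substitution rate
(Ks, Nei-Gojobori 1986 with Jukes-Cantor correction), and group means are
compared between element sets with Welch's t-test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import stats as sps

from .alignment import (
    CODON_TABLE,
    GlobalAlignmentStats,
    NucScoring,
    global_alignment_stats,
    make_protein_aligner,
    translate,
)


@dataclass
class IndelPairStat:
    id_a: str
    id_b: str
    len_a: int
    len_b: int
    aligned_cols: int
    identity: float
    n_indels: int
    indel_len_total: int
    ks: float | None = None

    @property
    def total_len(self) -> int:
        return self.len_a + self.len_b

    @property
    def nik(self) -> float:
        return self.n_indels * 1000.0 / self.total_len

    @property
    def lik(self) -> float:
        return self.indel_len_total * 1000.0 / self.total_len


def align_count_indels(
    seq_a: str, seq_b: str, scoring: NucScoring = NucScoring()
) -> GlobalAlignmentStats:
    """Indel and identity statistics from a global affine-gap alignment.

    The pair is aligned in a canonical order (lexicographically smaller
    sequence first) so the statistics are exactly symmetric in the
    arguments.
    """
    if min(len(seq_a), len(seq_b)) < 200:
        raise ValueError("sequences under 200 bp are too short for indel stats")
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    return global_alignment_stats(seq_a, seq_b, scoring)


def compute_nik_lik(stat: IndelPairStat) -> tuple[float, float]:
    if stat.total_len <= 0:
        raise ValueError("zero total length")
    return stat.nik, stat.lik


# ---------------------------------------------------------------------------
# Homolog pairing
# ---------------------------------------------------------------------------

def _edlib_alignment_len(a: str, b: str) -> tuple[int, float]:
    """(matched columns, crude identity) from a unit-cost global alignment.

    Matched columns (alignment length minus edits) proxy the length of the
    significant alignment: homologs share most of their length, unrelated
    sequences only scattered coincidental matches.
    """
    res = edlib.align(a, b, mode="NW", task="path")
    cols = 0
    for num, _op in _parse_cigar(res["cigar"]):
        cols += num
    matches = cols - res["editDistance"]
    identity = matches / cols if cols else 0.0
    return matches, identity


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def best_homolog_pairs(
    elements: dict[str, str],
    *,
    min_identity: float = 0.95,
    compute_ks_values: bool = False,
) -> list[IndelPairStat]:
    """Pair each element with its closest homolog and collect indel stats.

    Inputs are stripped sequences (nested TEs and one TSD copy removed).
    The partner maximises alignment length (ties: higher identity, then
    smaller id); unordered pairs are reported once.  Only pairs above
    ``min_identity`` (on non-gap aligned columns of the affine alignment)
    enter the statistics; singletons are skipped.
    """
    ids = sorted(elements)
    if len(ids) < 2:
        return []
    # partner selection on fast unit-cost alignments
    screen: dict[tuple[str, str], tuple[int, float]] = {}
    for a, b in itertools.combinations(ids, 2):
        screen[(a, b)] = _edlib_alignment_len(elements[a], elements[b])
    chosen: set[frozenset[str]] = set()
    for a in ids:
        best_key = None
        best_partner = None
        for b in ids:
            if b == a:
                continue
            cols, ident = screen[(a, b) if a < b else (b, a)]
            key = (cols, ident, tuple(sorted((a, b))))
            if best_key is None or key > best_key:
                best_key = key
                best_partner = b
        if best_partner is not None:
            chosen.add(frozenset((a, best_partner)))
    out: list[IndelPairStat] = []
    for pair in sorted(chosen, key=sorted):
        a, b = sorted(pair)
        st = align_count_indels(elements[a], elements[b])
        if st.identity <= min_identity:
            continue
        # genuine homolog pairs align over most of their length; a short
        # high-identity core between unrelated sequences does not qualify
        if st.aligned_cols < 0.5 * min(len(elements[a]), len(elements[b])):
            continue
        ks = compute_ks(elements[a], elements[b]) if compute_ks_values else None
        out.append(
            IndelPairStat(
                id_a=a,
                id_b=b,
                len_a=len(elements[a]),
                len_b=len(elements[b]),
                aligned_cols=st.aligned_cols,
                identity=st.identity,
                n_indels=st.n_indels,
                indel_len_total=st.indel_len_total,
                ks=ks,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Ks (NG86)
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _codon_syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (changes to stops count as
    nonsynonymous)."""
    aa = CODON_TABLE.get(codon)
    if aa is None or aa == "*":
        return 0.0
    s = 0.0
    for i in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[i]:
                continue
            alt = codon[:i] + base + codon[i + 1 :]
            if CODON_TABLE.get(alt) == aa:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences, averaged over all mutational
    pathways between two codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if CODON_TABLE.get(cur) == CODON_TABLE.get(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        sd_total += sd
        nd_total += nd
        n_paths += 1
    return sd_total / n_paths, nd_total / n_paths


def codon_align(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Codon-aware alignment: align the translations, thread the nt back."""
    prot_a, prot_b = translate(cds_a), translate(cds_b)
    aligner = make_protein_aligner()
    aligner.mode = "global"
    aligner.end_gap_score = 0.0
    aln = aligner.align(prot_a.replace("*", "X"), prot_b.replace("*", "X"))[0]
    blocks_a, blocks_b = aln.aligned
    out_a: list[str] = []
    out_b: list[str] = []
    prev_a = prev_b = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        if sb > prev_b:
            out_a.append("-" * 3 * (sb - prev_b))
            out_b.append(cds_b[3 * prev_b : 3 * sb])
        if sa > prev_a:
            out_a.append(cds_a[3 * prev_a : 3 * sa])
            out_b.append("-" * 3 * (sa - prev_a))
        out_a.append(cds_a[3 * sa : 3 * ea])
        out_b.append(cds_b[3 * sb : 3 * eb])
        prev_a, prev_b = ea, eb
    return "".join(out_a), "".join(out_b)


def compute_ks(cds_a: str, cds_b: str, min_codons: int = 30) -> float | None:
    """Synonymous substitutions per synonymous site (NG86, JC-corrected).

    Inputs may be pre-aligned (equal length, '-' gaps) or raw coding
    sequences, which are then codon-aligned via their translations.  Codons
    containing gaps, N, or stops in either sequence are dropped; fewer than
    ``min_codons`` comparable codons gives None.
    """
    if len(cds_a) != len(cds_b):
        cds_a, cds_b = codon_align(cds_a, cds_b)
    if len(cds_a) % 3 or len(cds_b) % 3:
        raise ValueError("aligned coding sequences must be codon-length")
    S = 0.0
    sd = 0.0
    nd = 0.0
    n_codons = 0
    for i in range(0, len(cds_a), 3):
        c1, c2 = cds_a[i : i + 3], cds_b[i : i + 3]
        if "-" in c1 + c2 or "N" in c1 + c2:
            continue
        if CODON_TABLE.get(c1, "*") == "*" or CODON_TABLE.get(c2, "*") == "*":
            continue
        n_codons += 1
        S += (_codon_syn_sites(c1) + _codon_syn_sites(c2)) / 2.0
        s_i, _n_i = _pathway_counts(c1, c2)
        sd += s_i
    if n_codons < min_codons or S <= 0:
        return None
    ps = sd / S
    x = 1.0 - 4.0 * ps / 3.0
    if x <= 0:
        return None
    return -0.75 * math.log(x)


# ---------------------------------------------------------------------------
# Binning and group comparison
# ---------------------------------------------------------------------------

IDENTITY_BINS = ((0.95, 0.96), (0.96, 0.97), (0.97, 0.98), (0.98, 0.99), (0.99, 1.0))
IDENTITY_BIN_LABELS = ("95-96", "96-97", "97-98", "98-99", "99-100")
DEFAULT_KS_BINS = ((0.0, 0.01), (0.01, 0.02), (0.02, 0.03), (0.03, 0.05), (0.05, math.inf))


def _identity_bin(identity: float) -> str | None:
    for (lo, hi), label in zip(IDENTITY_BINS, IDENTITY_BIN_LABELS):
        if lo < identity <= hi:
            return label
    return None


def bin_pairs(
    pair_stats: list[IndelPairStat],
    mode: str = "identity",
    ks_bins=DEFAULT_KS_BINS,
) -> pd.DataFrame:
    """Per-bin mean and SD of NIK and LIK.

    ``mode`` is "identity" (bins (95,96] ... (99,100] percent) or "ks"
    (configurable bins on Ks).  Empty bins report NaN.
    """
    if mode not in ("identity", "ks"):
        raise ValueError("mode must be 'identity' or 'ks'")
    rows = []
    if mode == "identity":
        bins = list(zip(IDENTITY_BINS, IDENTITY_BIN_LABELS))
        get = lambda st: st.identity  # noqa: E731
    else:
        bins = [((lo, hi), f"{lo:g}-{hi:g}") for lo, hi in ks_bins]
        get = lambda st: st.ks  # noqa: E731
    for (lo, hi), label in bins:
        vals = [st for st in pair_stats if get(st) is not None and lo < get(st) <= hi]
        niks = np.array([v.nik for v in vals])
        liks = np.array([v.lik for v in vals])
        rows.append(
            {
                "bin": label,
                "n_pairs": len(vals),
                "mean_nik": niks.mean() if len(vals) else np.nan,
                "sd_nik": niks.std(ddof=1) if len(vals) > 1 else np.nan,
                "mean_lik": liks.mean() if len(vals) else np.nan,
                "sd_lik": liks.std(ddof=1) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def compare_pair_sets(
    stats_a: list[IndelPairStat],
    stats_b: list[IndelPairStat],
    mode: str = "identity",
    value: str = "nik",
) -> pd.DataFrame:
    """Per-bin Welch t-test of NIK (or LIK) between two element sets."""
    df_a = bin_pairs(stats_a, mode)
    df_b = bin_pairs(stats_b, mode)
    rows = []
    for label in df_a["bin"]:
        va = [
            getattr(st, value)
            for st in stats_a
            if mode == "identity" and _identity_bin(st.identity) == label
        ]
        vb = [
            getattr(st, value)
            for st in stats_b
            if mode == "identity" and _identity_bin(st.identity) == label
        ]
        if len(va) >= 2 and len(vb) >= 2:
            t, p = sps.ttest_ind(va, vb, equal_var=False)
        else:
            t = p = np.nan
        rows.append(
            {
                "bin": label,
                f"mean_{value}_a": np.mean(va) if va else np.nan,
                f"mean_{value}_b": np.mean(vb) if vb else np.nan,
                "n_a": len(va),
                "n_b": len(vb),
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
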