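"""Synthetic genomes with planted MULEs and machine-readable ground truth.

The generator emulates the structural anatomy the downstream callers assume:
elements bounded by long terminal inverted repeats (TIRs, 100-500 bp at a
configurable pairwise identity), flanked by an 8-11 bp target site
duplication (TSD), with an internal transposase coding sequence into which
defined coding defects (catalytic-residue or start-codon mutation,
frameshift, premature stop, large deletion) are planted at recorded
positions.  Nested insertions (LTR retroelements with age-controlled LTR
divergence, MITEs, generic DNA transposons) create their own TSDs so that
excision restores the pre-insertion sequence exactly.

Background sequence is i.i.d. at a given GC content; all randomness flows
from one :class:`numpy.random.Generator`, so a fixed seed gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .alignment import revcomp
from .io_formats import GenomeRecord, TeAnnotation

DEFECT_KINDS = ("dde_mut", "start_mut", "frameshift", "premature_stop", "deletion")

from .alignment import CODON_TABLE as _CT

# codons per amino acid (standard table), for back-translation
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _CT.items():
    if _aa != "*":
        _CODONS.setdefault(_aa, []).append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated genome.

    Defaults describe the standard test condition: 50 structurally valid
    elements with 100-500 bp TIRs at 85% identity, 8-11 bp TSDs, element
    spans of roughly 2.5-9.5 kb, on a 600 kb background at 44% GC.
    """

    seed: int = 7
    genome_len: int = 600_000
    gc: float = 0.44
    n_elements: int = 50
    tir_len_range: tuple[int, int] = (100, 500)
    tir_identity: float = 0.85
    tsd_len_range: tuple[int, int] = (8, 11)
    element_len_range: tuple[int, int] = (2500, 9500)
    defect_spectrum: dict[str, float] = field(
        default_factory=lambda: {"intact": 1.0}
    )
    nested_rate: float = 0.0  # insertions per element (Poisson mean)
    nested_class_mix: float = 0.6  # fraction of nested TEs that are RNA (LTR)
    ltr_age_range: tuple[float, float] = (0.1, 3.0)  # Myr
    homolog_sub_rate: float = 0.02  # substitutions per site
    homolog_indel_rate: float = 2.0  # indel events per kb
    indel_len_geom_p: float = 0.3
    n_host_tes: int = 0  # standalone background TEs
    n_mules_in_te: int = 0  # elements embedded inside a background LTR retro
    min_gap: int = 2000  # background between planted features

    def __post_init__(self) -> None:
        total = sum(self.defect_spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"defect_spectrum probabilities sum to {total}, not 1")
        for key in self.defect_spectrum:
            if key != "intact" and key not in DEFECT_KINDS:
                raise ValueError(f"unknown defect kind {key!r}")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be a fraction")
        if self.tir_identity <= 0.75:
            raise ValueError("tir_identity must exceed 0.75")


LTR_SUB_RATE = 1.3e-8  # substitutions per site per year (grass neutral rate)


@dataclass(frozen=True)
class ReferenceTransposase:
    """A synthetic MURA-like transposase used as the homology reference.

    The sequence is generated, not a real protein; only its architecture
    matters: an N-terminal helix-turn-helix (HTH) segment and a C-terminal
    DDE catalytic triad whose first-D-to-E span exceeds 100 aa.
    """

    id: str
    protein: str
    hth_span: tuple[int, int]  # aa interval, 0-based half-open
    dde_positions: tuple[int, int, int]  # aa indices of D, D, E

    @property
    def catalytic_region(self) -> tuple[int, int]:
        d1, _, e = self.dde_positions
        return (max(0, d1 - 30), min(len(self.protein), e + 30))


def make_reference_transposase(seed: int, length: int = 800) -> ReferenceTransposase:
    """Generate the reference transposase deterministically from ``seed``."""
    rng = np.random.default_rng(seed)
    aas = list(rng.choice(list(_AA20), size=length))
    aas[0] = "M"
    # keep the start-codon scan unambiguous: no internal Met near the start
    for i in range(1, 32):
        if aas[i] == "M":
            aas[i] = "L"
    hth = (25, 65)
    d1, d2, e = 430, 470, 545
    aas[d1], aas[d2], aas[e] = "D", "D", "E"
    return ReferenceTransposase("TPASE_REF", "".join(aas), hth, (d1, d2, e))


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """DNA coding sequence for ``protein`` with random synonymous codons."""
    codons = [
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
    ]
    return "".join(codons)


def random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------

@dataclass
class NestedTruth:
    family: str
    te_kind: str  # LTR_retro | MITE | DNA_TE
    te_class: str  # RNA | DNA
    interval: tuple[int, int]  # element coordinates, TE proper (no TSD copy)
    length: int
    tsd_len: int  # duplicated target-site copy immediately 3' of interval
    in_coding: bool
    ltr_age_myr: float | None = None
    ltr_spans: tuple[tuple[int, int], tuple[int, int]] | None = None


@dataclass
class PlantedElement:
    """One planted MULE and everything the callers should recover."""

    element_id: str
    seq: str  # TIR ... TIR, no flanking TSD copies
    tsd: str
    tir_len: int
    tir_identity: float
    tir_spans: tuple[tuple[int, int], tuple[int, int]]
    cds_span: tuple[int, int]  # element coordinates of the transposase CDS
    defects: dict[str, object]  # defect kind -> planted detail
    hth_nt_span: tuple[int, int]
    dde_nt_positions: tuple[int, int, int]
    nested: list[NestedTruth] = field(default_factory=list)
    genome_span: tuple[int, int] | None = None  # set on placement
    homolog_partner: str | None = None

    @property
    def defect_labels(self) -> frozenset[str]:
        return frozenset(self.defects)


@dataclass
class SimTruth:
    elements: dict[str, PlantedElement]
    est_sources: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Element construction
# ---------------------------------------------------------------------------

def _make_tir_pair(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[str, str, int, float]:
    """Left TIR and the right-end sequence (revcomp of a mutated copy)."""
    tir_len = int(rng.integers(cfg.tir_len_range[0], cfg.tir_len_range[1] + 1))
    left = random_dna(tir_len, cfg.gc, rng)
    n_mut = int(round((1.0 - cfg.tir_identity) * tir_len))
    pos = rng.choice(tir_len, size=n_mut, replace=False)
    right_src = list(left)
    for p in pos:
        alt = [c for c in "ACGT" if c != right_src[p]]
        right_src[p] = alt[rng.integers(3)]
    identity = (tir_len - n_mut) / tir_len
    return left, revcomp("".join(right_src)), tir_len, identity


def plant_mule(
    cfg: SimConfig,
    defect_labels: Iterable[str],
    rng: np.random.Generator,
    *,
    element_id: str = "mule",
    reference: ReferenceTransposase | None = None,
) -> PlantedElement:
    """Build one element: TIR + filler + transposase CDS + filler + TIR'.

    ``defect_labels`` are planted into the CDS at recorded positions.  The
    flanking TSD string is returned in the truth record but not included in
    ``seq``; :func:`simulate_genome` writes the two copies into the genome.
    """
    labels = set(defect_labels)
    unknown = labels - set(DEFECT_KINDS)
    if unknown:
        raise ValueError(f"unknown defect labels {sorted(unknown)}")
    if reference is None:
        reference = make_reference_transposase(cfg.seed)

    tsd_len = int(rng.integers(cfg.tsd_len_range[0], cfg.tsd_len_range[1] + 1))
    tsd = random_dna(tsd_len, cfg.gc, rng)
    left_tir, right_tir, tir_len, tir_ident = _make_tir_pair(cfg, rng)

    cds = back_translate(reference.protein, rng) + "TGA"
    n_codons = len(reference.protein)
    defects: dict[str, object] = {}

    # positions in codon units on the intact CDS
    del_span_codons: tuple[int, int] | None = None
    if "deletion" in labels:
        d1 = reference.dde_positions[0]
        max_len = min(150, n_codons - 60)
        if max_len < 40:
            raise ValueError("CDS too short to plant a deletion")
        del_len = int(rng.integers(40, max_len + 1))
        # keep the start-codon scan region intact
        lo, hi = 40, n_codons - del_len - 10
        if hi <= lo:
            raise ValueError("deletion does not fit in the CDS")
        forbidden = set(reference.dde_positions) if "dde_mut" in labels else set()
        for _ in range(100):
            start = int(rng.integers(lo, hi))
            if not any(start <= p < start + del_len for p in forbidden):
                break
        else:
            raise ValueError("could not place deletion away from DDE residues")
        del_span_codons = (start, start + del_len)
        defects["deletion"] = {"codon_span": del_span_codons, "aa_len": del_len}

    def _free_codon(lo_frac: float, hi_frac: float) -> int:
        for _ in range(200):
            c = int(rng.integers(int(lo_frac * n_codons), int(hi_frac * n_codons)))
            if del_span_codons and del_span_codons[0] <= c < del_span_codons[1]:
                continue
            if c in reference.dde_positions:
                continue
            return c
        raise ValueError("no free codon for defect placement")

    edits: list[tuple[int, str]] = []  # (codon index, replacement codon)
    if "premature_stop" in labels:
        c = _free_codon(0.2, 0.8)
        edits.append((c, "TAA"))
        defects["premature_stop"] = {"codon": c}
    if "dde_mut" in labels:
        c = reference.dde_positions[0]
        edits.append((c, "AAC"))  # D -> N
        defects["dde_mut"] = {"codon": c}
    if "start_mut" in labels:
        edits.append((0, "ACG"))  # ATG -> ACG
        defects["start_mut"] = {"codon": 0}
    for c, codon in edits:
        cds = cds[: 3 * c] + codon + cds[3 * c + 3 :]

    if del_span_codons is not None:
        a, b = del_span_codons
        cds = cds[: 3 * a] + cds[3 * b :]

    if "frameshift" in labels:
        usable = len(cds) - 3  # keep away from the terminal stop
        p = int(rng.integers(int(0.2 * usable), int(0.8 * usable)))
        cds = cds[:p] + cds[p + 1 :]
        defects["frameshift"] = {"nt_pos": p}

    # size the fillers so the TIR-to-TIR span lands in element_len_range
    span_target = int(rng.integers(cfg.element_len_range[0], cfg.element_len_range[1] + 1))
    internal_len = span_target - 2 * tir_len
    min_internal = len(cds) + 200
    if internal_len < min_internal:
        internal_len = min_internal
    filler_total = internal_len - len(cds)
    left_fill = int(rng.integers(100, max(101, filler_total - 100)))
    right_fill = filler_total - left_fill
    left_filler = random_dna(left_fill, cfg.gc, rng)
    right_filler = random_dna(right_fill, cfg.gc, rng)

    seq = left_tir + left_filler + cds + right_filler + right_tir
    span_len = len(seq)
    if not (2000 <= span_len <= 30000):
        raise ValueError(f"element span {span_len} outside 2-30 kb")

    cds_start = tir_len + left_fill
    cds_span = (cds_start, cds_start + len(cds))
    hth_nt = (
        cds_start + 3 * reference.hth_span[0],
        cds_start + 3 * reference.hth_span[1],
    )
    dde_nt = tuple(cds_start + 3 * p for p in reference.dde_positions)
    return PlantedElement(
        element_id=element_id,
        seq=seq,
        tsd=tsd,
        tir_len=tir_len,
        tir_identity=tir_ident,
        tir_spans=((0, tir_len), (span_len - tir_len, span_len)),
        cds_span=cds_span,
        defects=defects,
        hth_nt_span=hth_nt,
        dde_nt_positions=dde_nt,  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# Nested insertions
# ---------------------------------------------------------------------------

_TE_TSD_LEN = {"LTR_retro": 5, "MITE": 3, "DNA_TE": 9}
_TE_CLASS = {"LTR_retro": "RNA", "MITE": "DNA", "DNA_TE": "DNA"}


def _mutate_sites(seq: str, n: int, rng: np.random.Generator) -> str:
    if n <= 0:
        return seq
    out = list(seq)
    pos = rng.choice(len(seq), size=min(n, len(seq)), replace=False)
    for p in pos:
        alt = [c for c in "ACGT" if c != out[p]]
        out[p] = alt[rng.integers(3)]
    return "".join(out)


def make_nested_te(
    te_kind: str,
    rng: np.random.Generator,
    *,
    target_age_myr: float = 0.0,
    gc: float = 0.44,
    family: str | None = None,
    mite_len: int = 274,
) -> tuple[str, dict[str, object]]:
    """Build the inserted TE sequence and its descriptive metadata."""
    if te_kind == "LTR_retro":
        ltr_len = int(rng.integers(200, 501))
        internal = random_dna(int(rng.integers(1000, 3001)), gc, rng)
        ltr = random_dna(ltr_len, gc, rng)
        # each LTR accumulates r*T expected substitutions/site independently,
        # so the pair diverges at 2*r*T
        mu = LTR_SUB_RATE * target_age_myr * 1e6
        n5 = int(rng.binomial(ltr_len, min(1.0, mu)))
        n3 = int(rng.binomial(ltr_len, min(1.0, mu)))
        ltr5 = _mutate_sites(ltr, n5, rng)
        ltr3 = _mutate_sites(ltr, n3, rng)
        te = ltr5 + internal + ltr3
        meta = {
            "ltr_age_myr": target_age_myr,
            "ltr_spans": ((0, ltr_len), (len(te) - ltr_len, len(te))),
        }
    elif te_kind == "MITE":
        te = random_dna(mite_len, gc, rng)
        meta = {}
    elif te_kind == "DNA_TE":
        te = random_dna(int(rng.integers(400, 1501)), gc, rng)
        meta = {}
    else:
        raise ValueError(f"unknown te_kind {te_kind!r}")
    meta["family"] = family or f"{te_kind}_fam"
    return te, meta


def insert_nested_te(
    element: PlantedElement,
    te_kind: str,
    rng: np.random.Generator,
    *,
    target_age_myr: float = 0.0,
    gc: float = 0.44,
    family: str | None = None,
) -> PlantedElement:
    """Insert one TE at a uniform internal position, with its own TSD.

    The inserted block is TE + duplicated target site, so excising the
    recorded interval (TE plus its TSD copy) restores the host exactly.
    Insertions that would push the element past 30 kb are rejected.
    """
    te, meta = make_nested_te(
        te_kind, rng, target_age_myr=target_age_myr, gc=gc, family=family
    )
    tsd_len = _TE_TSD_LEN[te_kind]
    if len(element.seq) + len(te) + tsd_len > 30000:
        raise ValueError("nested insertion would exceed the 30 kb element limit")
    lo = element.tir_spans[0][1] + tsd_len
    hi = element.tir_spans[1][0] - tsd_len
    p = int(rng.integers(lo, hi))
    dup = element.seq[p - tsd_len : p]
    new_seq = element.seq[:p] + te + dup + element.seq[p:]
    shift = len(te) + tsd_len

    def mv(x: int) -> int:
        return x + shift if x >= p else x

    def mv_span(sp: tuple[int, int]) -> tuple[int, int]:
        return (mv(sp[0]), mv(sp[1]))

    cds = element.cds_span
    in_coding = cds[0] < p < cds[1]
    nested = [
        replace(
            n,
            interval=mv_span(n.interval),
            ltr_spans=None
            if n.ltr_spans is None
            else (mv_span(n.ltr_spans[0]), mv_span(n.ltr_spans[1])),
        )
        for n in element.nested
    ]
    ltr_spans = meta.get("ltr_spans")
    nested.append(
        NestedTruth(
            family=str(meta["family"]),
            te_kind=te_kind,
            te_class=_TE_CLASS[te_kind],
            interval=(p, p + len(te)),
            length=len(te),
            tsd_len=tsd_len,
            in_coding=in_coding,
            ltr_age_myr=meta.get("ltr_age_myr"),  # type: ignore[arg-type]
            ltr_spans=None
            if ltr_spans is None
            else ((p + ltr_spans[0][0], p + ltr_spans[0][1]),
                  (p + ltr_spans[1][0], p + ltr_spans[1][1])),
        )
    )
    return replace(
        element,
        seq=new_seq,
        tir_spans=(element.tir_spans[0], mv_span(element.tir_spans[1])),
        cds_span=mv_span(cds),
        hth_nt_span=mv_span(element.hth_nt_span),
        dde_nt_positions=tuple(mv(x) for x in element.dde_nt_positions),  # type: ignore[arg-type]
        nested=nested,
    )


# ---------------------------------------------------------------------------
# Whole-genome simulation
# ---------------------------------------------------------------------------

def _sample_defect_labels(cfg: SimConfig, rng: np.random.Generator) -> set[str]:
    kinds = sorted(cfg.defect_spectrum)
    probs = np.array([cfg.defect_spectrum[k] for k in kinds])
    pick = str(rng.choice(kinds, p=probs))
    return set() if pick == "intact" else {pick}


def simulate_genome(
    cfg: SimConfig,
    *,
    seq_id: str = "synth1",
) -> tuple[GenomeRecord, list[TeAnnotation], SimTruth]:
    """Simulate one genome with planted elements and full annotations.

    The annotation table contains the planted MULEs, their nested TEs (in
    genome coordinates), and any standalone background TEs, so discovery and
    nesting can be exercised independently.
    """
    rng = np.random.default_rng(cfg.seed)
    reference = make_reference_transposase(cfg.seed)

    elements: list[PlantedElement] = []
    for i in range(cfg.n_elements):
        labels = _sample_defect_labels(cfg, rng)
        el = plant_mule(
            cfg, labels, rng, element_id=f"CM{i:03d}", reference=reference
        )
        n_nested = int(rng.poisson(cfg.nested_rate))
        for _ in range(n_nested):
            if rng.random() < cfg.nested_class_mix:
                kind = "LTR_retro"
                age = float(rng.uniform(*cfg.ltr_age_range))
            else:
                kind = "MITE" if rng.random() < 0.5 else "DNA_TE"
                age = 0.0
            try:
                el = insert_nested_te(
                    el, kind, rng, target_age_myr=age, gc=cfg.gc,
                    family=f"{kind}_{i:03d}_{len(el.nested)}",
                )
            except ValueError:
                continue  # would exceed 30 kb; skip this insertion
        elements.append(el)

    host_tes: list[tuple[str, str]] = []  # (family, seq) standalone background TEs
    for j in range(cfg.n_host_tes):
        te, meta = make_nested_te("LTR_retro", rng, target_age_myr=1.0, gc=cfg.gc,
                                  family=f"hostLTR_{j}")
        host_tes.append((str(meta["family"]), te))

    # layout: random gaps >= min_gap between consecutive features
    blocks: list[tuple[str, object]] = [("mule", el) for el in elements]
    blocks += [("host_te", ht) for ht in host_tes]
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]
    n_embed = min(cfg.n_mules_in_te, sum(1 for k, _ in blocks if k == "mule"))

    total_feat = sum(
        len(b.seq) + 2 * len(b.tsd) if kind == "mule" else len(b[1])
        for kind, b in blocks
    )
    n_gaps = len(blocks) + 1
    spare = cfg.genome_len - total_feat - n_gaps * cfg.min_gap
    if spare < 0:
        raise ValueError(
            f"genome_len {cfg.genome_len} too small for requested features"
        )
    cuts = np.sort(rng.integers(0, spare + 1, size=n_gaps - 1))
    gap_extra = np.diff(np.concatenate([[0], cuts, [spare]]))
    gaps = [cfg.min_gap + int(g) for g in gap_extra]

    parts: list[str] = []
    annos: list[TeAnnotation] = []
    truth = SimTruth(elements={})
    pos = 0
    embedded = 0
    for (kind, blk), gap in zip(blocks, gaps[:-1]):
        parts.append(random_dna(gap, cfg.gc, rng))
        pos += gap
        if kind == "mule":
            el: PlantedElement = blk  # type: ignore[assignment]
            if embedded < n_embed:
                # plant this element inside a host LTR retroelement
                host_te, hmeta = make_nested_te(
                    "LTR_retro", rng, target_age_myr=1.0, gc=cfg.gc,
                    family=f"hostLTR_embed_{embedded}",
                )
                cut = len(host_te) // 2
                block_seq = (
                    host_te[:cut]
                    + el.tsd + el.seq + el.tsd
                    + host_te[cut:]
                )
                el_start = pos + cut + len(el.tsd)
                annos.append(TeAnnotation(
                    seq_id, pos, pos + len(block_seq),
                    str(hmeta["family"]), "RNA", "+",
                ))
                embedded += 1
            else:
                block_seq = el.tsd + el.seq + el.tsd
                el_start = pos + len(el.tsd)
            el = replace(el, genome_span=(el_start, el_start + len(el.seq)))
            truth.elements[el.element_id] = el
            annos.append(TeAnnotation(
                seq_id, el_start, el_start + len(el.seq),
                f"MULE_{el.element_id}", "DNA", "+",
            ))
            for nt in el.nested:
                annos.append(TeAnnotation(
                    seq_id,
                    el_start + nt.interval[0],
                    el_start + nt.interval[1],
                    nt.family, nt.te_class, "+",
                ))
            parts.append(block_seq)
            pos += len(block_seq)
        else:
            fam, te_seq = blk  # type: ignore[misc]
            annos.append(TeAnnotation(seq_id, pos, pos + len(te_seq), fam, "RNA", "+"))
            parts.append(te_seq)
            pos += len(te_seq)
    parts.append(random_dna(gaps[-1], cfg.gc, rng))
    pos += gaps[-1]
    if pos < cfg.genome_len:
        parts.append(random_dna(cfg.genome_len - pos, cfg.gc, rng))
    genome = GenomeRecord(seq_id, "".join(parts))
    annos.sort(key=lambda a: a.start)
    return genome, annos, truth


# ---------------------------------------------------------------------------
# Homolog divergence and ESTs
# ---------------------------------------------------------------------------

@dataclass
class HomologTruth:
    n_substitutions: int
    n_indels: int
    indel_len_total: int


def mutate_homolog(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    indel_len_geom_p: float,
    rng: np.random.Generator,
) -> tuple[str, HomologTruth]:
    """Diverge a copy of ``seq``: Binomial substitutions, Poisson indels.

    ``indel_rate`` is events per kb; indel lengths are Geometric(p) >= 1.
    Realized counts are returned as truth.
    """
    if sub_rate < 0 or indel_rate < 0:
        raise ValueError("rates must be >= 0")
    L = len(seq)
    n_sub = int(rng.binomial(L, min(1.0, sub_rate))) if sub_rate > 0 else 0
    out = _mutate_sites(seq, n_sub, rng)
    n_indel = int(rng.poisson(L / 1000.0 * indel_rate)) if indel_rate > 0 else 0
    total_len = 0
    # apply right-to-left so earlier positions stay valid
    positions = sorted(
        (int(p) for p in rng.integers(50, max(51, len(out) - 50), size=n_indel)),
        reverse=True,
    )
    for p in positions:
        ln = int(rng.geometric(indel_len_geom_p))
        total_len += ln
        if rng.random() < 0.5:
            out = out[:p] + out[p + ln :]  # deletion
        else:
            ins = random_dna(ln, 0.5, rng)
            out = out[:p] + ins + out[p:]  # insertion
    return out, HomologTruth(n_sub, n_indel, total_len)


def simulate_est_records(
    elements: Sequence[tuple[str, str]],
    n: int,
    rng: np.random.Generator,
    *,
    mut_rate: float = 0.0,
    len_range: tuple[int, int] = (300, 1500),
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Draw ESTs as (near-)exact substrings of elements.

    Returns (est records, est_id -> source element id).  ``mut_rate`` is the
    per-site substitution probability applied to each EST (<= 0.005 for
    records meant to pass the expression filter).
    """
    ests: list[tuple[str, str]] = []
    sources: dict[str, str] = {}
    for i in range(n):
        el_id, el_seq = elements[int(rng.integers(len(elements)))]
        max_len = min(len_range[1], len(el_seq))
        ln = int(rng.integers(len_range[0], max_len + 1))
        start = int(rng.integers(0, len(el_seq) - ln + 1))
        sub = el_seq[start : start + ln]
        if mut_rate > 0:
            n_mut = int(rng.binomial(ln, mut_rate))
            sub = _mutate_sites(sub, n_mut, rng)
        est_id = f"EST{i:04d}"
        ests.append((est_id, sub))
        sources[est_id] = el_id
    return ests, sources
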