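"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere.  The two file dialects
that use 1-based inclusive coordinates (GFF3 and the RepeatMasker-style
interval table) are converted at the parsing/writing boundary and nowhere
else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_NUCLEOTIDES = set("ACGTN")


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GenomeRecord id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"GenomeRecord {self.id!r}: empty sequence")
        bad = set(self.seq) - _NUCLEOTIDES
        if bad:
            raise ValueError(
                f"GenomeRecord {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TeAnnotation:
    """A transposable-element interval on a genome sequence.

    ``start``/``end`` are 0-based half-open; ``te_class`` is "RNA" (class I,
    retrotransposons) or "DNA" (class II).
    """

    seq_id: str
    start: int
    end: int
    family: str
    te_class: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"TeAnnotation {self.family} on {self.seq_id}: "
                f"bad interval [{self.start}, {self.end})"
            )
        if self.te_class not in ("RNA", "DNA"):
            raise ValueError(f"te_class must be RNA or DNA, got {self.te_class!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize_sequence(raw: str) -> str:
    """Uppercase, U->T, and collapse anything outside {A,C,G,T,N} to N."""
    seq = raw.upper().replace("U", "T")
    n_bad = sum(1 for c in seq if c not in _NUCLEOTIDES)
    if n_bad:
        logger.info("replaced %d non-ACGTN characters with N", n_bad)
        seq = "".join(c if c in _NUCLEOTIDES else "N" for c in seq)
    return seq


def parse_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a nucleotide FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased, RNA is converted to DNA, and other characters
    become N.  Empty files and duplicate ids are hard errors.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeRecord(rec.id, normalize_sequence(str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def parse_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an id -> uppercase sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# TE annotation tables
# ---------------------------------------------------------------------------

def parse_te_annotations(
    path: str | Path,
    class_table: Mapping[str, str],
    *,
    default_class: str | None = None,
) -> list[TeAnnotation]:
    """Parse a TE interval table into annotations.

    Two dialects are accepted and auto-detected per line:

    * a 6-column TSV: seq_id, start, end, family, strand, te_class
      (te_class may be empty, then ``class_table`` is consulted);
    * a RepeatMasker ``.out``-style whitespace table (score, div, del, ins,
      query, begin, end, left, strand, family, class/family, ...).

    File coordinates are 1-based inclusive and converted to 0-based
    half-open.  Families absent from ``class_table`` raise unless
    ``default_class`` is given, in which case they are assigned to it with a
    warning.
    """
    annos: list[TeAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fields[0].lower() in ("score", "sw", "seq_id"):  # headers
                continue
            try:
                anno = _parse_annotation_fields(fields, class_table, default_class)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            annos.append(anno)
    return annos


def _parse_annotation_fields(
    fields: Sequence[str],
    class_table: Mapping[str, str],
    default_class: str | None,
) -> TeAnnotation:
    if fields[1].isdigit() or (fields[1].lstrip("-").isdigit()):
        # simple TSV dialect
        seq_id, start_s, end_s, family = fields[:4]
        strand = fields[4] if len(fields) > 4 and fields[4] else "+"
        te_class = fields[5] if len(fields) > 5 and fields[5] else None
    else:
        # RepeatMasker .out row
        seq_id = fields[4]
        start_s, end_s = fields[5], fields[6]
        strand = "-" if fields[8] in ("C", "-") else "+"
        family = fields[9]
        te_class = None
    start1, end1 = int(start_s), int(end_s)
    if start1 > end1:
        raise ValueError(f"start {start1} > end {end1}")
    if te_class is None:
        te_class = lookup_te_class(family, class_table, default_class)
    # 1-based inclusive -> 0-based half-open
    return TeAnnotation(seq_id, start1 - 1, end1, family, te_class, strand)


def lookup_te_class(
    family: str,
    class_table: Mapping[str, str],
    default_class: str | None = None,
) -> str:
    if family in class_table:
        return class_table[family]
    if default_class is not None:
        logger.warning("family %r not in class table; assuming %s", family, default_class)
        return default_class
    raise ValueError(f"family {family!r} has no class mapping")


def write_te_annotations(annos: Iterable[TeAnnotation], path: str | Path) -> None:
    """Write annotations as the 6-column TSV dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tfamily\tstrand\tte_class\n")
        for a in annos:
            fh.write(f"{a.seq_id}\t{a.start + 1}\t{a.end}\t{a.family}\t{a.strand}\t{a.te_class}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

@dataclass
class Gff3Feature:
    seq_id: str
    source: str
    type: str
    start: int  # 0-based half-open in memory
    end: int
    score: str = "."
    strand: str = "."
    attributes: dict[str, str] = field(default_factory=dict)


def write_gff3(features: Iterable[Gff3Feature], path: str | Path) -> None:
    """Write GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                f"{f.seq_id}\t{f.source}\t{f.type}\t{f.start + 1}\t{f.end}\t"
                f"{f.score}\t{f.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    feats: list[Gff3Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = {}
            if cols[8] != ".":
                for kv in cols[8].split(";"):
                    if kv:
                        k, _, v = kv.partition("=")
                        attrs[k] = v
            feats.append(
                Gff3Feature(
                    seq_id=cols[0],
                    source=cols[1],
                    type=cols[2],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    score=cols[5],
                    strand=cols[6],
                    attributes=attrs,
                )
            )
    return feats
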