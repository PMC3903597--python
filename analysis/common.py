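"""Shared paths and loaders for the numbered analysis scripts.

The scripts run in order; each consumes the files its predecessors wrote
under results/run/ and writes its tables under results/.
"""

from __future__ import annotations

from pathlib import Path

from mulescan.io_formats import parse_fasta, parse_te_annotations, read_gff3

ROOT = Path(__file__).resolve().parent.parent
# bulky regenerable inputs (genome, truth, stripped sequences) live under
# scratch/; only the small report tables go to results/
RUN_DIR = ROOT / "scratch" / "analysis_run"
RESULTS = ROOT / "results"

SEED = 7
SIM = {
    "genome_len": 600_000,
    "n_elements": 50,
    "nested_rate": 1.0,
    "nested_class_mix": 0.6,
    "defect_spectrum": {
        "intact": 0.30,
        "dde_mut": 0.10,
        "start_mut": 0.05,
        "frameshift": 0.15,
        "premature_stop": 0.20,
        "deletion": 0.20,
    },
}


def load_genome():
    return parse_fasta(RUN_DIR / "genome.fa")[0]


def load_annotations():
    return parse_te_annotations(RUN_DIR / "te_annotations.tsv", {}, default_class="DNA")


def load_element_calls():
    """Element spans and their TIR intervals from the discovery GFF3."""
    feats = read_gff3(RUN_DIR / "calls.gff3")
    elements = {}
    for f in feats:
        if f.type == "mule_element":
            elements[f.attributes["ID"]] = {
                "span": (f.start, f.end),
                "tirs": [],
                "tir_identity": float(f.attributes.get("tir_identity", "0")),
            }
    for f in feats:
        if f.type == "terminal_inverted_repeat":
            elements[f.attributes["Parent"]]["tirs"].append((f.start, f.end))
    for e in elements.values():
        e["tirs"].sort()
    return elements
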