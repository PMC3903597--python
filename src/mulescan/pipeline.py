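"""End-to-end orchestration: simulate -> discover -> nest -> date -> classify
-> indel -> express -> report.

Each stage consumes and produces plain files inside a run directory, so any
stage can be re-executed independently.  All randomness flows from the one
seed in the run configuration; a rerun with the same config is bit-identical
for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coding_capacity import annotate_transposase, classify_groups
from .discovery import (
    CandidateMule,
    call_candidate_elements,
    size_profile,
    translated_homology_scan,
)
from .expression import element_expression, expression_summary, match_expression
from .io_formats import (
    Gff3Feature,
    GenomeRecord,
    parse_fasta,
    parse_protein_fasta,
    parse_te_annotations,
    write_fasta,
    write_gff3,
    write_te_annotations,
)
from .indel_evolution import best_homolog_pairs, bin_pairs
from .ltr_dating import age_histogram, date_ltr_pair
from .nesting import (
    NestedInsertion,
    classify_insertion_pattern,
    detect_nested_insertions,
    insertion_disrupts_coding,
    insertion_preference,
    merge_for_strip,
    nested_length_summary,
    strip_nested,
)
from .simulate import (
    SimConfig,
    make_reference_transposase,
    simulate_est_records,
    simulate_genome,
)
from .stats_report import build_reports, group_count_table
from .coding_capacity import NON_REDUNDANT_GROUPS

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "genome",
    "proteins",
    "te_annotations",
    "ests",
    "simulate",
    "min_score",
    "min_tir_identity",
    "tir_len_range",
    "n_ests",
}


@dataclass
class RunConfig:
    seed: int = 7
    out_dir: str = "run"
    genome: str | None = None
    proteins: str | None = None
    te_annotations: str | None = None
    ests: str | None = None
    simulate: dict = field(default_factory=dict)
    min_score: float = 80.0
    min_tir_identity: float = 0.75
    tir_len_range: tuple[int, int] = (50, 800)
    n_ests: int = 40

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.__dict__, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def stage_simulate(cfg: RunConfig, out: Path) -> None:
    """Write a simulated genome, annotations, reference proteins, ESTs, and
    the ground-truth JSON into the run directory."""
    sim_cfg = SimConfig(seed=cfg.seed, **cfg.simulate)
    genome, annos, truth = simulate_genome(sim_cfg)
    ref = make_reference_transposase(sim_cfg.seed)
    write_fasta([(genome.id, genome.seq)], out / "genome.fa")
    write_fasta([(ref.id, ref.protein)], out / "proteins.faa")
    write_te_annotations(annos, out / "te_annotations.tsv")
    rng = np.random.default_rng(sim_cfg.seed + 1)
    elements = [
        (el.element_id, el.seq) for el in truth.elements.values()
    ]
    ests, est_truth = simulate_est_records(elements, cfg.n_ests, rng)
    write_fasta(ests, out / "ests.fa")
    truth_json = {
        "elements": {
            eid: {
                "genome_span": el.genome_span,
                "defects": sorted(el.defects),
                "tir_len": el.tir_len,
                "tsd": el.tsd,
                "nested": [
                    {
                        "family": n.family,
                        "interval": n.interval,
                        "te_class": n.te_class,
                        "ltr_age_myr": n.ltr_age_myr,
                    }
                    for n in el.nested
                ],
            }
            for eid, el in truth.elements.items()
        },
        "est_sources": est_truth,
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=1))


def stage_discover(cfg: RunConfig, out: Path) -> list[CandidateMule]:
    genome = parse_fasta(out / "genome.fa" if cfg.genome is None else cfg.genome)[0]
    proteins = parse_protein_fasta(
        out / "proteins.faa" if cfg.proteins is None else cfg.proteins
    )
    hits = translated_homology_scan(genome, proteins, min_score=cfg.min_score)
    calls = call_candidate_elements(
        genome,
        hits,
        tir_len_range=tuple(cfg.tir_len_range),
        min_identity=cfg.min_tir_identity,
    )
    feats = []
    rows = []
    for c in calls:
        feats.append(
            Gff3Feature(
                seq_id=c.seq_id,
                source="mulescan",
                type="mule_element",
                start=c.span[0],
                end=c.span[1],
                strand=c.strand,
                attributes={"ID": c.id, "tir_identity": f"{c.tir.identity:.3f}"},
            )
        )
        feats.append(
            Gff3Feature(
                c.seq_id, "mulescan", "terminal_inverted_repeat",
                c.tir.left[0], c.tir.left[1], strand="+",
                attributes={"Parent": c.id},
            )
        )
        feats.append(
            Gff3Feature(
                c.seq_id, "mulescan", "terminal_inverted_repeat",
                c.tir.right[0], c.tir.right[1], strand="-",
                attributes={"Parent": c.id},
            )
        )
        rows.append(
            {
                "id": c.id,
                "seq_id": c.seq_id,
                "start": c.span[0],
                "end": c.span[1],
                "tir_identity": round(c.tir.identity, 4),
                "tsd_len": c.tsd.length,
                "tsd_mismatches": c.tsd.mismatches,
                "strand": c.strand,
            }
        )
    write_gff3(feats, out / "calls.gff3")
    pd.DataFrame(rows).to_csv(out / "calls.tsv", sep="\t", index=False)
    return calls


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage; the manifest records versions, config, and failures."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": {},
    }
    stages: dict[str, object] = manifest["stages"]  # type: ignore[assignment]

    def run_stage(name: str, fn) -> object | None:
        try:
            result = fn()
            stages[name] = "ok"
            return result
        except Exception as exc:  # noqa: BLE001 - manifest records the failure
            logger.exception("stage %s failed", name)
            stages[name] = f"failed: {exc}"
            return None

    if cfg.genome is None:
        run_stage("simulate", lambda: stage_simulate(cfg, out))

    calls = run_stage("discover", lambda: stage_discover(cfg, out))
    if not calls:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return out

    genome = parse_fasta(out / "genome.fa" if cfg.genome is None else cfg.genome)[0]
    anno_path = (
        out / "te_annotations.tsv" if cfg.te_annotations is None else cfg.te_annotations
    )
    annos = (
        parse_te_annotations(anno_path, {}, default_class="DNA")
        if Path(anno_path).exists()
        else []
    )
    ref = make_reference_transposase(cfg.seed)

    # --- nesting, stripping, dating, classification --------------------
    element_ins: dict[str, list[NestedInsertion]] = {}
    stripped: dict[str, str] = {}
    labels: dict[str, str] = {}
    with_te: dict[str, bool] = {}
    intact_map: dict[str, bool] = {}
    ages = []
    age_rows = []
    nest_rows = []
    class_rows = []

    def stage_nest_classify() -> None:
        for c in calls:
            seq = genome.seq[c.span[0] : c.span[1]]
            own = {
                a.family
                for a in annos
                if abs(a.start - c.span[0]) <= 25 and abs(a.end - c.span[1]) <= 25
            }
            tirs = (
                (c.tir.left[0], c.tir.left[1]),
                (c.tir.right[0], c.tir.right[1]),
            )
            ins = detect_nested_insertions(
                c.id, c.span, tirs, annos, own_families=own, element_seq=seq
            )
            element_ins[c.id] = ins
            with_te[c.id] = bool(ins)
            stripped_seq, _ = strip_nested(seq, merge_for_strip(ins))
            stripped[c.id] = stripped_seq
            pattern = classify_insertion_pattern(c.id, ins)
            ann = annotate_transposase(c.id, stripped_seq, ref)
            coding = None if ann is None else ann.coding_interval
            for n in ins:
                n.disrupts_coding = insertion_disrupts_coding(n, coding)
                nest_rows.append(
                    {
                        "host_id": c.id,
                        "family": n.family,
                        "start": n.start,
                        "end": n.end,
                        "te_class": n.te_class,
                        "disrupts_coding": n.disrupts_coding,
                        "pattern": pattern.category,
                    }
                )
            if ann is None:
                labels[c.id] = "no_coding_region"
                intact_map[c.id] = False
            else:
                gl = classify_groups(ann)
                labels[c.id] = gl.non_redundant
                intact_map[c.id] = ann.intact
                class_rows.append(
                    {
                        "id": c.id,
                        "non_redundant": gl.non_redundant,
                        "redundant": ",".join(sorted(gl.redundant)),
                        "defects": ",".join(sorted(ann.defects)),
                        "intact": ann.intact,
                    }
                )

    run_stage("nest_classify", stage_nest_classify)
    pd.DataFrame(nest_rows).to_csv(out / "nested_insertions.tsv", sep="\t", index=False)
    pd.DataFrame(class_rows).to_csv(out / "coding_groups.tsv", sep="\t", index=False)

    # --- LTR dating (LTR spans provided by the annotations/truth) -------
    def stage_ltr() -> None:
        truth_path = out / "truth.json"
        if not truth_path.exists():
            return  # no recorded LTR coordinates available for this run
        # LTR boundaries are taken from the simulator's records (de novo LTR
        # boundary detection is out of scope); regenerate them from the seed
        sim_cfg = SimConfig(seed=cfg.seed, **cfg.simulate)
        _, _, full_truth = simulate_genome(sim_cfg)
        for eid, el in full_truth.elements.items():
            if el.genome_span is None:
                continue
            for i, n in enumerate(el.nested):
                if n.ltr_spans is None:
                    continue
                s0 = el.genome_span[0]
                l5 = genome.seq[s0 + n.ltr_spans[0][0] : s0 + n.ltr_spans[0][1]]
                l3 = genome.seq[s0 + n.ltr_spans[1][0] : s0 + n.ltr_spans[1][1]]
                age = date_ltr_pair(f"{eid}.n{i}", l5, l3)
                ages.append(age.age_myr)
                age_rows.append(
                    {
                        "insertion_id": age.insertion_id,
                        "d": round(age.d, 5),
                        "model": age.model,
                        "age_myr": round(age.age_myr, 3),
                    }
                )

    run_stage("ltr_dating", stage_ltr)
    pd.DataFrame(age_rows).to_csv(out / "ltr_ages.tsv", sep="\t", index=False)

    # --- indels ---------------------------------------------------------
    pair_stats = run_stage(
        "indel", lambda: best_homolog_pairs(stripped)
    ) or []
    pd.DataFrame(
        [
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "identity": round(p.identity, 4),
                "n_indels": p.n_indels,
                "indel_len_total": p.indel_len_total,
                "nik": round(p.nik, 4),
                "lik": round(p.lik, 4),
            }
            for p in pair_stats
        ]
    ).to_csv(out / "indel_pairs.tsv", sep="\t", index=False)

    # --- expression -----------------------------------------------------
    expressed: dict[str, bool] = {}

    def stage_express() -> None:
        est_path = out / "ests.fa" if cfg.ests is None else Path(cfg.ests)
        if not Path(est_path).exists():
            raise FileNotFoundError(f"EST file {est_path} missing")
        ests = [(r.id, r.seq) for r in parse_fasta(est_path)]
        hits = match_expression(stripped, ests)
        expressed.update(element_expression(hits))

    run_stage("expression", stage_express)

    # --- reports --------------------------------------------------------
    def stage_report() -> None:
        lengths = {eid: len(s) for eid, s in stripped.items()}
        red_labels = {eid: labels[eid].split(".")[0] for eid in labels}
        build_reports(
            out / "reports",
            size_profile=size_profile(lengths),
            nested_summary=nested_length_summary(element_ins),
            insertion_preference=insertion_preference(
                {c.id: c.span for c in calls},
                {c.id: c.tsd.length for c in calls},
                annos,
                element_ins,
                exclude_hosts={
                    a.family for a in annos if a.family.startswith("MULE_")
                },
            ),
            group_counts_redundant=group_count_table(
                red_labels, with_te, ("I", "II", "III", "IV", "V", "VI")
            ),
            group_counts_non_redundant=group_count_table(
                labels, with_te, NON_REDUNDANT_GROUPS
            ),
            expression=expression_summary(expressed, intact_map),
            indel_bins=bin_pairs(pair_stats, "identity"),
            age_bins=age_histogram(ages),
        )

    run_stage("report", stage_report)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
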