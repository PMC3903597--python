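"""Generate the study genome: 50 MULEs with a mixed defect spectrum and
nested TE insertions on a 600 kb background, plus reference transposase,
TE annotation table, EST set, and the ground-truth record."""

from common import RUN_DIR, SEED, SIM

from mulescan.pipeline import RunConfig, stage_simulate


def main() -> None:
    RUN_DIR.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(seed=SEED, out_dir=str(RUN_DIR), simulate=SIM, n_ests=60)
    stage_simulate(cfg, RUN_DIR)
    print(f"simulated inputs written to {RUN_DIR}")
    print("files: genome.fa, proteins.faa, te_annotations.tsv, ests.fa, truth.json")


if __name__ == "__main__":
    main()
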