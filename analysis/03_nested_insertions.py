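"""Detect nested TE insertions inside the called elements, tabulate their
classes and patterns, date the nested LTR retroelements, and write the
stripped element sequences for the downstream coding and indel analyses."""

import json

import pandas as pd
from common import RESULTS, RUN_DIR, SEED, SIM, load_annotations, load_element_calls, load_genome

from mulescan.io_formats import write_fasta
from mulescan.ltr_dating import age_histogram, date_ltr_pair
from mulescan.nesting import (
    classify_insertion_pattern,
    detect_nested_insertions,
    merge_for_strip,
    nested_length_summary,
    strip_nested,
)
from mulescan.simulate import SimConfig, simulate_genome
from mulescan.stats_report import histogram_table


def main() -> None:
    genome = load_genome()
    annos = load_annotations()
    elements = load_element_calls()

    element_ins = {}
    stripped = []
    patterns = []
    for eid, e in elements.items():
        span, tirs = e["span"], e["tirs"]
        own = {
            a.family for a in annos
            if abs(a.start - span[0]) <= 25 and abs(a.end - span[1]) <= 25
        }
        ins = detect_nested_insertions(
            eid, span, (tirs[0], tirs[1]), annos, own_families=own,
            element_seq=genome.seq[span[0]:span[1]],
        )
        element_ins[eid] = ins
        patterns.append(classify_insertion_pattern(eid, ins))
        seq, _ = strip_nested(genome.seq[span[0]:span[1]], merge_for_strip(ins))
        stripped.append((eid, seq))
    write_fasta(stripped, RUN_DIR / "stripped_elements.fa")
    pd.DataFrame(
        [
            {
                "host_id": n.host_id,
                "family": n.family,
                "start": n.start,
                "end": n.end,
                "te_class": n.te_class,
            }
            for ins in element_ins.values()
            for n in ins
        ]
    ).to_csv(RUN_DIR / "nested_insertions.tsv", sep="\t", index=False)

    summary = nested_length_summary(element_ins)
    summary.to_csv(RESULTS / "nested_te_summary.tsv", sep="\t", index=False)
    print("nested TE insertions by class (count, mean length):")
    print(summary.to_string(index=False))

    pat = pd.Series([p.category for p in patterns]).value_counts()
    pat.rename_axis("pattern").to_frame("n_elements").to_csv(
        RESULTS / "insertion_patterns.tsv", sep="\t"
    )
    print("\ninsertion patterns:", dict(pat))

    # dating uses the simulator's recorded LTR boundaries (de novo LTR
    # structure detection is out of scope)
    _, _, truth = simulate_genome(SimConfig(seed=SEED, **SIM))
    ages = []
    for eid, el in truth.elements.items():
        if el.genome_span is None:
            continue
        s0 = el.genome_span[0]
        for i, n in enumerate(el.nested):
            if n.ltr_spans is None:
                continue
            l5 = genome.seq[s0 + n.ltr_spans[0][0] : s0 + n.ltr_spans[0][1]]
            l3 = genome.seq[s0 + n.ltr_spans[1][0] : s0 + n.ltr_spans[1][1]]
            ages.append(date_ltr_pair(f"{eid}.n{i}", l5, l3).age_myr)
    hist = histogram_table(age_histogram(ages))
    hist.to_csv(RESULTS / "ltr_age_bins.tsv", sep="\t", index=False)
    print(f"\n{len(ages)} nested LTR retroelements dated; age bins (Myr):")
    print(hist.to_string(index=False))


if __name__ == "__main__":
    main()
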