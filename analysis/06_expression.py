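"""Score EST evidence for the stripped elements and build the expression
summary split by transposase status."""

import pandas as pd
from common import RESULTS, RUN_DIR

from mulescan.expression import element_expression, expression_summary, match_expression
from mulescan.io_formats import parse_fasta


def main() -> None:
    stripped = {r.id: r.seq for r in parse_fasta(RUN_DIR / "stripped_elements.fa")}
    ests = [(r.id, r.seq) for r in parse_fasta(RUN_DIR / "ests.fa")]
    hits = match_expression(stripped, ests)
    expressed = element_expression(hits)
    n_exp = sum(expressed.values())
    print(f"{len(hits)} EST/element matches; {n_exp} elements with evidence "
          f"(>=99.5% identity over the EST, >=300 bp)")

    defects = pd.read_csv(RESULTS / "coding_defects.tsv", sep="\t")
    intact = dict(zip(defects.id, defects.intact))
    summary = expression_summary(expressed, intact)
    summary.to_csv(RESULTS / "expression_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))

    pd.DataFrame(
        [
            {
                "element_id": h.element_id,
                "est_id": h.est_id,
                "identity": round(h.identity, 4),
                "matched_len": h.matched_len,
                "evidence": h.evidence,
            }
            for h in hits
        ]
    ).to_csv(RESULTS / "expression_hits.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
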