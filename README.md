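# mulescan

Structural annotation and degeneration analysis of **coding MULEs** —
*Mutator*-like DNA transposons that still carry transposase sequence,
complete or decayed.

MULEs are class II transposons bounded by long terminal inverted repeats
(TIRs, 100–500 bp) and flanked by an 8–11 bp target site duplication (TSD)
created on insertion. Autonomous copies encode a transposase with an
N-terminal helix-turn-helix (HTH) DNA-binding domain and a C-terminal DDE
catalytic triad. Over time most copies lose coding capacity — through nested
insertions of other transposable elements, deletions, frameshifts, premature
stop codons, and point mutations of key residues. `mulescan` implements the
complete desk-scale workflow for dissecting that decay:

1. **Discovery** — six-frame translated homology search for transposase,
   then validation of a flanking TIR pair (>75% identity, inverted
   orientation, 2–30 kb span) and an 8–11 bp TSD under per-length tolerance
   rules (8 bp: one mismatch *or* one single-base indel; 9–11 bp: two
   mismatches, or one mismatch plus one indel).
2. **Nesting** — nested TE insertions called from a RepeatMasker-style
   annotation table, classified (RNA / DNA / mixed patterns), tested for
   coding disruption, and excised (together with their own duplicated target
   sites) to restore the pre-insertion element.
3. **Dating** — nested LTR retroelements aged from the divergence *d* of
   their two LTRs: *T = d / (2r)* with *r* = 1.3×10⁻⁸ substitutions per
   site per year (K2P by default; JC69 and p-distance available).
4. **Coding capacity** — the transposase coding region is mapped by
   translated alignment to a reference transposase; defects are detected and
   elements fall into six groups (I intact; II DDE/start-codon mutation;
   III frameshift; IV premature stop; V frameshift + stop; VI deletions),
   in both redundant and single-label (non-redundant) schemes.
5. **Indel accumulation** — each element is paired with its closest homolog;
   indels are counted on affine-gap global alignments and normalised per kb
   of summed pair length (**NIK** = indels/kb, **LIK** = indel bp/kb),
   binned by nucleotide identity or by synonymous substitution rate
   (**Ks**, Nei–Gojobori 1986 with Jukes–Cantor correction).
6. **Expression** — EST/flcDNA evidence at ≥99.5% identity over the whole
   EST with ≥300 bp matched.
7. **Statistics** — Pearson χ² on 2×2 tables (df = 1, *no* continuity
   correction — that is the variant that reproduces the published values)
   and Welch *t*-tests.

Real genome assemblies are out of scope; the package ships a synthetic-data
generator (`mulescan.simulate`) that plants elements with fully recorded
ground truth — TIR identity, TSD, coding defects at known positions, nested
TEs with age-controlled LTR divergence — so every step is validated by
recovery against truth.

## Worked example

```bash
mulescan run-all --seed 7 --out run_demo
```

runs simulate → discover → nest → date → classify → indel → express →
report on a default simulation (600 kb genome, 50 planted elements) and
prints the stage status. The numbered scripts under `analysis/` run the
same study step by step with a mixed defect spectrum and nested TEs; on the
default seed they print:

```
50 calls; precision 1.000, recall 1.000 vs planted truth
nested TE insertions by class: RNA 34 (mean 2858 bp), DNA 16 (mean 486 bp)
34 nested LTR retroelements dated; largest age bin 1-2 Myr
18/50 elements carry a putative intact transposase
overall mean NIK: 1.30 vs 0.75 (ratio 1.75, planted 1.77)
chi2 reproduction: all eight published statistics match to ±0.01
```

meaning: every planted element was recovered with exact or near-exact
boundaries; the defect-group table matches the planted spectrum; doubling
the simulated indel rate doubles the measured NIK; and the eight published
χ² statistics recompute exactly from their 2×2 count tables (e.g.
`[[31, 499], [168, 308]]` → χ² = 137.0185 for the intact-transposase
contrast between 530 and 476 elements of two grass genomes).

Individual stages are also exposed as subcommands
(`mulescan simulate | discover | chi2 | run-all`), e.g.

```bash
mulescan chi2 --table 31,499,168,308
# chi2 = 137.0185, df = 1, p = 0.0000
```

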