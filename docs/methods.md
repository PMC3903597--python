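# Methods

## Scope and design

`mulescan` annotates coding MULEs — *Mutator*-like DNA transposons carrying
transposase sequence — and quantifies how they lose coding capacity. The
package replaces the external tools a genome-scale study would use (BLAST,
RepeatMasker, MUSCLE, MEGA, KaKs_Calculator, Jpred3) with compact,
self-contained equivalents of the *decision rules* those tools feed:
translated homology search, interval arithmetic over an annotation table,
alignment-based divergence, NG86 Ks, and a homology-based stand-in for
secondary-structure HTH detection. Genome-scale runs on real assemblies are
out of scope; all validation is against synthetic genomes with planted
ground truth.

## Element model and discovery

A candidate element must satisfy three criteria: transposase homology
between a TIR pair; pairwise TIR identity above 0.75 in inverted
orientation, spanning 2–30 kb (measured TIR start to TIR end, nested
insertions included); and an 8–11 bp TSD immediately flanking the TIRs
(8 bp: one mismatch or one single-nucleotide indel allowed; 9–11 bp: up to
two mismatches, or one mismatch plus one indel). An 8/9-length TSD pair is
scored at the longer length.

**Translated search.** Exact amino-acid 4-mer seeds between each reading
frame of the genome and the reference transposase are clustered by diagonal
(band 20 aa, positional gap ≤ 120 aa, ≥ 2 seeds); each cluster is refined by
BLOSUM62 local alignment (gap open −11, extend −1). The raw-score threshold
(default 80) replaces a database-size-dependent E-value; on random 100 kb
sequence it yields no hits in ≥95% of seeds (tested).

**TIR pairing.** Exact 12-mer seeds between a window and its reverse
complement are clustered by diagonal and polished by local alignment with a
deliberately mild mismatch penalty (+1/−0.75, gaps −4/−1) so that noisy but
real TIR ends are not trimmed away; identity is matches over aligned
columns. TIR length is searched at 50–800 bp, a superset of the canonical
100–500 bp, to avoid boundary misses.

**TSD anchoring.** The aligned TIR core can be off by a few bases
(mismatched terminal columns), occasionally trimmed deep where mutations
cluster at a TIR end, or slightly over-extended. The element boundary is
defined by the TSD, so the flanking direct repeat is searched around the
aligned boundary: within ±3 bp the full tolerance rules apply; farther out
(to 160 bp outward / 45 bp inward) only an *exact* direct repeat is
accepted, and the two boundary shifts must be near-opposite because one
local alignment couples the two TIR ends. Candidates are ranked by fewest
TSD edits, then longest TSD, then smallest boundary adjustment. The inward
limit reflects overshoot dynamics (a random walk against drift, empirically
≤ 40 bp); the asymmetric exact-only rule keeps the false-TSD rate per
element in the percent range despite the permissive 8 bp rule. When several
TIR pairs explain one homology hit, the pair with a valid TSD, then the
highest identity, then the smallest span wins; spans are deduplicated.

## Nesting

Annotated TE intervals strictly inside an element (excluding its own TIRs
and own family) are insertion events; fragments of one family and strand
within 50 bp merge into one event (masking output fragments single
insertions; the window is a design choice). "Disrupts coding" means *any*
overlap with the coding interval, not containment — a TE straddling a CDS
edge still breaks the frame. Because annotation intervals cover the TE
proper, the duplicated target site the TE created is located by direct
comparison (longest exact duplicate ≥ 3 bp immediately 3′ of the interval)
and excised together with it, so stripping restores the pre-insertion
sequence exactly; overlapping excisions (TEs nested inside nested TEs) are
unioned first. An element counts as inserted *into* another TE when its
span plus TSD (±20 bp) lies inside one annotated feature.

## LTR dating

Age = d / (2r) with r = 1.3×10⁻⁸ substitutions/site/year; the factor 2 is
the standard LTR-dating convention (each LTR accumulates r·T independently
after insertion). d is computed on a global alignment with gap columns
excluded; the default model is K2P (the common default of the usual
distance software), with JC69 and p-distance as options, because the exact
model behind the published ages is unstated — the dating acceptance is
therefore property-based (recovery of planted ages), not tied to published
bin fractions. Pairs under 50 bp, or aligning at <50% identity or coverage,
are rejected as non-LTR pairs. De novo LTR boundary detection is out of
scope: boundaries come from the simulator's records or from annotations.

## Coding capacity

The stripped element is aligned in translated frames (both strands, best
strand kept) to the reference transposase; alignment blocks with score ≥ 60
define the coding region. Defect rules, with explicit stand-in thresholds
where the original operational definitions are unstated:

* **frameshift** — consecutive blocks in different frames (a deletion of
  length not divisible by 3 records both deletion and frameshift);
* **premature stop** — an aligned stop before 95% of the aligned reference
  span;
* **deletion** — a reference-coverage gap ≥ 30 aa, terminal gaps included,
  so a lost HTH or DDE region counts;
* **DDE/start mutation** — a catalytic D, D or E aligned to a different
  residue (only called when the catalytic span is frameshift-free;
  otherwise the residues sit in misaligned wrong-frame sequence), or no Met
  within 30 codons of the aligned reference start (assessed only when the
  reference start is covered).

The catalytic domain is present when the three residues align as D, D, E,
the element-side first-D-to-E span exceeds 100 aa, and that span contains no
stop or frameshift. The HTH domain uses homology to the annotated reference
HTH segment (≥80% coverage at ≥40% identity, clean of stops/frameshifts) —
a pluggable stand-in for secondary-structure prediction; the classification
logic, not the predictor, is the scientific content. Intact ⇔ both domains
present and no defects. Group labels: redundant membership in I–VI, and a
single non-redundant label in which deletion-bearing elements take a VI
subtype keyed by their co-occurring defects. Elements with domain evidence
missing but no recorded defect default to the deletion-only subtype.

## Indels and Ks

Partner selection ("most significant alignment" operationalised as longest
alignment, ties by identity then id) is screened with unit-cost global
alignment (edlib), scoring partners by matched columns — alignment *columns*
alone would favour unrelated sequences, which accumulate columns through
indels. Final statistics come from an affine-gap global alignment (match
+1, mismatch −2, gap open −8, extend −1, free terminal gaps; GCG-`gap`-like
defaults, configurable): one maximal gap run = one indel regardless of
length, terminal runs excluded, identity = matches over non-gap columns
(gap columns excluded; exposed as the package's reading of an ambiguous
convention). Pairs must exceed 95% identity and align over ≥50% of the
shorter sequence. NIK = indels × 1000 / (len_a + len_b); LIK likewise with
summed indel length. The pair is aligned in canonical order so the
statistics are exactly symmetric. Ks uses NG86 — per-codon synonymous-site
fractions averaged over the two sequences, pathway-averaged difference
counts, Jukes–Cantor correction — on a codon alignment threaded through the
protein alignment; codons with gaps, N or stops are dropped and fewer than
30 comparable codons yields no estimate. Changes to stop codons count as
nonsynonymous. Insertions cannot be distinguished from deletions in pairwise
data, so no polarisation is attempted.

## Expression

An element has evidence when an EST matches at ≥99.5% identity with ≥300 bp
matched and ≥99% EST coverage — the conjunction of the two published
phrasings ("over the entire length of the EST" and "entire matched sequence,
at least 300 bp"). Matching is a 16-mer prefilter followed by semi-global
(infix) unit-cost alignment of the EST into the element, both strands;
multi-element ESTs credit every element they match.

## Statistics

χ² on 2×2 tables is Pearson's statistic with expected counts from margins,
df = 1, *without* continuity correction — verified to reproduce all eight
published statistics to four decimals from their printed counts; with Yates
correction none of them reproduce. Published values whose underlying counts
are not printed in full (49.6349, 71.4396, 112.5264, 20.3473, 25.7360,
23.0278, 25.1084) are not reproducible from the text alone and are excluded.
The two-sample test is Welch's t by default (the published "t-test" variant
is unstated), Student's optional.

## Synthetic data: what it emulates, and what it does not

The generator plants, on an i.i.d. background of configurable GC (default
0.44, a grass-like value): elements of 2.5–9.5 kb with TIRs of 100–500 bp at
a planted identity (default 0.85, realised exactly by counting mutated
sites), identical 8–11 bp TSD copies, and a transposase CDS back-translated
with random synonymous codons from a synthetic ~800-aa reference of
MURA-like architecture (HTH at residues 25–65; D, D, E at 430/470/545,
first-D-to-E span 115 aa) — generated, not a real protein, so no third-party
sequence ships with the package; every rule depends only on architecture.
Defects are planted at recorded positions: catalytic D→N, start ATG→ACG,
single-base frameshift, in-frame TAA at 20–80% of the CDS, in-frame
deletions of 40–150 codons placed to leave the start-scan window intact.
Nested TEs carry their own TSDs (LTR retroelement 5 bp, MITE 3 bp — 274 bp
long by default, the size of a well-known *Tourist*-like MITE — generic
DNA TE 9 bp); both LTRs of a retroelement are mutated independently at
r·T per site so the pair diverges at 2rT (pooled divergence verified within
10% over ≥100 replicates). Homolog divergence is Binomial substitution +
Poisson(L/1000·rate) indels with Geometric(p = 0.3) lengths — a short-indel-
dominated shape chosen as the standard empirical default, configurable, as
no distribution is prescribed. ESTs are 300–1500 bp (near-)exact substrings.

Not emulated: isochores and repeat landscape, TE family phylogenies,
transposition dynamics, selection, polymorphic boundaries, sequencing error.
Passing recovery tests therefore demonstrates the correctness of the
decision rules and their robustness to the modelled noise — not performance
on real assemblies, where diverged TIR families, fragmented annotations and
tandem repeats add failure modes this generator does not produce.

## Problem sizes and determinism

Default study conditions: 600 kb genome, 50 elements (discovery recovery);
200 single-defect elements (classification); 100 replicates for LTR ages and
for each indel-rate level; 40–60 ESTs. One `numpy` Generator seeded from the
run seed drives everything; fixed seed gives bit-identical FASTA/TSV output.
The pipeline writes stage outputs as plain files in a run directory with a
manifest (version, config hash, per-stage status), so stages can be re-run
independently and a failed stage does not take down the rest.

## Known limitations

* Discovery assumes TSDs survive recognisably; elements with fully decayed
  TSDs are (correctly, per the calling rules) not called.
* A frameshift element's wrong-frame tail occasionally aligns a chance stop
  codon, upgrading III to V (~1–2% of frameshift cases in testing).
* The non-redundant VI subtypes prioritise frameshift+stop > frameshift >
  stop > DDE/start when several co-occur with deletion.
* `best_homolog_pairs` needs genuine families; independently planted
  elements rarely exceed the 95% identity bar, so family-level statistics
  on simulations use controlled homolog pairs instead.
* Representative clustering measures identity over the shorter element
  ("80% of the element region" is read as coverage of the shorter).
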