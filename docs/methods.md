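# Methods

## The design problem

A back-splice junction (BSJ) is the covalent joint between a circRNA's 3'
end and its 5' start. Linear primer pairs anywhere else on the locus also
amplify the host transcript or the genome; only an amplicon that crosses
the BSJ is specific to the circular isoform. circseam therefore designs on
a *junction template* — a linear sequence that exists only in the circle —
and requires every reported product to contain the junction strictly in
its interior.

## Junction templates

For a record `[start, end)` with span `s = end − start` and shift ranges
`(L, R)` (defaults 150/150 nt):

* `left_used = min(L, s)`, `right_used = min(R, s)`; the junction index is
  `left_used`.
* `+` strand: `genome[end−left_used : end] + genome[start : start+right_used]`.
* `−` strand: built on the transcribed strand — reverse complement of
  `genome[start : start+left_used]` followed by reverse complement of
  `genome[end−right_used : end]`.

Clamping at one full turn is deliberate: wrapping a short circle further
would place a second copy of the junction inside the template and create
artifactual primer sites. Templates are contiguous genomic flanks; BED12
block structure (introns of multi-exon circles) is *not* spliced out. For
a multi-exon circle whose BSJ-adjacent exons are shorter than the shifts,
part of a flank may be intronic — a known approximation; shrink the shifts
if this matters for a given locus.

Records on sequences missing from the genome, records exceeding contig
bounds, and records whose entire flank is N are reported in
`failures.tsv`, not errors.

## Thermodynamics

Tm uses the unified nearest-neighbor DNA/DNA parameter set: stacking
ΔH°/ΔS° per dinucleotide, terminal initiation terms (G·C: +0.1 kcal/mol,
−2.8 cal/mol·K; A·T: +2.3, +4.1), an entropic salt correction
`0.368·(N−1)·ln[Na+]`, and `Tm = ΔH°·1000 / (ΔS° + R·ln(CT/4)) − 273.15`
for a non-self-complementary primer in excess over template. Defaults:
CT = 50 nM, [Na+] = 50 mM. The engine is deterministic to well below
0.01 °C; the test suite checks it against both a hand-written summation
oracle with the full 16-entry table and Biopython's implementation of the
same parameter set.

## Screens and scoring

| parameter | default | notes |
|---|---|---|
| primer length | 15–20 nt, optimum 19 | |
| product size | 150–200 nt | must strictly contain the junction |
| Tm window | 57–63 °C, optimum 60 | user-set in °C |
| pair ΔTm | ≤ 3 °C | |
| GC | 20–80% | |
| homopolymer | ≤ 4 nt | |
| self-dimer | ≤ 8 matches overall, ≤ 4 at the 3' end | max Watson–Crick matches over all ungapped antiparallel offsets |
| hairpin stem | ≤ 4 bp | loop ≥ 3 nt |
| sets per circRNA | 4 | ranked alternatives for one junction, not a multiplex |
| record cap | 100 per run | truncate with a warning; `--strict` errors |

Candidate penalty: `1.0·|len−19| + 1.0·|Tm−60| + 10.0·|GC−0.5|`; pair
penalty adds `0.5·ΔTm`. Ties are broken by (penalty, product start,
forward sequence), which makes ranked output byte-deterministic. Filters
run cheapest-first (alphabet, homopolymer, GC, Tm, then the quadratic/cubic
structure screens), which keeps exhaustive window enumeration at default
template size around tens of milliseconds per circRNA.

Candidates may themselves lie across the junction point; only the product
is required to contain it (`primer_on_junction=False` forbids it).

## Specificity check

A windowed in-silico PCR: both primers are exact-matched on both strands
of the locus ± 5 kb; the pair fails if any convergent placement yields a
linear product ≤ 5 kb. Junction-spanning pairs are divergent on the linear
locus by construction, so failures indicate local repeats (the fixture
generator can plant such repeats on purpose). This is a locus-windowed
check with exact matching, not a genome-wide thermodynamic off-target
search.

## PCR conditions

Bench heuristics, configurable: annealing at `min(Tm_f, Tm_r) − 3 °C`
(rounded to 0.1), extension `max(30, ceil(product/1000)·30)` s, 35 cycles,
95 °C denaturation.

## Synthetic data

`make_fixture` writes an i.i.d. random genome at a target GC, plants
non-overlapping circles, and serializes the truth set in all eight caller
dialects with each dialect's own coordinate convention; the same seed
always produces identical bytes. Options mask a circle's sequence to N
(an undesignable record) or copy a donor flank reverse-complemented
downstream (a convergent repeat that fails the specificity check).

What the generator emulates: coordinate conventions, strand mix, span
distributions, GC composition. What it does not: splice-site motifs, exon
structure, repeat families, assembly gaps, chromosome naming schemes
(`chr1` vs `NC_…`). Passing tests therefore demonstrate the coordinate
arithmetic, thermodynamics and design contract, not recall on real
genomes, where candidate yield depends on local GC and the configured Tm
window. Test and acceptance runs use 20–80 kb contigs with 10–100 circles
per dataset, sizes at which an exhaustive enumeration engine is already
comfortably fast.

## Open choices made here

* The Tm window has no universal default in common practice; 57/60/63 °C
  was fixed so the tool runs usefully out of the box at the default 50 nM
  / 50 mM conditions. At these conditions a 57–63 °C window selects
  GC-rich candidates; AT-rich loci may need a lower window.
* "Primer sets" means ranked alternative pairs for the same junction.
* Duplicate input rows are merged (first occurrence wins); the cap
  truncates rather than errors unless `--strict`.
* Strand `.` is treated as `+` with a warning.
* Chromosome-name mismatches between the coordinate file and the genome
  are surfaced as per-record failures, never silently aliased.
* `circRNA_finder` files are column-compatible with BED6, so format
  auto-detection labels them BED; coordinates are identical either way.
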