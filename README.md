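# circseam

Circle-specific PCR primer design for circular RNA (circRNA) validation.

circRNAs are covalently closed RNAs produced by back-splicing: a downstream
splice donor joins an upstream splice acceptor, so the only sequence unique
to the circular isoform is the back-splice junction (BSJ) itself. RT-PCR and
qPCR validation of bioinformatically predicted circRNAs therefore needs
*divergent* primers — a pair that points away from each other on the linear
host gene but converges across the BSJ on the circle, so only the circular
isoform yields a product.

circseam takes circRNA coordinates in the native output of any major
predictor — CIRI2, find_circ, CIRCexplorer2, DCC, circRNA_finder, KNIFE,
mapsplice, or plain BED — together with a reference genome (a local FASTA,
or an NCBI assembly accession fetched once into a cache), and designs ranked
junction-spanning primer sets with recommended thermocycling conditions. It
is a library plus a command line; people who design validation primers for
circRNA-seq studies are the intended users.

## Method

For each circRNA `[start, end)` on a strand, the circle is linearized
locally around its junction: the template is the circle's 3'-flank
concatenated to its 5'-flank,

```
template = genome[end-L : end] + genome[start : start+R]        (+ strand)
```

with the junction at index `L`. The shift ranges `L` and `R` default to
150 nt each, so a circle of span ≥ 150 gives a 300-nt template with the
junction at 150; shorter circles are clamped to one full turn per flank.
Minus-strand circles are built on the transcribed strand.

Candidate primers are every template substring of length 15–20 nt (optimum
19) passing GC (20–80%), homopolymer (≤ 4), self-dimer, hairpin and melting
temperature screens. Tm is computed in-package by unified nearest-neighbor
thermodynamics:

```
Tm = ΔH° / (ΔS° + 0.368 (N−1) ln[Na+] + R ln(CT/4)) − 273.15
```

with per-dinucleotide ΔH°/ΔS° stacking and terminal initiation terms, at
50 nM primer and 50 mM monovalent salt by default (window 57–63 °C, optimum
60 °C). Pairs must give a product of 150–200 nt that *strictly contains the
junction*, with |ΔTm| ≤ 3 °C; they are ranked by a penalty
`|len−19| + |Tm−60| + 10·|GC−0.5|` per primer plus `0.5·ΔTm`, and the top 4
sets per circRNA are reported (all bounds configurable). A windowed
in-silico PCR against the linear locus flags repeat-mediated convergent
sites, and each pair gets bench conditions (annealing at min Tm − 3 °C,
extension 30 s per started kb, 35 cycles). Up to 100 records are processed
per run; duplicates are dropped keeping the first.

## Worked example

```
$ circseam fixture --seed 5 --out demo/fx --circles 6 --contig-len 20000 --gc 0.6
wrote genome + 8 call files to demo/fx

$ circseam design --input demo/fx/calls.bed --genome demo/fx/genome.fa --out demo/out
designed primer sets for 6 of 6 circRNAs -> demo/out
```

`demo/out/primers.tsv` begins:

```
circ_id   set_rank  forward_seq          reverse_seq          ...  product_size  junction_index  pair_penalty  annealing_temp  specificity
circ_001  1         GACTCGCGTTTCGCCGGGT  GCGCGCGAAAGGTGCCTTG  ...  174           150             3.873         57.0            pass
circ_001  2         ACTCGCGTTTCGCCGGGTC  GCGCGCGAAAGGTGCCTTG  ...  173           150             3.873         57.0            pass
```

Read: for `circ_001` the best pair amplifies a 174-nt product whose
template interval contains the junction (index 150), both primers melt
near 60 °C (pair penalty 3.873, lower is better), anneal at 57 °C, and the
pair is divergent on the linear locus (`specificity pass` — no convergent
linear product within 5 kb). Undesignable records appear in
`failures.tsv` with a reason; `templates.fasta` holds the junction
templates and `run_log.txt` echoes the configuration.

The same run works directly from predictor output (`--format ciri2`, `dcc`,
…) and from an assembly accession instead of a local FASTA
(`--accession GCF_001858045.2`, downloaded once into `~/.cache/circseam`).

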