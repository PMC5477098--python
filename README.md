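# mpxdesign

Multiplex-PCR (MPCR) primer design for continuous genomic targets, aimed at
targeted amplicon sequencing on short-read instruments. Given a region such
as a whole small gene or a run of closely spaced exons (with its flanking
sequence), `mpxdesign` tiles it with overlapping 300–500 bp amplicons,
assigns the amplicons round-robin to *m* ≥ 2 reaction tubes, and guarantees
that all primers placed in one tube are pairwise free of stable cross-dimers.
Because adjacent amplicons overlap and land in different tubes, every
internal primer binding site is itself sequenced from a neighboring
amplicon — the standard guard against allele dropout caused by an unknown
variant under a primer's 3′ end.

## The design model

Every candidate primer is an oligo of 23–30 nt lying inside the target that
passes:

* GC fraction in [0.30, 0.70] (inclusive);
* no homopolymer of 4+ bases;
* nearest-neighbor melting temperature within 0.5 °C of the configured
  optimum, Tm = ΔH° / (ΔS° + R ln(C_T/x)) − 273.15 with the unified
  SantaLucia (1998) dinucleotide parameters and entropy salt correction;
* hairpin and homodimer ΔG°₃₇ ≥ −3 kcal/mol (structures below −3 kcal/mol
  are stable enough to inhibit PCR);
* no known variant on the template under the oligo's 3′-terminal 3 bases;
* optionally, specificity: a candidate with more than one hit in a reference
  (exact-match index, or `blastn` alignments with E < 0.01) is discarded —
  the one allowed hit being its own locus.

A solution is an ordered chain of primer pairs. Writing Pos(F_n) for a
forward primer's first template base and Pos(R_n) for a reverse primer's
last, product *n* (tube *n* mod *m*) must satisfy

```
Pos(F_0) within the first n_flank bases        (first window)
Pos(R_last) within the last n_flank bases      (final window)
Pos(F_n) < Pos(R_n-1)                          (adjacent products overlap)
Pos(F_n) > Pos(R_n-2)                          (products two apart disjoint)
Pos(R_n) > Pos(R_n-1)                          (strict left-to-right progress)
Pos(F_n) > Pos(R of previous product in tube)  (no within-tube overlap)
```

plus, per pair, amplicon length in [300, 500], |ΔTm| ≤ 0.5 °C and
heterodimer ΔG ≥ −3 kcal/mol; and per tube, *all* primers pairwise
compatible — each tube is a clique in the primer-compatibility graph.
Finding such cliques is NP-complete, so the search is a time-limited
depth-first walk over candidates (in one of four configurable orderings by
base location) that returns the **first** feasible tiling, or `infeasible` /
`timeout`.

## Worked example

```bash
python examples/01_design_multiplex.py
```

```
region: fixture_seed42 (909 bp)
status: solved   pairs: 3   elapsed: 0.026 s

product 0 -> tube 0  amplicon [9, 349) (340 bp)
  fwd     9-32    AAATGCCCAGTCCTAGCGAGAAA  Tm=56.20C GC=0.48
  rev   326-349   AAAGACCTGTACTCGGCTCGAAA  Tm=55.94C GC=0.48

product 1 -> tube 1  amplicon [259, 599) (340 bp)
  fwd   259-282   AAAGTCCAGCGAGGTATCCCAAA  Tm=55.86C GC=0.48
  rev   576-599   AAAGCGATGAACACACCGTGAAA  Tm=55.93C GC=0.43

product 2 -> tube 0  amplicon [509, 849) (340 bp)
  fwd   509-532   AAACGCAGGATCTGTTTGCCAAA  Tm=56.13C GC=0.43
  rev   826-849   AAATGTCCCGCACATTGGTGAAA  Tm=55.86C GC=0.43
```

Three overlapping 340 bp amplicons cover the region; products 0 and 2 share
tube 0 and do not overlap each other, while product 1 (tube 1) covers both
internal primer sites. All six primers sit within 0.5 °C of each other.
The other examples show the thermodynamic screens (`02`), the factorial
benchmark grid with Fisher's exact comparisons (`03`), and the BED/TSV
export formats (`04`).

The same run is available as a shell command:

```bash
mpxdesign design --fasta region.fa --flank 240 --tubes 2 \
    --ordering bothNormal --time-limit 240 --out-prefix mydesign
```

writing `mydesign.amplicons.bed` (score column = tube index) and
`mydesign.primers.tsv` (1-based inclusive coordinates).

## Layout

| Path | What it holds |
| --- | --- |
| `src/mpxdesign/thermo.py` | NN melting temperature, duplex/hairpin ΔG |
| `src/mpxdesign/candidates.py` | candidate enumeration, filters, specificity |
| `src/mpxdesign/search.py` | the depth-first tiling search |
| `src/mpxdesign/verify.py` | standalone solution verifier |
| `src/mpxdesign/fixtures.py` | synthetic regions + exhaustive tiling oracle |
| `src/mpxdesign/benchmark.py` | factorial grid, Fisher comparisons |
| `src/mpxdesign/reporting.py` | BED / TSV serialization |
| `docs/methods.md` | model, parameters, numerical choices, limitations |
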