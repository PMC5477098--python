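# Methods

## Problem and model

`mpxdesign` designs primers for multiplex PCR over one continuous genomic
target. The input is a single DNA sequence (the target plus flanking
sequence on both sides), an optional set of known variant positions, and a
configuration. The output is an ordered chain of forward/reverse primer
pairs whose amplicons tile the target left to right with overlaps, each
product assigned to tube `n mod m`.

The overlap-and-alternate layout exists for one biological reason: an
unknown variant under a primer's 3′ end can silence one allele (allele
dropout). If each internal primer site lies inside the neighboring
amplicon — which, being in another tube, is amplified without that primer —
the site is still sequenced and the dropout is detectable. This is why the
tube count must be at least 2, why adjacent products must overlap, and why
products two apart (and any two products sharing a tube) must be disjoint.

Within a tube, all primers must be pairwise compatible: no two may form a
cross-dimer with ΔG below the threshold. Each tube is therefore a clique in
the compatibility graph over primers, which makes the exact problem
NP-complete; the search is a depth-first heuristic that returns the first
feasible tiling rather than an optimal one. All constraint thresholds are
checked identically by a standalone verifier (`verify.py`) that shares no
code with the search.

## Thermodynamics

All oligo physics uses the unified SantaLucia (1998) DNA/DNA
nearest-neighbor table, shipped as `data/santalucia1998.tsv` so independent
oracles can read the same numbers.

* **Tm** (°C): ΔH°/(ΔS° + R ln(C_T/x)) − 273.15, with terminal-pair
  initiation terms, the entropy salt correction ΔS° += 0.368·N·ln[Na⁺]
  (N = stack count) and the von Ahsen monovalent-equivalent conversion for
  Mg²⁺. Defaults: 50 mM monovalent salt, no divalents, 50 nM total strand
  concentration, x = 4 (x = 1 plus the symmetry correction for
  self-complementary oligos). Matches Biopython's `Tm_NN` with the
  equivalent settings to < 0.01 °C (asserted in the tests).
* **Duplex ΔG** (kcal/mol, at 37 °C by default): the most stable ungapped
  antiparallel alignment between two oligos. Every maximal run of ≥ 4
  consecutive Watson–Crick pairs over all offsets is scored as its NN stacks
  plus both terminal initiation terms; no bulges, internal loops, mismatch
  or dangling-end corrections. 0.0 when no qualifying run exists; symmetric
  in its arguments; the homodimer is the self case. No salt correction is
  applied to ΔG (the table's 1 M reference state); the acceptance threshold
  is interpreted at the same state, so the comparison is consistent.
* **Hairpin ΔG**: best single stem of ≥ 3 pairs enclosing a loop of ≥ 3
  unpaired bases; stem scored by its NN stacks plus a fixed loop penalty
  (+3.5 kcal/mol, configurable). Never positive, since the unfolded state
  is always available.

These are deliberately the simplest models admitting an exact brute-force
oracle (exhaustive enumeration of alignments and stem-loops), which the test
suite runs against 500 random oligomers at 10⁻⁶ kcal/mol.

**Threshold reading.** The screening rule is stated in the field as dimer
and hairpin ΔG "less than −3 kcal" being unacceptable; this package rejects
a candidate or pair exactly when ΔG < −3.0 kcal/mol and accepts at −3.0.
The evaluation temperature is 37 °C by default and configurable, since
screening practice varies between 37 °C and the annealing temperature.

## Filters and their boundaries

Per primer: length 23–30 nt; GC ∈ [0.30, 0.70] with both endpoints passing
("not more than 70% or less than 30%" admits the endpoints); homopolymers
capped at 3; |Tm − optimum| ≤ 0.5 °C (closed interval); hairpin and
homodimer ΔG ≥ −3.0; no variant under the 3′-terminal 3 template bases,
applied on template coordinates for both strands because the destabilizing
mismatch is positional on the template. Per pair: product length ∈
[300, 500] (closed), |ΔTm| ≤ 0.5 °C, heterodimer ΔG ≥ −3.0.

Specificity uses a pluggable backend: an exact-match index (counts
occurrences of the oligo and its reverse complement in a reference string;
used in tests and fully offline) or `blastn -task blastn-short` against a
local database, counting alignments with E < 0.01. A candidate is kept with
at most one hit — the hit count is assumed to include the candidate's own
locus, so "more than one" kills it.

## Search

Candidates are enumerated exhaustively over the region on both strands in
canonical (start, length) order, then re-ordered by one of four strategies
(`bothNormal`, `fwdReverse`, `revReverse`, `bothReverse`: each role
ascending or descending by base location, stable over the canonical order).
The depth-first search extends the chain one pair at a time: forward
candidates are filtered by the positional window (inside the previous
product, past the product two back, past the last product of its own tube;
the first forward must start within the first `flank_len` bases), reverse
candidates by amplicon bounds and strict end progress; per-tube
compatibility is maintained incrementally (newcomer vs. current members),
with duplex ΔG values memoized per sequence pair. The first state whose
reverse primer ends within the final `flank_len` bases is returned. Index
bookkeeping: product index n is global and 0-based, tube = n mod m, and the
boundary-window length is a separate parameter — the only reading under
which all positional rules are simultaneously satisfiable for round-robin
tubes. The within-tube rule is enforced with strict inequality so a primer
region is never duplicated in one tube, and strict end progress holds for
every tube count.

The search is completely deterministic: no randomness anywhere, ties broken
by the canonical order. The only nondeterminism in outcomes is the
wall-clock time limit, checked against a monotonic clock at every node
expansion; on timeout the partial state is discarded and only
status/duration are reported. A zero budget times out immediately.
Compatibility between the two primers of one pair is enforced as part of
pair validity (they share a tube, so the clique condition implies it).
Exhausting the space returns `infeasible`, with the diagnostic
distinguishing "no candidates at all" from "no first-window forward" from
"no compatible tiling". One invocation runs exactly one ordering strategy;
callers wanting restarts loop over strategies themselves.

## Synthetic fixtures

The generator emulates the intended inputs — a 1–2 kb stretch with flanks,
GC-controlled background, optional point variants — while making
solvability a construction-time guarantee rather than a hope:

* A chain of k products (default 3) is laid out with forward starts every
  250 bases and product length 340, so adjacent products overlap by 90 and
  products two apart are disjoint. These two numbers are chosen so that in
  the 3-product layout *no* unintended combination of planted sites (or
  their opposite-strand twins, which pass the strand-symmetric filters too)
  yields an amplicon within [300, 500]: the pairing graph contains exactly
  the planted pairs.
* Planted primers are rejection-sampled 23-mers: template windows capped
  AAA (forward) / TTT (reverse) so both primers read 5′-AAA…AAA-3′, with
  Tm within ±0.2 °C of the fixture optimum (56 °C by default — reachable
  with moderately GC-rich interiors that are not intrinsically dimer-prone),
  GC within [0.35, 0.65], structures and *all* mutual cross-dimers above
  −2.9 kcal/mol. Any subset of planted primers is therefore
  tube-compatible, and planted pairs always pass the pair rules.
* `poison_mode` fills the background with the neighboring caps' bases
  (poly-A/poly-T): every candidate window crossing a planted-site boundary
  then contains a homopolymer ≥ 4, and all-background windows have GC = 0,
  so the planted sites are provably the only candidates and the default
  layout has exactly one feasible tiling.
* `n_decoys` plants alternative forward sites 26 bases left of planted
  forwards (the offset keeps all unintended pairings outside the amplicon
  band), each doubling the tiling count in the 3-product layout; the layout
  keeps decoys out of the first search window, where they could otherwise
  seed shorter chains.
* `first_forward_pos` pins the first planted forward. Setting it beyond the
  search's first window yields guaranteed-infeasible fixtures; setting it
  between 120 and 240 builds the family on which only the long initial
  window succeeds.

`brute_force_tilings` enumerates every feasible tiling by exhaustive
recursion, restating all rules independently of the search (thermodynamic
quantities recomputed from sequences); it refuses fixtures with more than
200 candidates. It is the oracle for the search's completeness, uniqueness
and ordering-effect properties.

What the fixtures do **not** emulate: real exon/intron structure, repeat
families and low-complexity tracts of real genomes, dbSNP-like allele
frequencies, or a genome-scale off-target landscape. Passing tests
therefore demonstrate the algorithm's correctness (soundness, completeness
at small scale, determinism, qualitative factor effects), not wet-lab
primer performance or success rates on any particular genome.

## Benchmark harness

`paper_grid` builds the 48-cell factorial layout — batches Short240 (short
initial window, short limit), Short480 (short window, long limit), Long240
(long window, short limit), crossed with the four orderings and tube counts
2–5 — and `run_benchmark` records status, time-to-first-solution and pair
count per region and cell, with success compared between groups by
two-sided Fisher's exact test (sidedness is a package choice; `scipy`
provides the test). Candidate enumeration is shared across cells because no
grid factor affects the filters. Time limits are parameters, not constants:
wall-clock behaviour is hardware-dependent, so the desk-scale defaults in
tests and the acceptance script use budgets of seconds with regions of
~1 kb and 3-product chains — sizes chosen so the full grid, the 50-fixture
soundness sweep and the 20-fixture completeness sweep all run in well under
a minute each on one core. Success rates on such engineered families are
by design 0 or 1 per batch; the harness exists to reproduce the qualitative
findings (the initial-window length decides feasibility, extra time does
not; two tubes never beat three), not any specific published percentages,
which depend on a particular exon panel, variant snapshot, BLAST database
and hardware.

## Known limitations

* Dimer/hairpin models are ungapped and single-stem; no partition function,
  bulges, coaxial stacking, or mismatch/dangling NN corrections (a config
  hook for alternative NN tables exists, but only one table ships).
* Primer–product and product–product interactions are not modeled; the
  compatibility graph is over primers only.
* The search returns the first feasible tiling, not a minimum-pair or
  maximum-robustness one.
* Variants are point positions; alleles and frequencies are ignored, and
  the caller decides which variants matter enough to supply.
* The BLAST backend shells out per query; for large candidate sets an
  offline index or a pre-screened store is the practical choice.
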