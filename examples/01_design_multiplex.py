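"""Design a multiplex tiling for a synthetic target region.

Builds a ~950 bp region with a planted chain of three overlapping amplicons,
runs the depth-first tiling search with two reaction tubes, and prints the
resulting primers.  Every primer within one tube is pairwise
dimer-compatible, and each internal primer site is covered by the
neighboring amplicon from the other tube (the allele-dropout guard).
"""

from mpxdesign import design_multiplex
from mpxdesign.fixtures import FixtureSpec, generate_fixture

fixture = generate_fixture(FixtureSpec(seed=42, poison_mode=True))
cfg = fixture.config(m_tubes=2, time_limit_s=60.0)
solution = design_multiplex(fixture.region, cfg)

print(f"region: {fixture.region.name} ({fixture.region.length} bp)")
print(f"status: {solution.status}   pairs: {solution.n_pairs}   "
      f"elapsed: {solution.elapsed_s:.3f} s")
for pair in solution.pairs:
    print(f"\nproduct {pair.product_index} -> tube {pair.tube}  "
          f"amplicon [{pair.amplicon_start}, {pair.amplicon_end}) "
          f"({pair.amplicon_length} bp)")
    for role, p in (("fwd", pair.forward), ("rev", pair.reverse)):
        print(f"  {role} {p.start:>5}-{p.end:<5} {p.sequence}  "
              f"Tm={p.tm_C:.2f}C GC={p.gc:.2f}")
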