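"""The oligo-level physics behind every design filter.

Computes GC fraction, homopolymer run, nearest-neighbor melting temperature
and secondary-structure free energies for a primer, then the cross-dimer ΔG
for a primer pair.  ΔG below -3 kcal/mol means a structure stable enough to
inhibit PCR, so the design filters reject it.
"""

from mpxdesign import (
    duplex_dG,
    gc_fraction,
    hairpin_dG,
    max_homopolymer_run,
    melting_temperature,
    reverse_complement,
)

primer = "AGCGTAGCTAGCTAGCTAGCTAG"
print(f"primer            {primer}")
print(f"GC fraction       {gc_fraction(primer):.3f}")
print(f"longest run       {max_homopolymer_run(primer)}")
print(f"Tm                {melting_temperature(primer):.2f} C")
print(f"hairpin dG        {hairpin_dG(primer):.2f} kcal/mol")
print(f"homodimer dG      {duplex_dG(primer, primer):.2f} kcal/mol")

partner = "TTGGCATCGATCGGCTAGCTAAGC"
worst = reverse_complement(primer)
print(f"\nheterodimer vs {partner}: {duplex_dG(primer, partner):.2f} kcal/mol")
print(f"heterodimer vs its own reverse complement: "
      f"{duplex_dG(primer, worst):.2f} kcal/mol  (a full duplex: rejected)")
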