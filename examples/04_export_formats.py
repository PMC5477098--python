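"""Export a solved design: BED amplicon track and primer TSV table.

The BED file is 0-based half-open with the tube index in the score column;
the TSV is the human-facing report with 1-based inclusive coordinates.
"""

import tempfile
from pathlib import Path

from mpxdesign import DesignReport, design_multiplex, write_amplicon_bed, write_primer_tsv
from mpxdesign.fixtures import FixtureSpec, generate_fixture, write_fixture

fixture = generate_fixture(FixtureSpec(seed=42, poison_mode=True))
cfg = fixture.config(time_limit_s=60.0)
solution = design_multiplex(fixture.region, cfg)

out = Path(tempfile.mkdtemp())
write_fixture(fixture, out / "region.fa")
write_amplicon_bed(solution, fixture.region.name, out / "amplicons.bed")
write_primer_tsv(DesignReport(fixture.region.name, solution, cfg),
                 out / "primers.tsv")

print(f"wrote {out}/region.fa, amplicons.bed, primers.tsv\n")
print("amplicons.bed:")
print((out / "amplicons.bed").read_text())
print("primers.tsv (first lines):")
for line in (out / "primers.tsv").read_text().splitlines()[:4]:
    print(line)
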