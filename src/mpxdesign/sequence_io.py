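"""Target-region input/output and coordinate conventions.

Coordinates are 0-based, half-open everywhere inside the package; BED files
keep that convention; only the human-readable primer TSV report (see
:mod:`mpxdesign.reporting`) converts to 1-based inclusive.

Variant positions are point positions on the target: a BED interval of width
w contributes each of its w covered positions.  Variant alleles/types are
ignored — the design rule is purely positional (no known variant under a
primer's 3'-terminal bases).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .thermo import _VALID_BASES

__all__ = ["TargetRegion", "read_target_region", "write_target_region"]


@dataclass(frozen=True)
class TargetRegion:
    """A continuous DNA target with flanking windows and known variants.

    ``flank_len`` is the boundary-window length: the first forward primer must
    start within the first ``flank_len`` bases and the last reverse primer
    must end within the last ``flank_len`` bases of the sequence.
    """

    name: str
    sequence: str
    flank_len: int
    variant_positions: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        for pos, base in enumerate(seq):
            if base not in _VALID_BASES:
                raise ValueError(
                    f"non-ACGT character {base!r} at position {pos} in "
                    f"record {self.name!r} (ambiguity codes are rejected)"
                )
        if self.flank_len <= 0:
            raise ValueError("flank_len must be positive")
        if 2 * self.flank_len >= len(seq):
            raise ValueError(
                f"flank_len={self.flank_len} too large: the invariant "
                f"2*flank_len < length requires length > {2 * self.flank_len}, "
                f"got {len(seq)}"
            )
        object.__setattr__(
            self, "variant_positions", frozenset(int(p) for p in self.variant_positions)
        )
        for p in self.variant_positions:
            if not 0 <= p < len(seq):
                raise ValueError(
                    f"variant position {p} outside sequence [0, {len(seq)})"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_bed_positions(bed_path, seq_len: int) -> frozenset:
    positions: set = set()
    with _open_text(bed_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"BED line {lineno}: expected at least 3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            start, end = int(fields[1]), int(fields[2])
            if start < 0 or end > seq_len or start >= end:
                raise ValueError(
                    f"BED line {lineno}: interval [{start}, {end}) outside "
                    f"sequence [0, {seq_len}) or empty"
                )
            positions.update(range(start, end))
    return frozenset(positions)


def read_target_region(fasta_path, flank_len: int, variant_bed_path=None) -> TargetRegion:
    """Read a single-record FASTA (plus optional variant BED) into a region.

    The FASTA must contain exactly one record; lowercase is uppercased; the
    BED uses 0-based half-open intervals, each contributing every covered
    position as a point variant.
    """
    with _open_text(fasta_path) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"expected exactly one FASTA record in {fasta_path}, found "
            f"{len(records)}"
        )
    record = records[0]
    sequence = str(record.seq).upper()
    variants: frozenset = frozenset()
    if variant_bed_path is not None:
        variants = _parse_bed_positions(variant_bed_path, len(sequence))
    return TargetRegion(
        name=record.id,
        sequence=sequence,
        flank_len=flank_len,
        variant_positions=variants,
    )


def write_target_region(region: TargetRegion, fasta_path, variant_bed_path=None) -> None:
    """Write a region back to FASTA (and its variants to BED, if requested)."""
    record = SeqRecord(Seq(region.sequence), id=region.name, description="")
    with open(fasta_path, "w") as handle:
        SeqIO.write([record], handle, "fasta")
    if variant_bed_path is not None:
        with open(variant_bed_path, "w") as handle:
            for pos in sorted(region.variant_positions):
                handle.write(f"{region.name}\t{pos}\t{pos + 1}\n")
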