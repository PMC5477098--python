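"""Serialization of solved designs: BED amplicon tracks and primer TSV tables.

BED output stays 0-based half-open; because BED has no notion of a reaction
tube, the score column carries the (0-based) tube index — a documented
convention of this package.  The primer TSV is the one human-facing report
and therefore uses 1-based inclusive coordinates; it is written byte-for-byte
deterministically for a fixed solution (UTF-8, LF, floats to 2 decimals).
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import DesignConfig
from .search import SOLVED, TilingSolution

__all__ = ["DesignReport", "write_amplicon_bed", "write_primer_tsv", "TSV_COLUMNS"]

TSV_COLUMNS = (
    "region",
    "product_index",
    "tube",
    "role",
    "start_1based",
    "end_1based",
    "length",
    "sequence",
    "tm_C",
    "gc_percent",
    "hairpin_dG",
    "homodimer_dG",
)


def _require_solved(solution: TilingSolution) -> None:
    if solution.status != SOLVED:
        raise ValueError(
            f"cannot report a solution with status {solution.status!r}; "
            f"only solved designs are serialized"
        )


@dataclass(frozen=True)
class DesignReport:
    """Per-primer rows for a solved design, plus the configuration echo."""

    region_name: str
    solution: TilingSolution
    config: DesignConfig

    def __post_init__(self) -> None:
        _require_solved(self.solution)

    @property
    def rows(self) -> list[dict]:
        rows = []
        for pair in self.solution.pairs:
            for role, primer in (("forward", pair.forward), ("reverse", pair.reverse)):
                rows.append(
                    {
                        "region": self.region_name,
                        "product_index": pair.product_index,
                        "tube": pair.tube,
                        "role": role,
                        "start_1based": primer.start + 1,
                        "end_1based": primer.end,
                        "length": primer.length,
                        "sequence": primer.sequence,
                        "tm_C": primer.tm_C,
                        "gc_percent": 100.0 * primer.gc,
                        "hairpin_dG": primer.hairpin_dG,
                        "homodimer_dG": primer.homodimer_dG,
                    }
                )
        return rows


def write_amplicon_bed(solution: TilingSolution, region_name: str, path) -> None:
    """One BED6 line per amplicon: name ``p<index>``, score = tube index."""
    _require_solved(solution)
    with open(path, "w", newline="\n") as handle:
        for pair in solution.pairs:
            handle.write(
                f"{region_name}\t{pair.amplicon_start}\t{pair.amplicon_end}"
                f"\tp{pair.product_index}\t{pair.tube}\t+\n"
            )


def write_primer_tsv(report: DesignReport, path) -> None:
    """Header plus one row per primer, deterministic byte-for-byte."""
    with open(path, "w", newline="\n") as handle:
        handle.write("\t".join(TSV_COLUMNS) + "\n")
        for row in report.rows:
            cells = []
            for col in TSV_COLUMNS:
                value = row[col]
                if isinstance(value, float):
                    cells.append(f"{value:.2f}")
                else:
                    cells.append(str(value))
            handle.write("\t".join(cells) + "\n")
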