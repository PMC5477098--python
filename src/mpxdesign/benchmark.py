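"""Benchmark harness: the factorial evaluation grid at desk scale.

Runs the designer over a set of regions for every cell of a factor grid —
initial-window length x time limit x candidate ordering x tube count — and
aggregates success rate, time to first solution, and pair counts.
``paper_grid`` builds the canonical 48-cell layout: three setting batches
(Short240: short window / short limit, Short480: short window / long limit,
Long240: long window / short limit) crossed with the four orderings and tube
counts 2–5.  Group differences in success are compared with a two-sided
Fisher's exact test.

Time limits are configuration, never hardcoded: wall-clock behaviour is
hardware-dependent, so desk-scale runs simply pass smaller budgets.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .candidates import FORWARD, REVERSE, SpecificityBackend, apply_specificity_filter, enumerate_candidates
from .config import ORDERINGS, DesignConfig
from .search import SOLVED, design_multiplex
from .sequence_io import TargetRegion

__all__ = [
    "BenchmarkCell",
    "BenchmarkRow",
    "BenchmarkResult",
    "paper_grid",
    "run_benchmark",
    "compare_success",
    "results_frame",
    "aggregate_frame",
]


@dataclass(frozen=True)
class BenchmarkCell:
    """One grid cell: a full factor combination, optionally batch-labelled."""

    flank_len: int
    time_limit_s: float
    ordering: str
    m_tubes: int
    batch: str = ""

    @property
    def label(self) -> str:
        batch = self.batch or f"flank{self.flank_len}_t{self.time_limit_s:g}"
        return f"{batch}/{self.ordering}/m{self.m_tubes}"


@dataclass(frozen=True)
class BenchmarkRow:
    region_id: str
    status: str
    elapsed_s: float
    n_pairs: int

    @property
    def solved(self) -> bool:
        return self.status == SOLVED


@dataclass(frozen=True)
class BenchmarkResult:
    cell: BenchmarkCell
    rows: tuple

    @property
    def success_rate(self) -> float:
        return sum(r.solved for r in self.rows) / len(self.rows)

    @property
    def median_elapsed(self) -> float:
        solved = [r.elapsed_s for r in self.rows if r.solved]
        return statistics.median(solved) if solved else float("nan")

    @property
    def median_pairs(self) -> float:
        solved = [r.n_pairs for r in self.rows if r.solved]
        return statistics.median(solved) if solved else float("nan")


def paper_grid(
    time_short: float = 240.0,
    time_long: float = 480.0,
    flank_short: int = 120,
    flank_long: int = 240,
    tube_counts: Sequence[int] = (2, 3, 4, 5),
    orderings: Sequence[str] = ORDERINGS,
) -> list[BenchmarkCell]:
    """The 48-cell factorial layout: 3 setting batches x orderings x tubes."""
    batches = (
        ("Short240", flank_short, time_short),
        ("Short480", flank_short, time_long),
        ("Long240", flank_long, time_short),
    )
    return [
        BenchmarkCell(flank, limit, ordering, m, batch)
        for ordering in orderings
        for batch, flank, limit in batches
        for m in tube_counts
    ]


def run_benchmark(
    regions: Sequence[TargetRegion],
    cells: Sequence[BenchmarkCell],
    cfg_base: DesignConfig | None = None,
    backend: SpecificityBackend | None = None,
) -> list[BenchmarkResult]:
    """Run the designer for every (region, cell) and collect per-row outcomes.

    Candidate enumeration depends only on the filter thresholds, which the
    grid factors never touch, so candidates are enumerated once per region
    and shared across cells; statuses are deterministic for fixed inputs and
    generous budgets.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    if cfg_base is None:
        cfg_base = DesignConfig()
    cache = {}
    for region in regions:
        forwards = enumerate_candidates(region, 0, region.length, FORWARD, cfg_base)
        reverses = enumerate_candidates(region, 0, region.length, REVERSE, cfg_base)
        if backend is not None:
            forwards = apply_specificity_filter(forwards, backend)
            reverses = apply_specificity_filter(reverses, backend)
        cache[region.name] = (forwards, reverses)
    results = []
    for cell in cells:
        cfg = replace(
            cfg_base,
            flank_len=cell.flank_len,
            time_limit_s=cell.time_limit_s,
            ordering=cell.ordering,
            m_tubes=cell.m_tubes,
        )
        rows = []
        for region in regions:
            solution = design_multiplex(
                region, cfg, candidates=cache[region.name]
            )
            rows.append(
                BenchmarkRow(
                    region_id=region.name,
                    status=solution.status,
                    elapsed_s=solution.elapsed_s,
                    n_pairs=solution.n_pairs,
                )
            )
        results.append(BenchmarkResult(cell=cell, rows=tuple(rows)))
    return results


def compare_success(
    group_a: Iterable[BenchmarkRow], group_b: Iterable[BenchmarkRow]
) -> float:
    """Two-sided Fisher's exact p-value on the 2x2 solved/unsolved table."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    table = [
        [sum(r.solved for r in group_a), sum(not r.solved for r in group_a)],
        [sum(r.solved for r in group_b), sum(not r.solved for r in group_b)],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def results_frame(results: Sequence[BenchmarkResult]) -> pd.DataFrame:
    """One row per region x cell."""
    records = [
        {
            "batch": res.cell.batch,
            "flank_len": res.cell.flank_len,
            "time_limit_s": res.cell.time_limit_s,
            "ordering": res.cell.ordering,
            "m_tubes": res.cell.m_tubes,
            "region_id": row.region_id,
            "status": row.status,
            "elapsed_s": row.elapsed_s,
            "n_pairs": row.n_pairs,
        }
        for res in results
        for row in res.rows
    ]
    return pd.DataFrame.from_records(records)


def aggregate_frame(results: Sequence[BenchmarkResult]) -> pd.DataFrame:
    """One row per cell with the aggregate statistics."""
    records = [
        {
            "batch": res.cell.batch,
            "flank_len": res.cell.flank_len,
            "time_limit_s": res.cell.time_limit_s,
            "ordering": res.cell.ordering,
            "m_tubes": res.cell.m_tubes,
            "n_regions": len(res.rows),
            "success_rate": res.success_rate,
            "median_elapsed_s": res.median_elapsed,
            "median_pairs": res.median_pairs,
        }
        for res in results
    ]
    return pd.DataFrame.from_records(records)
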