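"""Depth-first multiplex tiling search — the core of the package.

The target is tiled left to right with overlapping amplicons.  Product
``n`` (0-based) goes to tube ``n mod m``; within a state the next forward
primer must start inside the previous product (so its binding site is covered
by a neighboring amplicon from another tube), past the product two back
(products two apart share no base), and past the last product of its own
tube; reverse primer ends increase strictly.  All primers placed in one tube
must be pairwise dimer-compatible — the tubes are cliques in the primer
compatibility graph.  The search is depth-first, deterministic for a fixed
configuration, returns the first feasible solution, and aborts with status
``timeout`` when the wall-clock budget is exhausted.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from .candidates import (
    FORWARD,
    REVERSE,
    PrimerCandidate,
    SpecificityBackend,
    apply_specificity_filter,
    enumerate_candidates,
)
from .config import ORDERINGS, DesignConfig
from .sequence_io import TargetRegion
from . import thermo

__all__ = [
    "PrimerPair",
    "TilingSolution",
    "SOLVED",
    "TIMEOUT",
    "INFEASIBLE",
    "order_candidates",
    "pair_is_valid",
    "tube_compatible",
    "design_multiplex",
]

SOLVED = "solved"
TIMEOUT = "timeout"
INFEASIBLE = "infeasible"


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse candidate pair defining one amplicon."""

    forward: PrimerCandidate
    reverse: PrimerCandidate
    product_index: int
    m_tubes: int

    @property
    def tube(self) -> int:
        return self.product_index % self.m_tubes

    @property
    def amplicon_start(self) -> int:
        return self.forward.start

    @property
    def amplicon_end(self) -> int:
        return self.reverse.end

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_end - self.amplicon_start

    def coordinates(self) -> tuple:
        """Hashable identity used to compare solutions across runs."""
        return (
            self.forward.start, self.forward.end,
            self.reverse.start, self.reverse.end,
        )


@dataclass(frozen=True)
class TilingSolution:
    """Outcome of one search: the ordered pairs, grouped by tube on demand."""

    pairs: tuple
    status: str
    elapsed_s: float
    message: str = ""

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def tubes(self) -> dict:
        grouped: dict = {}
        for pair in self.pairs:
            grouped.setdefault(pair.tube, []).append(pair)
        return grouped

    def coordinates(self) -> tuple:
        return tuple(pair.coordinates() for pair in self.pairs)


def order_candidates(
    candidates: list[PrimerCandidate], role: str, strategy: str
) -> list[PrimerCandidate]:
    """Order candidates by base location according to a named strategy.

    "Normal" order is ascending base location (forward primers keyed by
    start, reverse primers by end); "reverse" order is descending.  The sort
    is stable with respect to the canonical (start, length) input order.
    """
    if strategy not in ORDERINGS:
        raise ValueError(
            f"unknown ordering {strategy!r}; valid orderings: {', '.join(ORDERINGS)}"
        )
    descending = {
        "bothNormal": {"forward": False, "reverse": False},
        "fwdReverse": {"forward": True, "reverse": False},
        "revReverse": {"forward": False, "reverse": True},
        "bothReverse": {"forward": True, "reverse": True},
    }[strategy]
    if role not in (FORWARD, REVERSE):
        raise ValueError(f"role must be {FORWARD!r} or {REVERSE!r}")
    return sorted(candidates, key=lambda c: c.position, reverse=descending[role])


def pair_is_valid(
    fwd: PrimerCandidate, rev: PrimerCandidate, cfg: DesignConfig
) -> bool:
    """Amplicon length in bounds, Tm difference within tolerance, no cross-dimer."""
    length = rev.end - fwd.start
    if not cfg.amplicon_min <= length <= cfg.amplicon_max:
        return False
    if abs(fwd.tm_C - rev.tm_C) > cfg.tm_pair_tolerance_C:
        return False
    return thermo.duplex_dG(fwd.sequence, rev.sequence, cfg.thermo) >= cfg.dG_threshold


def tube_compatible(
    candidate: PrimerCandidate,
    tube_members: list[PrimerCandidate],
    cfg: DesignConfig,
) -> bool:
    """True iff the candidate cross-dimers with no current tube member.

    Incremental clique maintenance: members were pairwise compatible when
    admitted, so checking the newcomer against each of them preserves the
    complete-graph condition.
    """
    return all(
        thermo.duplex_dG(candidate.sequence, member.sequence, cfg.thermo)
        >= cfg.dG_threshold
        for member in tube_members
    )


class _Timeout(Exception):
    pass


class _Searcher:
    def __init__(self, region, cfg, forwards, reverses):
        self.region = region
        self.cfg = cfg
        self.forwards = forwards
        self.reverses = reverses
        self.t0 = time.monotonic()
        self._dimer_cache: dict = {}

    def elapsed(self) -> float:
        return time.monotonic() - self.t0

    def _check_time(self) -> None:
        if self.elapsed() > self.cfg.time_limit_s:
            raise _Timeout

    def _dimer(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        g = self._dimer_cache.get(key)
        if g is None:
            g = thermo.duplex_dG(a, b, self.cfg.thermo)
            self._dimer_cache[key] = g
        return g

    def _compatible(self, cand: PrimerCandidate, members: list) -> bool:
        return all(
            self._dimer(cand.sequence, m.sequence) >= self.cfg.dG_threshold
            for m in members
        )

    def search(self) -> tuple | None:
        self._check_time()
        return self._extend([])

    def _extend(self, pairs: list) -> tuple | None:
        cfg = self.cfg
        i = len(pairs)
        tube = i % cfg.m_tubes
        members = [
            p
            for j, pair in enumerate(pairs)
            if j % cfg.m_tubes == tube
            for p in (pair.forward, pair.reverse)
        ]
        if i == 0:
            fwd_lo, fwd_hi = -1, cfg.flank_len  # start < flank_len
        else:
            fwd_hi = pairs[-1].reverse.end  # overlap the previous product
            fwd_lo = -1
            if i >= 2:
                fwd_lo = max(fwd_lo, pairs[-2].reverse.end)
            if i >= cfg.m_tubes:
                fwd_lo = max(fwd_lo, pairs[i - cfg.m_tubes].reverse.end)
        prev_end = pairs[-1].reverse.end if pairs else -1
        final_cut = self.region.length - cfg.flank_len
        for fwd in self.forwards:
            self._check_time()
            if not fwd_lo < fwd.start < fwd_hi:
                continue
            if not self._compatible(fwd, members):
                continue
            rev_lo = fwd.start + cfg.amplicon_min
            rev_hi = fwd.start + cfg.amplicon_max
            for rev in self.reverses:
                if rev.end < rev_lo or rev.end > rev_hi or rev.end <= prev_end:
                    continue
                if abs(fwd.tm_C - rev.tm_C) > cfg.tm_pair_tolerance_C:
                    continue
                if self._dimer(fwd.sequence, rev.sequence) < cfg.dG_threshold:
                    continue
                if not self._compatible(rev, members):
                    continue
                pair = PrimerPair(fwd, rev, i, cfg.m_tubes)
                if rev.end > final_cut:
                    return tuple(pairs + [pair])  # first feasible solution
                result = self._extend(pairs + [pair])
                if result is not None:
                    return result
        return None


def design_multiplex(
    region: TargetRegion,
    cfg: DesignConfig,
    backend: SpecificityBackend | None = None,
    candidates: tuple | None = None,
) -> TilingSolution:
    """Run the time-limited depth-first tiling search on a target region.

    Candidate primers are enumerated over the whole region on both strands
    (optionally screened for specificity through ``backend``), put in the
    order prescribed by ``cfg.ordering``, and extended pair by pair under the
    positional, pairing and per-tube compatibility rules.  The first state
    whose last reverse primer ends within the final ``cfg.flank_len`` bases
    is returned as ``solved``; an exhausted search returns ``infeasible``;
    exceeding ``cfg.time_limit_s`` (checked at every node expansion) returns
    ``timeout`` with the partial state discarded.

    ``candidates`` may carry pre-enumerated ``(forwards, reverses)`` lists in
    canonical order (as produced by :func:`enumerate_candidates` over the
    whole region) to avoid re-enumeration across repeated runs on one region;
    they are ordered per ``cfg.ordering`` here either way.
    """
    t0 = time.monotonic()

    def result(status: str, pairs=(), message: str = "") -> TilingSolution:
        return TilingSolution(
            pairs=tuple(pairs),
            status=status,
            elapsed_s=time.monotonic() - t0,
            message=message,
        )

    if cfg.time_limit_s <= 0 or time.monotonic() - t0 > cfg.time_limit_s:
        return result(TIMEOUT, message="time limit exhausted before search")
    if candidates is None:
        forwards = enumerate_candidates(region, 0, region.length, FORWARD, cfg)
        reverses = enumerate_candidates(region, 0, region.length, REVERSE, cfg)
        if backend is not None:
            forwards = apply_specificity_filter(forwards, backend)
            reverses = apply_specificity_filter(reverses, backend)
    else:
        forwards, reverses = candidates
    if not forwards and not reverses:
        return result(INFEASIBLE, message="no primer candidates in the region")
    if not any(f.start < cfg.flank_len for f in forwards):
        return result(
            INFEASIBLE,
            message=f"no forward candidate starts in the first window "
                    f"[0, {cfg.flank_len})",
        )
    searcher = _Searcher(
        region,
        cfg,
        order_candidates(forwards, FORWARD, cfg.ordering),
        order_candidates(reverses, REVERSE, cfg.ordering),
    )
    searcher.t0 = t0
    try:
        pairs = searcher.search()
    except _Timeout:
        return result(TIMEOUT, message="time limit exceeded during search")
    if pairs is None:
        return result(
            INFEASIBLE,
            message="candidate space exhausted: no compatible tiling",
        )
    return result(SOLVED, pairs=pairs)
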