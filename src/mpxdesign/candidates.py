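"""Primer-candidate enumeration and filtering.

A candidate is any oligo of 23–30 bases lying fully inside the target that
survives every per-primer filter: GC fraction in [0.30, 0.70] (inclusive),
no homopolymer of 4+ bases, melting temperature within 0.5 °C of the
configured optimum, hairpin and homodimer ΔG not below −3 kcal/mol, and no
known variant on the template under the oligo's 3'-terminal 3 bases (the
allele-dropout guard).  An optional specificity backend then discards
candidates with more than one hit in a reference (the candidate's own locus
counts as the one allowed hit).
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

from .config import DesignConfig
from .sequence_io import TargetRegion
from . import thermo
from .thermo import reverse_complement

__all__ = [
    "PrimerCandidate",
    "SpecificityBackend",
    "ExactMatchIndex",
    "BlastBackend",
    "evaluate_primer",
    "primer_ok",
    "enumerate_candidates",
    "apply_specificity_filter",
]

logger = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class PrimerCandidate:
    """An oriented oligo on the target with cached screening metrics.

    ``start``/``end`` are 0-based half-open template coordinates of the
    binding site; ``sequence`` is the primer 5'→3' (reverse-complemented
    relative to the template for reverse-strand candidates).
    """

    start: int
    end: int
    strand: str
    sequence: str
    tm_C: float
    gc: float
    hairpin_dG: float
    homodimer_dG: float
    specificity_checked: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def position(self) -> int:
        """Base location used for ordering: start (forward) or end (reverse)."""
        return self.start if self.strand == FORWARD else self.end

    def three_prime_template_positions(self, k: int = 3) -> range:
        """Template positions under the oligo's 3'-terminal ``k`` bases."""
        if self.strand == FORWARD:
            return range(self.end - k, self.end)
        return range(self.start, self.start + k)


def evaluate_primer(seq: str, cfg: DesignConfig):
    """Apply the sequence-level filters; return metrics or None on rejection.

    Checks, cheapest first: length, GC bounds (inclusive), homopolymer, Tm
    band (|Tm − optimum| ≤ tolerance, inclusive), hairpin ΔG, homodimer ΔG
    (rejected when below ``cfg.dG_threshold``).  Positional checks (the
    3'-variant rule, window membership) live in :func:`enumerate_candidates`.
    """
    if not cfg.primer_len_min <= len(seq) <= cfg.primer_len_max:
        return None
    gc = thermo.gc_fraction(seq)
    if not cfg.gc_min <= gc <= cfg.gc_max:
        return None
    if thermo.max_homopolymer_run(seq) > cfg.max_homopolymer:
        return None
    tm = thermo.melting_temperature(seq, cfg.thermo)
    if abs(tm - cfg.optimum_tm_C) > cfg.primer_tm_tolerance_C:
        return None
    hp = thermo.hairpin_dG(seq, cfg.thermo)
    if hp < cfg.dG_threshold:
        return None
    hd = thermo.duplex_dG(seq, seq, cfg.thermo)
    if hd < cfg.dG_threshold:
        return None
    return tm, gc, hp, hd


def primer_ok(seq: str, cfg: DesignConfig) -> bool:
    """True iff ``seq`` passes every sequence-level primer filter."""
    return evaluate_primer(seq, cfg) is not None


def _variant_clash(region: TargetRegion, lo: int, hi: int) -> bool:
    return any(p in region.variant_positions for p in range(lo, hi))


def enumerate_candidates(
    region: TargetRegion,
    window_start: int,
    window_end: int,
    strand: str,
    cfg: DesignConfig,
) -> list[PrimerCandidate]:
    """All passing candidates whose anchor lies in the window, in canonical order.

    Forward candidates are constrained by their 5' start:
    ``window_start <= start < window_end``.  Reverse candidates are
    constrained by their 3'-most template coordinate, i.e. their (exclusive)
    end: ``window_start < end <= window_end``.  Output is sorted by
    ascending (start, length) and is a pure function of its arguments.
    """
    if strand not in (FORWARD, REVERSE):
        raise ValueError(f"strand must be {FORWARD!r} or {REVERSE!r}, got {strand!r}")
    if window_start >= window_end:
        return []
    if window_start < 0 or window_end > region.length:
        raise ValueError(
            f"window [{window_start}, {window_end}) outside region "
            f"[0, {region.length})"
        )
    k = cfg.variant_exclusion_len
    out: list[PrimerCandidate] = []
    if strand == FORWARD:
        for start in range(window_start, window_end):
            for length in range(cfg.primer_len_min, cfg.primer_len_max + 1):
                end = start + length
                if end > region.length:
                    break
                if _variant_clash(region, end - k, end):
                    continue
                metrics = evaluate_primer(region.sequence[start:end], cfg)
                if metrics is None:
                    continue
                tm, gc, hp, hd = metrics
                out.append(
                    PrimerCandidate(start, end, FORWARD, region.sequence[start:end],
                                    tm, gc, hp, hd)
                )
    else:
        for end in range(window_start + 1, window_end + 1):
            for length in range(cfg.primer_len_min, cfg.primer_len_max + 1):
                start = end - length
                if start < 0:
                    break
                if _variant_clash(region, start, start + k):
                    continue
                seq = reverse_complement(region.sequence[start:end])
                metrics = evaluate_primer(seq, cfg)
                if metrics is None:
                    continue
                tm, gc, hp, hd = metrics
                out.append(PrimerCandidate(start, end, REVERSE, seq, tm, gc, hp, hd))
        out.sort(key=lambda c: (c.start, c.length))
    return out


@runtime_checkable
class SpecificityBackend(Protocol):
    """Counts putative binding sites of an oligo in a reference."""

    def query(self, sequence: str) -> int:  # pragma: no cover - protocol
        ...


class ExactMatchIndex:
    """Offline specificity backend: exact-match counting in a reference string.

    A hit is any (overlapping) occurrence of the oligo or of its reverse
    complement in the reference sequence; the candidate's own locus therefore
    contributes exactly one hit.
    """

    def __init__(self, reference: str):
        self.reference = reference.upper()

    @staticmethod
    def _count(haystack: str, needle: str) -> int:
        count = 0
        pos = haystack.find(needle)
        while pos != -1:
            count += 1
            pos = haystack.find(needle, pos + 1)
        return count

    def query(self, sequence: str) -> int:
        seq = sequence.upper()
        hits = self._count(self.reference, seq)
        rc = reverse_complement(seq)
        hits += self._count(self.reference, rc)
        if seq == rc:  # palindrome: both scans saw the same sites
            hits //= 2
        return hits


class BlastBackend:
    """Specificity backend shelling out to blastn against a local database.

    A hit is one tabular (outfmt 6) alignment row with E-value < ``evalue``;
    short-query settings (``-task blastn-short``) are used, matching how
    primer-length queries are normally screened.
    """

    def __init__(self, db_path, evalue: float = 0.01, blastn: str = "blastn"):
        self.db_path = str(db_path)
        self.evalue = evalue
        self.blastn = blastn

    def query(self, sequence: str) -> int:
        with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
            fh.write(f">query\n{sequence}\n")
            query_path = fh.name
        try:
            proc = subprocess.run(
                [
                    self.blastn, "-task", "blastn-short", "-db", self.db_path,
                    "-query", query_path, "-outfmt", "6",
                ],
                capture_output=True, text=True, check=True,
            )
        finally:
            Path(query_path).unlink(missing_ok=True)
        hits = 0
        for line in proc.stdout.splitlines():
            fields = line.split("\t")
            if len(fields) >= 11 and float(fields[10]) < self.evalue:
                hits += 1
        return hits


def apply_specificity_filter(
    candidates: Iterable[PrimerCandidate],
    backend: SpecificityBackend | None,
    on_missing: str = "fail",
) -> list[PrimerCandidate]:
    """Retain candidates with at most one reference hit, preserving order.

    The single allowed hit is the candidate's own locus; any additional hit
    discards the candidate.  With ``backend=None`` the policy ``on_missing``
    applies: "fail" raises, "pass" returns the candidates unchanged with
    ``specificity_checked`` left False and a logged warning.
    """
    candidates = list(candidates)
    if backend is None:
        if on_missing == "pass":
            logger.warning(
                "no specificity backend configured; %d candidates pass "
                "through unchecked", len(candidates),
            )
            return candidates
        raise ValueError("no specificity backend available (policy: fail)")
    return [
        replace(c, specificity_checked=True)
        for c in candidates
        if backend.query(c.sequence) <= 1
    ]
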