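"""Synthetic test regions with controllable difficulty.

The generator emulates the kind of input the designer targets — a ~1.5–2 kb
stretch of genomic DNA with flanks — while guaranteeing, by construction,
how many feasible tilings exist:

* A chain of ``k`` planted products is laid out with fixed geometry
  (spacing :data:`SPACING`, product length :data:`PRODUCT_LEN`), chosen so
  that products overlap by 90 bases, products two apart are disjoint, and —
  crucially — no unintended (forward, reverse) combination yields an
  amplicon inside the 300–500 base window.  With the default three-product
  layout this makes the planted chain the *only* pairing graph, so a
  poisoned background yields exactly one feasible tiling.
* Planted primer sites are drawn by rejection sampling: 23-mers whose
  template windows are capped with ``AAA`` on both ends and that clear every
  per-primer filter with margin (Tm within ±0.2 °C of the optimum, secondary
  structures and all mutual cross-dimers above −2.5 kcal/mol), so any
  subset of the planted primers is tube-compatible.
* ``poison_mode`` fills the background with poly-A.  Together with the
  ``AAA`` window caps this provably kills every candidate other than the
  planted sites themselves: any window crossing a site boundary contains a
  homopolymer of four or more bases, and any all-background window is pure A.
* ``n_decoys`` plants alternative forward sites just left of planted
  forwards, multiplying the number of feasible tilings by 2 per decoy in
  the default three-product layout.
* ``first_forward_pos`` pins the first planted forward start — placing it
  beyond the search's first window makes the fixture infeasible for that
  flank length, which is how the flank-length benchmark families are built.

``brute_force_tilings`` exhaustively enumerates every feasible tiling on a
small fixture; it restates the positional and compatibility rules
independently of the search module and is the completeness oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .candidates import FORWARD, REVERSE, enumerate_candidates
from .config import DesignConfig
from .search import SOLVED, PrimerPair, TilingSolution
from .sequence_io import TargetRegion, write_target_region
from . import thermo

__all__ = [
    "FixtureSpec",
    "Fixture",
    "FixtureError",
    "generate_fixture",
    "generate_region",
    "write_fixture",
    "brute_force_tilings",
    "SPACING",
    "PRODUCT_LEN",
    "PLANTED_OLIGO_LEN",
]

SPACING = 250  # distance between consecutive planted forward starts
PRODUCT_LEN = 340  # planted amplicon length (products overlap by 90 bases)
PLANTED_OLIGO_LEN = 23
# Decoy forward sites sit this far left of a planted forward.  26 keeps every
# unintended pairing (decoy vs planted reverses, decoy vs strand-twins of
# planted sites) outside the 300-500 amplicon band in the 3-product layout:
# the closest miss is decoy vs the next forward's reverse twin at
# SPACING + 23 + 26 = 299 bases.
DECOY_OFFSET = 26
# Template-window caps.  Forward windows are capped AAA, reverse windows TTT,
# so every planted *primer* (5'->3') is AAA-capped: the caps cannot cross-pair
# between planted primers.  In poison mode the background adjacent to a window
# repeats the cap base, so any candidate window crossing a site boundary
# carries a homopolymer of four or more bases and is filtered out.
_CAPS = {FORWARD: "AAA", REVERSE: "TTT"}
_CAP_LEN = 3
_TM_MARGIN = 0.2  # < 0.25, so any planted pair differs by < 0.5 °C
_STRUCTURE_MARGIN = -2.9  # clear of the -3.0 acceptance threshold
_GC_MARGIN = (0.35, 0.65)


class FixtureError(RuntimeError):
    """The fixture specification admits no valid planted layout."""


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic region (fully determined by ``seed``)."""

    seed: int
    length: int | None = None
    gc_target: float = 0.5
    n_planted_windows: int = 6
    variant_density: float = 0.0
    poison_mode: bool = False
    n_decoys: int = 0
    first_forward_pos: int | None = None
    optimum_tm_C: float = 56.0
    flank_len: int = 240

    def __post_init__(self) -> None:
        if self.n_planted_windows < 2 or self.n_planted_windows % 2:
            raise ValueError("n_planted_windows must be an even count >= 2")
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must be in (0, 1)")
        if self.variant_density < 0:
            raise ValueError("variant_density must be >= 0")
        if self.n_decoys < 0 or self.n_decoys > self.n_products - 1:
            raise ValueError(
                f"n_decoys must be in [0, {self.n_products - 1}] for "
                f"{self.n_products} planted products"
            )

    @property
    def n_products(self) -> int:
        return self.n_planted_windows // 2


@dataclass(frozen=True)
class Fixture:
    """A generated region plus the planted layout (for tests and oracles)."""

    spec: FixtureSpec
    region: TargetRegion
    forward_starts: tuple
    reverse_ends: tuple
    decoy_starts: tuple

    def config(self, **overrides) -> DesignConfig:
        """A DesignConfig matching the fixture's planted conditions."""
        base = DesignConfig(
            optimum_tm_C=self.spec.optimum_tm_C, flank_len=self.spec.flank_len
        )
        return replace(base, **overrides) if overrides else base

    @property
    def planted_coordinates(self) -> tuple:
        """The (fwd_start, fwd_end, rev_start, rev_end) of each planted pair."""
        k = PLANTED_OLIGO_LEN
        return tuple(
            (f, f + k, e - k, e)
            for f, e in zip(self.forward_starts, self.reverse_ends)
        )


def _layout(spec: FixtureSpec, rng: np.random.Generator):
    # With decoys, the first decoy (product 1, offset -60) must sit outside
    # the first search window, otherwise it can seed extra, shorter tilings
    # and the "2 tilings per decoy" guarantee breaks.
    f0_min = 5
    if spec.n_decoys:
        f0_min = max(f0_min, spec.flank_len - SPACING + DECOY_OFFSET)
    f0 = (
        spec.first_forward_pos
        if spec.first_forward_pos is not None
        else int(rng.integers(f0_min, f0_min + 56))
    )
    if f0 < 0:
        raise FixtureError("first_forward_pos must be >= 0")
    if spec.n_decoys and f0 + SPACING - DECOY_OFFSET < spec.flank_len:
        raise FixtureError(
            f"first_forward_pos={f0} places a decoy inside the first "
            f"{spec.flank_len}-base window; use first_forward_pos >= {f0_min}"
        )
    k = spec.n_products
    forward_starts = tuple(f0 + SPACING * i for i in range(k))
    reverse_ends = tuple(s + PRODUCT_LEN for s in forward_starts)
    total = reverse_ends[-1]
    length = spec.length if spec.length is not None else total + 60
    if total > length:
        raise FixtureError(
            f"length {length} too short for {k} planted products ending at "
            f"{total}"
        )
    if total <= length - spec.flank_len:
        raise FixtureError(
            f"planted chain ends at {total}, outside the last "
            f"{spec.flank_len} bases of a length-{length} region"
        )
    if 2 * spec.flank_len >= length:
        raise FixtureError(
            f"length {length} violates 2*flank_len < length for "
            f"flank_len={spec.flank_len}"
        )
    decoy_starts = tuple(
        forward_starts[i] - DECOY_OFFSET for i in range(1, spec.n_decoys + 1)
    )
    return forward_starts, reverse_ends, decoy_starts, length


def _sample_window(
    rng: np.random.Generator,
    role: str,
    optimum_tm: float,
    existing: list[str],
    max_tries: int = 50_000,
) -> tuple[str, str]:
    """Rejection-sample one planted template window; return (window, primer)."""
    cap = _CAPS[role]
    interior_len = PLANTED_OLIGO_LEN - 2 * _CAP_LEN
    bases = np.array(list("ACGT"))
    # moderately GC-rich interior compensates the AT caps without making the
    # oligos intrinsically dimer-prone
    probs = np.array([0.175, 0.325, 0.325, 0.175])
    lo, hi = _GC_MARGIN
    for _ in range(max_tries):
        interior = "".join(rng.choice(bases, size=interior_len, p=probs))
        window = cap + interior + cap
        primer = window if role == FORWARD else thermo.reverse_complement(window)
        if not lo <= thermo.gc_fraction(primer) <= hi:
            continue
        if thermo.max_homopolymer_run(primer) > 3:
            continue
        if abs(thermo.melting_temperature(primer) - optimum_tm) > _TM_MARGIN:
            continue
        if thermo.hairpin_dG(primer) < _STRUCTURE_MARGIN:
            continue
        if thermo.duplex_dG(primer, primer) < _STRUCTURE_MARGIN:
            continue
        if any(
            thermo.duplex_dG(primer, other) < _STRUCTURE_MARGIN
            for other in existing
        ):
            continue
        return window, primer
    raise FixtureError(
        f"could not sample a planted {role} window near Tm="
        f"{optimum_tm:.1f} °C within {max_tries} tries"
    )


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build a seeded, reproducible fixture with its planted layout."""
    rng = np.random.default_rng(spec.seed)
    forward_starts, reverse_ends, decoy_starts, length = _layout(spec, rng)
    oligo = PLANTED_OLIGO_LEN

    windows: list[tuple[int, str, str]] = []  # (start, role, template window)
    primers: list[str] = []
    for start in forward_starts:
        window, primer = _sample_window(rng, FORWARD, spec.optimum_tm_C, primers)
        windows.append((start, FORWARD, window))
        primers.append(primer)
    for end in reverse_ends:
        window, primer = _sample_window(rng, REVERSE, spec.optimum_tm_C, primers)
        windows.append((end - oligo, REVERSE, window))
        primers.append(primer)
    for start in decoy_starts:
        window, primer = _sample_window(rng, FORWARD, spec.optimum_tm_C, primers)
        windows.append((start, FORWARD, window))
        primers.append(primer)

    occupied = sorted(
        (start, start + oligo, role) for start, role, _ in windows
    )
    for (s1, e1, _), (s2, e2, _) in zip(occupied, occupied[1:]):
        if s2 < e1:
            raise FixtureError(f"planted windows [{s1},{e1}) and [{s2},{e2}) overlap")

    if spec.poison_mode:
        # Background in each gap repeats the neighboring sites' cap bases
        # (left half extends the left site's cap, right half the right
        # site's), so every junction-crossing window carries a 4+ homopolymer
        # and every all-background window is A/T-only (GC = 0).
        seq = ["A"] * length
        cuts = [(0, None)] + [(e, role) for _, e, role in occupied]
        nexts = [(s, role) for s, _, role in occupied] + [(length, None)]
        for (gap_start, left_role), (gap_end, right_role) in zip(cuts, nexts):
            left_char = _CAPS[left_role or right_role or FORWARD][0]
            right_char = _CAPS[right_role or left_role or FORWARD][0]
            mid = (gap_start + gap_end) // 2
            seq[gap_start:mid] = left_char * (mid - gap_start)
            seq[mid:gap_end] = right_char * (gap_end - mid)
    else:
        bases = np.array(list("ACGT"))
        g = spec.gc_target / 2.0
        a = (1.0 - spec.gc_target) / 2.0
        seq = list(rng.choice(bases, size=length, p=[a, g, g, a]))
    for start, _, window in windows:
        seq[start : start + oligo] = list(window)

    variants: set[int] = set()
    n_variants = int(round(spec.variant_density * length / 1000.0))
    if n_variants:
        blocked = set()
        for start, _, _ in windows:
            blocked.update(range(start, start + oligo))
        free = np.array(sorted(set(range(length)) - blocked))
        if len(free) < n_variants:
            raise FixtureError("not enough background positions for variants")
        variants = set(int(p) for p in rng.choice(free, size=n_variants, replace=False))

    region = TargetRegion(
        name=f"fixture_seed{spec.seed}",
        sequence="".join(seq),
        flank_len=spec.flank_len,
        variant_positions=frozenset(variants),
    )

    # every planted window must survive the real filters as a candidate
    cfg = DesignConfig(optimum_tm_C=spec.optimum_tm_C, flank_len=spec.flank_len)
    for start, role, _ in windows:
        if role == FORWARD:
            found = enumerate_candidates(region, start, start + 1, FORWARD, cfg)
            hit = any(c.start == start and c.length == oligo for c in found)
        else:
            end = start + oligo
            found = enumerate_candidates(region, end - 1, end, REVERSE, cfg)
            hit = any(c.end == end and c.length == oligo for c in found)
        if not hit:
            raise FixtureError(
                f"planted {role} window at {start} yields no candidate "
                f"(fixture bug, not a search failure)"
            )

    return Fixture(
        spec=spec,
        region=region,
        forward_starts=forward_starts,
        reverse_ends=reverse_ends,
        decoy_starts=decoy_starts,
    )


def generate_region(spec: FixtureSpec) -> TargetRegion:
    """Seeded, reproducible region; see :func:`generate_fixture` for details."""
    return generate_fixture(spec).region


def write_fixture(fixture: Fixture, fasta_path, variant_bed_path=None) -> None:
    """Write the fixture as FASTA (+ optional variant BED) for CLI use."""
    write_target_region(fixture.region, fasta_path, variant_bed_path)


def brute_force_tilings(
    region: TargetRegion, cfg: DesignConfig, max_candidates: int = 200
) -> list[TilingSolution]:
    """Every feasible tiling, by exhaustive recursion over ordered pair chains.

    Restates the tiling rules independently of the search module (positions,
    amplicon bounds, pair Tm, per-tube pairwise ΔG) with Tm and ΔG recomputed
    straight from the thermodynamics module.  A chain is recorded as a
    solution at the first pair whose reverse ends within the final flank
    window, mirroring the search's stopping rule.  Intended for small
    fixtures only: refuses to run beyond ``max_candidates`` candidates.
    """
    forwards = enumerate_candidates(region, 0, region.length, FORWARD, cfg)
    reverses = enumerate_candidates(region, 0, region.length, REVERSE, cfg)
    total = len(forwards) + len(reverses)
    if total > max_candidates:
        raise ValueError(
            f"{total} candidates exceed the brute-force guard of "
            f"{max_candidates}; shrink the fixture"
        )
    tm = {
        c.sequence: thermo.melting_temperature(c.sequence, cfg.thermo)
        for c in forwards + reverses
    }
    dimers: dict = {}

    def dg(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in dimers:
            dimers[key] = thermo.duplex_dG(key[0], key[1], cfg.thermo)
        return dimers[key]

    final_cut = region.length - cfg.flank_len
    m = cfg.m_tubes
    solutions: list[TilingSolution] = []

    def recurse(chain: list[PrimerPair]) -> None:
        i = len(chain)
        tube = i % m
        members = [
            p
            for j, pair in enumerate(chain)
            if j % m == tube
            for p in (pair.forward, pair.reverse)
        ]
        if i == 0:
            lo, hi = -1, cfg.flank_len
        else:
            hi = chain[-1].reverse.end
            lo = -1
            if i >= 2:
                lo = max(lo, chain[-2].reverse.end)
            same_tube = [pair for j, pair in enumerate(chain) if j % m == tube]
            if same_tube:
                lo = max(lo, same_tube[-1].reverse.end)
        prev_end = chain[-1].reverse.end if chain else -1
        for f in forwards:
            if not lo < f.start < hi:
                continue
            if any(dg(f.sequence, p.sequence) < cfg.dG_threshold for p in members):
                continue
            for r in reverses:
                length = r.end - f.start
                if not cfg.amplicon_min <= length <= cfg.amplicon_max:
                    continue
                if r.end <= prev_end:
                    continue
                if abs(tm[f.sequence] - tm[r.sequence]) > cfg.tm_pair_tolerance_C:
                    continue
                if dg(f.sequence, r.sequence) < cfg.dG_threshold:
                    continue
                if any(
                    dg(r.sequence, p.sequence) < cfg.dG_threshold for p in members
                ):
                    continue
                pair = PrimerPair(f, r, i, m)
                if r.end > final_cut:
                    solutions.append(
                        TilingSolution(
                            pairs=tuple(chain + [pair]), status=SOLVED, elapsed_s=0.0
                        )
                    )
                else:
                    recurse(chain + [pair])

    recurse([])
    return solutions
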