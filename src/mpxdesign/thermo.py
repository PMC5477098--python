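"""Oligonucleotide thermodynamics.

Every primer-level physical quantity the design filters consume lives here:
GC fraction, homopolymer runs, nearest-neighbor (NN) melting temperature, and
duplex / hairpin free energies.

The NN model treats a duplex as a chain of dinucleotide "stacks", each
contributing tabulated enthalpy (ΔH, kcal/mol) and entropy (ΔS, cal/mol/K),
plus initiation terms for the two terminal base pairs.  The default parameter
set is the unified DNA/DNA table of SantaLucia (1998), shipped as a versioned
plain-text file under :mod:`mpxdesign.data` so that tests and independent
oracles can read the very same numbers.

Free energies are evaluated at ``ThermoConfig.temperature_C`` (default 37 °C)
as ΔG = ΔH − T·ΔS and reported in kcal/mol; melting temperatures apply the
SantaLucia entropy salt correction and are reported in °C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

__all__ = [
    "ThermoConfig",
    "NNTable",
    "load_nn_table",
    "reverse_complement",
    "gc_fraction",
    "max_homopolymer_run",
    "melting_temperature",
    "duplex_dG",
    "hairpin_dG",
    "DUPLEX_MIN_PAIRS",
    "HAIRPIN_MIN_STEM",
    "HAIRPIN_MIN_LOOP",
]

R_CAL = 1.98720425864083  # gas constant, cal/(mol*K)
MIN_NN_LENGTH = 8  # below this the two-state NN model is unreliable

#: minimum number of consecutive complementary pairs for a duplex to count
DUPLEX_MIN_PAIRS = 4
#: minimum stem pairs / minimum unpaired loop bases for a hairpin
HAIRPIN_MIN_STEM = 3
HAIRPIN_MIN_LOOP = 3

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_seq(seq: str, min_len: int = 1) -> None:
    if len(seq) < min_len:
        raise ValueError(
            f"sequence of length {len(seq)} is too short (minimum {min_len})"
        )
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)!r}")


@dataclass(frozen=True)
class NNTable:
    """Nearest-neighbor parameter set (ΔH kcal/mol, ΔS cal/mol/K)."""

    name: str
    stack_dh: dict
    stack_ds: dict
    init_dh: dict  # keyed by terminal base: A/T share one term, G/C the other
    init_ds: dict
    symmetry_dh: float
    symmetry_ds: float


@lru_cache(maxsize=None)
def load_nn_table(name: str = "santalucia1998") -> NNTable:
    """Load a named NN parameter table from the packaged data directory."""
    try:
        text = resources.files("mpxdesign.data").joinpath(f"{name}.tsv").read_text()
    except FileNotFoundError as exc:
        raise ValueError(f"unknown NN parameter set {name!r}") from exc
    stack_dh: dict = {}
    stack_ds: dict = {}
    init_dh: dict = {}
    init_ds: dict = {}
    sym_dh = sym_ds = 0.0
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, dh, ds = line.split("\t")
        dh, ds = float(dh), float(ds)
        if key == "symmetry":
            sym_dh, sym_ds = dh, ds
        elif key == "init_AT":
            init_dh["A"] = init_dh["T"] = dh
            init_ds["A"] = init_ds["T"] = ds
        elif key == "init_GC":
            init_dh["G"] = init_dh["C"] = dh
            init_ds["G"] = init_ds["C"] = ds
        else:
            stack_dh[key] = dh
            stack_ds[key] = ds
    if len(stack_dh) != 16:
        raise ValueError(f"NN table {name!r} has {len(stack_dh)} stacks, expected 16")
    return NNTable(name, stack_dh, stack_ds, init_dh, init_ds, sym_dh, sym_ds)


@dataclass(frozen=True)
class ThermoConfig:
    """Conditions under which Tm and ΔG are evaluated.

    Concentrations follow common PCR practice: ~50 mM monovalent salt and a
    total oligo strand concentration of 50 nM.  ``temperature_C`` is the
    temperature at which duplex/hairpin ΔG values are computed.
    """

    nn_parameter_set: str = "santalucia1998"
    monovalent_salt_mM: float = 50.0
    divalent_salt_mM: float = 0.0
    dntp_mM: float = 0.0
    oligo_concentration_nM: float = 50.0
    temperature_C: float = 37.0
    hairpin_loop_penalty_kcal: float = 3.5

    def __post_init__(self) -> None:
        for name in ("monovalent_salt_mM", "divalent_salt_mM", "dntp_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.oligo_concentration_nM <= 0:
            raise ValueError("oligo_concentration_nM must be > 0")

    @property
    def table(self) -> NNTable:
        return load_nn_table(self.nn_parameter_set)

    @property
    def effective_monovalent_M(self) -> float:
        """Monovalent-equivalent cation concentration (von Ahsen conversion)."""
        free_mg = max(self.divalent_salt_mM - self.dntp_mM, 0.0)
        return (self.monovalent_salt_mM + 120.0 * math.sqrt(free_mg)) / 1000.0


_DEFAULT = ThermoConfig()


def gc_fraction(seq: str) -> float:
    """Fraction of G+C bases in ``seq`` (exact rational division)."""
    _check_seq(seq)
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of a single repeated base."""
    _check_seq(seq)
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        if run > best:
            best = run
    return best


def melting_temperature(seq: str, cfg: ThermoConfig = _DEFAULT) -> float:
    """Nearest-neighbor melting temperature in °C.

    Tm = ΔH / (ΔS + R·ln(C_T/x)) − 273.15 with the SantaLucia entropy salt
    correction ΔS += 0.368·N·ln[Na+] (N = number of stacks).  x is 4 for a
    non-self-complementary oligo hybridizing an equimolar complement, 1 for a
    self-complementary one.
    """
    _check_seq(seq, MIN_NN_LENGTH)
    tab = cfg.table
    dh = tab.init_dh[seq[0]] + tab.init_dh[seq[-1]]
    ds = tab.init_ds[seq[0]] + tab.init_ds[seq[-1]]
    for i in range(len(seq) - 1):
        step = seq[i : i + 2]
        dh += tab.stack_dh[step]
        ds += tab.stack_ds[step]
    x = 4.0
    if seq == reverse_complement(seq):
        dh += tab.symmetry_dh
        ds += tab.symmetry_ds
        x = 1.0
    na = cfg.effective_monovalent_M
    if na <= 0:
        raise ValueError("effective monovalent cation concentration must be > 0")
    ds += 0.368 * (len(seq) - 1) * math.log(na)
    ct = cfg.oligo_concentration_nM * 1e-9
    return 1000.0 * dh / (ds + R_CAL * math.log(ct / x)) - 273.15


def _stack_dg(tab: NNTable, step: str, temp_k: float) -> float:
    return tab.stack_dh[step] - temp_k * tab.stack_ds[step] / 1000.0


def _init_dg(tab: NNTable, base: str, temp_k: float) -> float:
    return tab.init_dh[base] - temp_k * tab.init_ds[base] / 1000.0


def duplex_dG(seq_a: str, seq_b: str, cfg: ThermoConfig = _DEFAULT) -> float:
    """ΔG (kcal/mol) of the most stable ungapped duplex between two oligos.

    ``seq_a`` is scanned against the reverse-complement sense of ``seq_b`` at
    every offset (antiparallel alignment, no bulges).  Each maximal run of at
    least :data:`DUPLEX_MIN_PAIRS` consecutive Watson-Crick pairs is scored as
    the sum of its NN stacks plus the two terminal initiation terms, at
    ``cfg.temperature_C``.  Returns 0.0 when no qualifying run exists.
    Symmetric in its arguments; the homodimer case is ``seq_a == seq_b``.
    """
    _check_seq(seq_a, MIN_NN_LENGTH)
    _check_seq(seq_b, MIN_NN_LENGTH)
    tab = cfg.table
    temp_k = cfg.temperature_C + 273.15
    br = seq_b[::-1]
    la, lb = len(seq_a), len(seq_b)
    best: float | None = None
    for shift in range(-(lb - 1), la):
        i0 = max(0, shift)
        i1 = min(la, lb + shift)
        if i1 - i0 < DUPLEX_MIN_PAIRS:
            continue
        run_start = None
        for i in range(i0, i1 + 1):
            paired = i < i1 and br[i - shift] == _COMP[seq_a[i]]
            if paired and run_start is None:
                run_start = i
            elif not paired and run_start is not None:
                run_len = i - run_start
                if run_len >= DUPLEX_MIN_PAIRS:
                    g = _init_dg(tab, seq_a[run_start], temp_k)
                    g += _init_dg(tab, seq_a[i - 1], temp_k)
                    for k in range(run_start, i - 1):
                        g += _stack_dg(tab, seq_a[k : k + 2], temp_k)
                    if best is None or g < best:
                        best = g
                run_start = None
    return best if best is not None else 0.0


def hairpin_dG(seq: str, cfg: ThermoConfig = _DEFAULT) -> float:
    """ΔG (kcal/mol) of the best single-stem hairpin, 0.0 if none exists.

    A hairpin pairs positions (i+t, j−t) for t < s with a stem of
    s ≥ :data:`HAIRPIN_MIN_STEM` Watson-Crick pairs enclosing a loop of at
    least :data:`HAIRPIN_MIN_LOOP` unpaired bases.  The stem is scored by its
    NN stacks plus a fixed loop penalty (``cfg.hairpin_loop_penalty_kcal``).
    Never positive: the unfolded state (ΔG = 0) is always available.
    """
    _check_seq(seq, MIN_NN_LENGTH)
    tab = cfg.table
    temp_k = cfg.temperature_C + 273.15
    n = len(seq)
    span = 2 * HAIRPIN_MIN_STEM + HAIRPIN_MIN_LOOP  # minimum j - i + 1
    best = 0.0
    for i in range(0, n - span + 1):
        for j in range(i + span - 1, n):
            s = 0
            stacks = 0.0
            while True:
                ii, jj = i + s, j - s
                # loop left after adding pair s+1 must stay >= HAIRPIN_MIN_LOOP
                if jj - ii - 1 < HAIRPIN_MIN_LOOP:
                    break
                if seq[jj] != _COMP[seq[ii]]:
                    break
                if s >= 1:
                    stacks += _stack_dg(tab, seq[ii - 1 : ii + 1], temp_k)
                s += 1
                if s >= HAIRPIN_MIN_STEM:
                    g = stacks + cfg.hairpin_loop_penalty_kcal
                    if g < best:
                        best = g
    return best
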