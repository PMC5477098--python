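"""Design configuration: every threshold and search parameter in one place.

The defaults encode the design rules the package enforces: amplicons of
300–500 bases, primers of 23–30 bases with 30–70% GC, no homopolymer of four
or more bases, primer Tm within 0.5 °C of the optimum (and of each other
within a pair), and no secondary structure or cross-dimer with
ΔG below −3 kcal/mol.  Amplicons are assigned round-robin to ``m_tubes``
reaction tubes; at least two tubes are required so that every internal primer
site is covered by a neighboring amplicon from the other tube (the guard
against allele dropout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .thermo import ThermoConfig

__all__ = ["DesignConfig", "ORDERINGS"]

#: Candidate-ordering strategies for the depth-first search.  "Normal" order
#: is ascending base location (forward primers by start, reverse primers by
#: end); "reverse" order is descending.
ORDERINGS = ("bothNormal", "fwdReverse", "revReverse", "bothReverse")


@dataclass(frozen=True)
class DesignConfig:
    """All thresholds and search parameters for a multiplex design run."""

    m_tubes: int = 2
    optimum_tm_C: float = 60.0
    flank_len: int = 240
    amplicon_min: int = 300
    amplicon_max: int = 500
    primer_len_min: int = 23
    primer_len_max: int = 30
    gc_min: float = 0.30
    gc_max: float = 0.70
    max_homopolymer: int = 3
    primer_tm_tolerance_C: float = 0.5
    tm_pair_tolerance_C: float = 0.5
    dG_threshold: float = -3.0
    variant_exclusion_len: int = 3
    time_limit_s: float = 240.0
    ordering: str = "bothNormal"
    thermo: ThermoConfig = field(default_factory=ThermoConfig)

    def __post_init__(self) -> None:
        if self.m_tubes < 2:
            raise ValueError(
                f"m_tubes must be at least 2 (amplicons are split across tubes "
                f"so neighboring products cover internal primer sites); got "
                f"{self.m_tubes}"
            )
        if self.amplicon_min > self.amplicon_max:
            raise ValueError("amplicon_min must not exceed amplicon_max")
        if not 0 < self.primer_len_min <= self.primer_len_max:
            raise ValueError("invalid primer length bounds")
        if not 0.0 <= self.gc_min <= self.gc_max <= 1.0:
            raise ValueError("invalid GC bounds")
        if self.flank_len <= 0:
            raise ValueError("flank_len must be positive")
        if self.ordering not in ORDERINGS:
            raise ValueError(
                f"unknown ordering {self.ordering!r}; valid orderings: "
                f"{', '.join(ORDERINGS)}"
            )
        if self.time_limit_s < 0:
            raise ValueError("time_limit_s must be >= 0")
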