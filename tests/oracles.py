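"""Independent oracle implementations used only by the test-suite.

These re-derive every thermodynamic and filtering quantity from scratch —
their own parse of the shipped parameter file, their own summation code, and
exhaustive enumeration instead of scanning — so that agreement with the
package is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import math
import re
from functools import lru_cache
from importlib import resources

R = 1.98720425864083
COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

# frozen values computed with a separate hand-summation script before the
# package implementation was written
TM_23MER = "AGCGTAGCTAGCTAGCTAGCTAG"
TM_23MER_EXPECTED = 55.056974  # °C, default conditions
FULL_DUPLEX_23MER_EXPECTED = -28.618980  # kcal/mol at 37 °C vs exact rev-comp
HAIRPIN_EXPECTED = {"GGGGAAAACCCC": -1.984045, "ATATATAT": 0.0}


@lru_cache(maxsize=None)
def nn_params():
    """Parse the packaged NN table with independent code."""
    text = resources.files("mpxdesign.data").joinpath("santalucia1998.tsv").read_text()
    rows = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, dh, ds = line.split("\t")
        rows[key] = (float(dh), float(ds))
    return rows


def _init_terms(base):
    return nn_params()["init_AT" if base in "AT" else "init_GC"]


def oracle_tm(seq, na_M=0.050, total_oligo_M=50e-9):
    """Independent NN melting temperature (non-self-complementary oligo)."""
    p = nn_params()
    dh = _init_terms(seq[0])[0] + _init_terms(seq[-1])[0]
    ds = _init_terms(seq[0])[1] + _init_terms(seq[-1])[1]
    for a, b in zip(seq, seq[1:]):
        step_dh, step_ds = p[a + b]
        dh += step_dh
        ds += step_ds
    ds += 0.368 * (len(seq) - 1) * math.log(na_M)
    return 1000.0 * dh / (ds + R * math.log(total_oligo_M / 4.0)) - 273.15


def _dg(key, temp_k):
    dh, ds = nn_params()[key]
    return dh - temp_k * ds / 1000.0


def _init_dg(base, temp_k):
    dh, ds = _init_terms(base)
    return dh - temp_k * ds / 1000.0


def oracle_duplex(seq_a, seq_b, temp_c=37.0, min_pairs=4):
    """Exhaustive enumeration of all ungapped complementary runs.

    Every (i, j, L) with seq_a[i+t] pairing seq_b[j-t] for t < L is scored;
    submaximal runs are included (they are never more stable than their
    maximal extension under this table, so the minimum is unchanged).
    """
    temp_k = temp_c + 273.15
    best = None
    la, lb = len(seq_a), len(seq_b)
    for i in range(la):
        for j in range(lb):
            run = 0
            g = None
            while i + run < la and j - run >= 0:
                if seq_b[j - run] != COMP[seq_a[i + run]]:
                    break
                run += 1
                if run >= 2:
                    step = seq_a[i + run - 2 : i + run]
                    g = (g or 0.0) + _dg(step, temp_k)
                if run >= min_pairs:
                    total = (
                        (g or 0.0)
                        + _init_dg(seq_a[i], temp_k)
                        + _init_dg(seq_a[i + run - 1], temp_k)
                    )
                    if best is None or total < best:
                        best = total
    return best if best is not None else 0.0


def oracle_hairpin(seq, temp_c=37.0, loop_penalty=3.5, min_stem=3, min_loop=3):
    """Exhaustive enumeration of all single-stem hairpins."""
    temp_k = temp_c + 273.15
    n = len(seq)
    best = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            for s in range(min_stem, n):
                if j - i - 2 * s + 1 < min_loop:
                    break
                if all(seq[j - t] == COMP[seq[i + t]] for t in range(s)):
                    g = loop_penalty
                    for t in range(s - 1):
                        g += _dg(seq[i + t : i + t + 2], temp_k)
                    best = min(best, g)
    return best


def oracle_gc(seq):
    return sum(1 for b in seq if b in "GC") / len(seq)


def oracle_max_run(seq):
    return max(len(m.group(0)) for m in re.finditer(r"(.)\1*", seq))


def oracle_primer_predicate(
    seq,
    optimum_tm,
    three_prime_positions=(),
    variant_positions=frozenset(),
    len_bounds=(23, 30),
    gc_bounds=(0.30, 0.70),
    max_run=3,
    tm_tol=0.5,
):
    """Independently coded per-primer filter: length, GC, homopolymer,
    Tm band and 3'-variant exclusion (structure screens handled separately)."""
    if not len_bounds[0] <= len(seq) <= len_bounds[1]:
        return False
    if not gc_bounds[0] <= oracle_gc(seq) <= gc_bounds[1]:
        return False
    if oracle_max_run(seq) > max_run:
        return False
    if abs(oracle_tm(seq) - optimum_tm) > tm_tol:
        return False
    if any(p in variant_positions for p in three_prime_positions):
        return False
    return True
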