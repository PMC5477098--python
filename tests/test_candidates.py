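"""Candidate enumeration, per-primer filters, specificity screening."""

import subprocess

import numpy as np
import pytest

from mpxdesign import (
    DesignConfig,
    ExactMatchIndex,
    TargetRegion,
    apply_specificity_filter,
    enumerate_candidates,
    primer_ok,
    reverse_complement,
)
from mpxdesign.candidates import FORWARD, REVERSE, BlastBackend, evaluate_primer

import oracles
from conftest import random_oligo

# wide Tm band / disabled structure screens isolate the compositional filters
RELAXED = DesignConfig(primer_tm_tolerance_C=1e6, dG_threshold=-1e6)


class TestPerPrimerFilters:
    def test_gc_bounds_inclusive(self):
        # length-30 oligos hit the 30% / 70% endpoints exactly
        at_30 = "ATG" * 9 + "ATA"  # 9/30 GC = 0.30
        at_70 = "GCA" * 9 + "GCG"  # 21/30 GC = 0.70
        over = "GCA" * 8 + "GCGCGC"  # 22/30 GC = 0.733
        assert oracles.oracle_gc(at_30) == pytest.approx(0.30)
        assert oracles.oracle_gc(at_70) == pytest.approx(0.70)
        assert primer_ok(at_30, RELAXED)
        assert primer_ok(at_70, RELAXED)
        assert not primer_ok(over, RELAXED)

    def test_length_bounds(self):
        rng = np.random.default_rng(0)
        short = random_oligo(rng, 22)
        long = random_oligo(rng, 31)
        assert not primer_ok(short, RELAXED)
        assert not primer_ok(long, RELAXED)

    def test_homopolymer_filter(self):
        seq = "ACGTACGTACGTAAAAACGTACG"  # run of 5
        assert not primer_ok(seq, RELAXED)

    def test_tm_band_inclusive_boundaries(self):
        from dataclasses import replace

        from mpxdesign.thermo import melting_temperature

        rng = np.random.default_rng(1)
        seq = None
        while seq is None:
            cand = random_oligo(rng, 24)
            if evaluate_primer(cand, RELAXED) is not None:
                seq = cand
        tm = melting_temperature(seq)
        at_band = replace(RELAXED, optimum_tm_C=tm + 0.5, primer_tm_tolerance_C=0.5)
        outside = replace(RELAXED, optimum_tm_C=tm + 0.5001, primer_tm_tolerance_C=0.5)
        assert primer_ok(seq, at_band)
        assert not primer_ok(seq, outside)


def brute_force_window_candidates(region, cfg, strand):
    """Independent double-loop enumeration with the oracle predicate."""
    from mpxdesign import thermo

    out = []
    for start in range(0, region.length):
        for length in range(23, 31):
            end = start + length
            if end > region.length:
                continue
            window = region.sequence[start:end]
            seq = window if strand == FORWARD else reverse_complement(window)
            if strand == FORWARD:
                three_prime = range(end - 3, end)
            else:
                three_prime = range(start, start + 3)
            if not oracles.oracle_primer_predicate(
                seq, cfg.optimum_tm_C, three_prime, region.variant_positions
            ):
                continue
            if oracles.oracle_hairpin(seq) < cfg.dG_threshold:
                continue
            if oracles.oracle_duplex(seq, seq) < cfg.dG_threshold:
                continue
            out.append((start, end))
    return out


class TestEnumerateCandidates:
    def test_exhaustive_against_independent_predicate(self, random_fixture):
        region = random_fixture.region
        # shrink to a 400-base slice to keep the brute force lean
        small = TargetRegion("slice", region.sequence[:400], 100,
                             frozenset(p for p in region.variant_positions if p < 400))
        cfg = random_fixture.config()
        for strand in (FORWARD, REVERSE):
            got = [
                (c.start, c.end)
                for c in enumerate_candidates(small, 0, small.length, strand, cfg)
            ]
            assert got == brute_force_window_candidates(small, cfg, strand)

    def test_forward_window_binds_start_reverse_binds_end(self, poison_fixture):
        region = poison_fixture.region
        cfg = poison_fixture.config()
        f0 = poison_fixture.forward_starts[0]
        e0 = poison_fixture.reverse_ends[0]
        fwd = enumerate_candidates(region, f0, f0 + 1, FORWARD, cfg)
        assert [c.start for c in fwd] == [f0]
        rev = enumerate_candidates(region, e0 - 1, e0, REVERSE, cfg)
        assert [c.end for c in rev] == [e0]

    def test_empty_window_returns_empty(self, poison_fixture):
        cfg = poison_fixture.config()
        assert enumerate_candidates(poison_fixture.region, 10, 10, FORWARD, cfg) == []

    def test_poly_a_region_has_no_candidates(self):
        region = TargetRegion("polya", "A" * 900, 240)
        cfg = DesignConfig()
        assert enumerate_candidates(region, 0, 900, FORWARD, cfg) == []

    def test_variant_under_three_prime_kills_candidate(self, poison_fixture):
        cfg = poison_fixture.config()
        base = poison_fixture.region
        f0 = poison_fixture.forward_starts[0]
        oligo_end = f0 + 23

        def with_variant(pos):
            return TargetRegion(base.name, base.sequence, base.flank_len,
                                frozenset({pos}))

        killed = with_variant(oligo_end - 1)  # under the 3'-terminal base
        spared = with_variant(oligo_end - 4)  # 4 bases from the 3' end
        assert enumerate_candidates(killed, f0, f0 + 1, FORWARD, cfg) == []
        assert [c.start for c in
                enumerate_candidates(spared, f0, f0 + 1, FORWARD, cfg)] == [f0]

    def test_deterministic(self, random_fixture):
        region = random_fixture.region
        cfg = random_fixture.config()
        a = enumerate_candidates(region, 0, 300, FORWARD, cfg)
        b = enumerate_candidates(region, 0, 300, FORWARD, cfg)
        assert a == b

    def test_canonical_order(self, random_fixture):
        cfg = random_fixture.config()
        for strand in (FORWARD, REVERSE):
            cands = enumerate_candidates(
                random_fixture.region, 0, random_fixture.region.length, strand, cfg
            )
            keys = [(c.start, c.length) for c in cands]
            assert keys == sorted(keys)


class TestSpecificity:
    def test_exact_match_counts(self):
        # "ACCTGAC" occurs twice; its reverse complement "GTCAGGT" never
        ref = "GGACCTGACGGTTTTTAAACCTGACAA"
        idx = ExactMatchIndex(ref)
        assert idx.query("ACCTGAC") == 2
        assert idx.query("GGACCTGACGG") == 1
        # a hit on the opposite strand counts the same
        assert idx.query(reverse_complement("GGACCTGACGG")) == 1
        assert idx.query("GGGGGGG") == 0

    def test_filter_discards_repeated_candidates(self, poison_fixture):
        region = poison_fixture.region
        cfg = poison_fixture.config()
        cands = enumerate_candidates(region, 0, region.length, FORWARD, cfg)
        assert cands
        # the region itself: every candidate occurs exactly once -> retained
        idx = ExactMatchIndex(region.sequence)
        kept = apply_specificity_filter(cands, idx)
        assert [(c.start, c.end) for c in kept] == [(c.start, c.end) for c in cands]
        assert all(c.specificity_checked for c in kept)
        # duplicate the first candidate's site elsewhere -> discarded
        dup = region.sequence + "TTTT" + cands[0].sequence + "TTTT"
        kept2 = apply_specificity_filter(cands, ExactMatchIndex(dup))
        assert (cands[0].start, cands[0].end) not in [(c.start, c.end) for c in kept2]

    def test_empty_input(self):
        assert apply_specificity_filter([], ExactMatchIndex("ACGT" * 10)) == []

    def test_missing_backend_policies(self, poison_fixture):
        cfg = poison_fixture.config()
        cands = enumerate_candidates(
            poison_fixture.region, 0, poison_fixture.region.length, FORWARD, cfg
        )
        with pytest.raises(ValueError):
            apply_specificity_filter(cands, None)
        passed = apply_specificity_filter(cands, None, on_missing="pass")
        assert passed == cands
        assert not any(c.specificity_checked for c in passed)

    def test_blast_backend_counts_evalue_hits(self, tmp_path, poison_fixture):
        region = poison_fixture.region
        db_fa = tmp_path / "ref.fa"
        seq = region.sequence
        cand = enumerate_candidates(
            region, 0, region.length, FORWARD, poison_fixture.config()
        )[0]
        # reference with the candidate's locus present twice
        db_fa.write_text(f">ref\n{seq}\n>dup\n{'T' * 40}{cand.sequence}{'T' * 40}\n")
        subprocess.run(
            ["makeblastdb", "-in", str(db_fa), "-dbtype", "nucl"],
            check=True, capture_output=True,
        )
        backend = BlastBackend(db_fa)
        assert backend.query(cand.sequence) >= 2
        kept = apply_specificity_filter([cand], backend)
        assert kept == []
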