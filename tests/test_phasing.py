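"""Phase score arithmetic, locus scanning, phasiRNA naming, trigger sites."""

import math

import numpy as np
import pytest

from oracles import recount_phase_window
from phasiscan.phasing import (
    PhasLocus,
    annotate_trigger,
    enumerate_phasirnas,
    parse_phasirna_name,
    phase_score,
    phase_score_window,
    scan_phas_loci,
)
from phasiscan.seqtools import random_seq, revcomp
from phasiscan.srna import PositionProfile


def profile_with(entries):
    prof = PositionProfile()
    for ref, strand, pos, length, count in entries:
        prof.add(ref, strand, pos, length, count)
    return prof


class TestPhaseScore:
    def test_three_cycles_no_background(self):
        assert phase_score(3, 12.0, 0.0) == pytest.approx(math.log(121.0))

    def test_with_background(self):
        assert phase_score(3, 12.0, 12.0) == pytest.approx(math.log(1 + 120 / 13))

    def test_fewer_than_three_slots_zero(self):
        assert phase_score(2, 100.0, 0.0) == 0.0

    def test_monotone_in_p_and_u(self):
        base = phase_score(5, 50.0, 10.0)
        assert phase_score(5, 60.0, 10.0) > base
        assert phase_score(5, 50.0, 20.0) < base
        assert phase_score(6, 50.0, 10.0) > base


class TestPhaseScoreWindow:
    def test_matches_manual_counts(self):
        entries = [
            ("r", "+", 100, 21, 4.0),
            ("r", "+", 121, 21, 4.0),
            ("r", "+", 142, 21, 4.0),
            ("r", "+", 150, 21, 2.0),  # off-register
            ("r", "+", 163, 24, 9.0),  # wrong length: ignored
        ]
        stat = phase_score_window(profile_with(entries), "r", 95, 21, 100 % 21)
        assert (stat.k, stat.phased_abundance, stat.unphased_abundance) == (3, 12.0, 2.0)
        assert stat.score == pytest.approx(phase_score(3, 12.0, 2.0))

    def test_minus_strand_shift(self):
        # minus read 5' at register - 2 counts as in-register
        entries = [
            ("r", "+", 100, 21, 1.0),
            ("r", "-", 119, 21, 1.0),
            ("r", "+", 142, 21, 1.0),
        ]
        stat = phase_score_window(profile_with(entries), "r", 95, 21, 100 % 21)
        assert stat.k == 3 and stat.phased_abundance == 3.0

    def test_empty_window(self):
        stat = phase_score_window(PositionProfile(), "r", 0, 21, 0)
        assert stat.k == 0 and stat.score == 0.0

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            phase_score_window(PositionProfile(), "r", 0, 22, 0)
        with pytest.raises(ValueError):
            phase_score_window(PositionProfile(), "r", 50, 21, 0, reference_length=200)

    def test_agrees_with_recount_on_fuzzed_profiles(self, rng):
        for _ in range(30):
            entries = [
                (
                    "r",
                    "+" if rng.random() < 0.5 else "-",
                    int(rng.integers(0, 700)),
                    int(rng.integers(18, 31)),
                    float(rng.integers(1, 9)),
                )
                for _ in range(60)
            ]
            prof = profile_with(entries)
            start = int(rng.integers(0, 400))
            register = int(rng.integers(0, 21))
            stat = phase_score_window(prof, "r", start, 21, register)
            # recount from the collapsed (unique-key) entries
            collapsed = [(s, p, ln, c) for (_r, s, p, ln), c in prof.counts.items()]
            k, P, U = recount_phase_window(collapsed, start, 21, register)
            assert (stat.k, stat.phased_abundance, stat.unphased_abundance) == (k, P, U)
            assert stat.score == pytest.approx(phase_score(k, P, U))


class TestScanPhasLoci:
    def _phased_profile(self, start, cycles, period=21, count=10.0, ref="r"):
        entries = []
        for j in range(cycles):
            entries.append((ref, "+", start + j * period, period, count))
            entries.append((ref, "-", start + j * period - 2, period, count))
        return entries

    def test_recovers_single_locus_with_register(self):
        prof = profile_with(self._phased_profile(300, 10))
        loci = scan_phas_loci(prof, 21, reference_lengths={"r": 2000})
        assert len(loci) == 1
        (locus,) = loci
        assert locus.register == 300 % 21
        assert locus.locus_id == "21PHAS0001"
        assert locus.max_k >= 4 and locus.max_score >= 15

    def test_two_distant_loci_not_merged(self):
        entries = self._phased_profile(100, 10) + self._phased_profile(900, 10)
        loci = scan_phas_loci(profile_with(entries), 21, reference_lengths={"r": 2500})
        assert len(loci) == 2
        assert [L.locus_id for L in loci] == ["21PHAS0001", "21PHAS0002"]

    def test_no_cross_period_calls(self):
        prof = profile_with(self._phased_profile(300, 12, period=21))
        assert scan_phas_loci(prof, 24, reference_lengths={"r": 2000}) == []

    def test_empty_profile(self):
        assert scan_phas_loci(PositionProfile(), 21) == []

    def test_uniform_background_specificity(self):
        """Null model: uniform random reads almost never produce a locus."""
        n_with_calls = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            prof = PositionProfile()
            n = rng.poisson(0.05 * 20_000)
            for _ in range(n):
                prof.add(
                    "bg",
                    "+" if rng.random() < 0.5 else "-",
                    int(rng.integers(0, 20_000)),
                    int(rng.integers(18, 31)),
                    1.0,
                )
            loci = scan_phas_loci(prof, 21, reference_lengths={"bg": 20_000})
            n_with_calls += bool(loci)
        assert n_with_calls <= 5


class TestEnumeratePhasirnas:
    def test_names_offsets_and_sequences(self, rng):
        refseq = random_seq(rng, 800)
        entries = []
        for j in range(5):
            entries.append(("r", "+", 210 + j * 21, 21, 3.0))
        entries.append(("r", "-", 229, 21, 2.0))  # in register via +2 shift
        entries.append(("r", "+", 231, 22, 9.0))  # in register, wrong length
        prof = profile_with(entries)
        (locus,) = scan_phas_loci(prof, 21, reference_lengths={"r": 800})
        phas = enumerate_phasirnas(locus, prof, {"r": refseq})
        names = {x.name for x in phas}
        assert len(phas) == 6
        assert locus.n_offlength_inregister == 1
        for x in phas:
            loc, offset, strand = parse_phasirna_name(x.name)
            assert loc == locus.locus_id
            assert offset == x.position - locus.start
            if strand == "+":
                assert x.sequence == refseq[x.position : x.position + 21]
            else:
                assert x.sequence == revcomp(
                    refseq[x.position - 20 : x.position + 1]
                )
            eff = x.position if strand == "+" else x.position + 2
            assert eff % 21 == locus.register
        # locus spans from the leftmost read base (the minus read at 229
        # covers 209..229), so the first plus-strand 5' end sits at offset 1
        assert f"{locus.locus_id}_1+" in names
        assert f"{locus.locus_id}_20-" in names

    def test_empty_locus(self):
        locus = PhasLocus("21PHAS0001", "r", 100, 400, 21, 5, "+", 20.0, 6)
        assert enumerate_phasirnas(locus, PositionProfile(), {"r": "A" * 500}) == []

    def test_name_parse_rejects_garbage(self):
        with pytest.raises(ValueError):
            parse_phasirna_name("PHAS12_3+")


class TestAnnotateTrigger:
    def _locus_for(self, cleavage0, period=21, ref="pre"):
        return PhasLocus(
            "21PHAS0001", ref, cleavage0, cleavage0 + 10 * period, period,
            cleavage0 % period, "+", 50.0, 10,
        )

    def test_exact_embedded_site(self, rng):
        trigger = "TTGCAATCCGTCACCAATCCT"
        pre = random_seq(rng, 400)
        pre = pre[:50] + revcomp(trigger) + pre[71:]
        cleavage0 = 50 + 21 - 10
        ann = annotate_trigger(self._locus_for(cleavage0), pre, {"miRX": trigger})
        assert ann is not None
        assert ann.mirna == "miRX" and ann.score == 0.0
        assert ann.cleavage_pos0 == cleavage0
        assert ann.register_consistent

    def test_no_qualifying_site(self, rng):
        ann = annotate_trigger(
            self._locus_for(42), random_seq(rng, 300), {"miRX": random_seq(rng, 21)}
        )
        assert ann is None

    def test_best_of_two_triggers_with_secondary(self, rng):
        t1 = "TTGCAATCCGTCACCAATCCT"
        t2 = list(t1)
        t2[4] = "C"  # one core mismatch against the t1 site (C:T)
        t2 = "".join(t2)
        pre = random_seq(rng, 400)
        pre = pre[:50] + revcomp(t1) + pre[71:]
        ann = annotate_trigger(
            self._locus_for(61), pre, {"worse": t2, "exact": t1}
        )
        assert ann.mirna == "exact" and ann.score == 0.0
        assert ("worse", 1.0) in ann.secondary
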