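"""Mispair duplex scoring: hand cases, DP-vs-enumeration, site search."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import brute_force_duplex_score
from phasiscan.seqtools import random_seq, revcomp
from phasiscan.targets import (
    PenaltyScheme,
    find_candidate_sites,
    iter_candidates_concat,
    predict_targets,
    score_duplex,
)

SRNA = "TTGCAATCCGTCACCAATCCT"  # 21 nt, G at position 10


def mutate_paired_base(window: str, srna_pos: int, new_base: str) -> str:
    """Replace the window base paired with a given 1-based sRNA position."""
    w = list(window)
    w[len(window) - srna_pos] = new_base
    return "".join(w)


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        aln = score_duplex(SRNA, revcomp(SRNA))
        assert aln.score == 0.0
        assert aln.states == "|" * 21
        # sRNA position 10 pairs window index 11 -> 1-based site 12
        assert aln.cleavage_site == 12

    def test_single_core_gu_wobble(self):
        w = mutate_paired_base(revcomp(SRNA), 10, "T")  # G:U at position 10
        assert score_duplex(SRNA, w).score == 0.5

    def test_terminal_penalties_halved(self):
        srna = list(SRNA)
        srna[17] = "G"  # position 18, outside the 2-17 core
        srna = "".join(srna)
        w = revcomp(srna)
        w = mutate_paired_base(w, 18, "T")  # G:U outside core: 0.25
        w = mutate_paired_base(w, 1, "C")  # T:C mismatch at position 1: 0.5
        assert score_duplex(srna, w).score == pytest.approx(0.75)

    def test_window_length_bounds(self):
        with pytest.raises(ValueError):
            score_duplex(SRNA, revcomp(SRNA)[:17])

    def test_score_recomputable_from_states(self, rng):
        scheme = PenaltyScheme()
        for _ in range(50):
            n = int(rng.integers(12, 22))
            m = int(rng.integers(n - 2, n + 3))
            aln = score_duplex(random_seq(rng, n), random_seq(rng, m), scheme)
            assert aln.recomputed_score(scheme) == pytest.approx(aln.score)

    @given(st.integers(2, 17))
    def test_wobble_and_mismatch_ordering(self, pos):
        """WC -> G:U never decreases the score; G:U -> mismatch never decreases it."""
        srna = list(SRNA)
        srna[pos - 1] = "G"
        srna = "".join(srna)
        perfect = revcomp(srna)
        wc = score_duplex(srna, perfect).score
        gu = score_duplex(srna, mutate_paired_base(perfect, pos, "T")).score
        mm = score_duplex(srna, mutate_paired_base(perfect, pos, "A")).score
        assert wc <= gu <= mm


class TestDPOptimality:
    def test_matches_exhaustive_enumeration(self, rng):
        scheme = PenaltyScheme()
        for _ in range(150):
            n = int(rng.integers(8, 16))
            m = int(rng.integers(n - 2, n + 3))
            s = random_seq(rng, n)
            w = random_seq(rng, m)
            assert score_duplex(s, w, scheme).score == pytest.approx(
                brute_force_duplex_score(s, w, scheme)
            )


class TestFindCandidateSites:
    def test_planted_perfect_site(self, rng):
        t = random_seq(rng, 400)
        t = t[:150] + revcomp(SRNA) + t[171:]
        sites = find_candidate_sites(SRNA, t)
        assert len(sites) >= 1
        best = min(sites, key=lambda s: s.score)
        assert (best.target_start, best.score) == (150, 0.0)
        assert best.cleavage_site == 150 + 12

    def test_inclusive_retention_at_exactly_3_5(self, rng):
        # three core mismatches (+3) and one core wobble (+0.5)
        srna = list(SRNA)
        srna[5] = "G"
        srna = "".join(srna)
        w = revcomp(srna)
        for pos in (4, 8, 13):
            w = mutate_paired_base(w, pos, srna[pos - 1])  # self-pairing mismatch
        w = mutate_paired_base(w, 6, "T")
        assert score_duplex(srna, w).score == pytest.approx(3.5)
        t = random_seq(rng, 300)[:100] + w + random_seq(rng, 300)[:100]
        sites = find_candidate_sites(srna, t)
        assert any(s.target_start == 100 and s.score == pytest.approx(3.5) for s in sites)

    def test_sites_agree_with_per_window_oracle(self, rng):
        scheme = PenaltyScheme()
        srna = random_seq(rng, 14)
        t = random_seq(rng, 500)
        t = t[:200] + revcomp(srna) + t[214:]
        sites = find_candidate_sites(srna, t, scheme)
        assert sites, "planted perfect site must be found"
        for s in sites:
            assert s.score <= scheme.max_score
            assert s.score == pytest.approx(
                brute_force_duplex_score(srna, t[s.target_start : s.target_end], scheme)
            )
        for a, b in zip(sites, sites[1:]):  # non-overlap, sorted
            assert a.target_end <= b.target_start

    def test_short_transcript_empty(self):
        assert find_candidate_sites(SRNA, "ACGT") == []


class TestPredictTargets:
    def test_concat_scan_matches_single_transcript_scan(self, rng):
        scheme = PenaltyScheme()
        srnas = {f"s{i}": random_seq(rng, 21) for i in range(3)}
        transcripts = {f"t{i}": random_seq(rng, 600) for i in range(4)}
        # plant one perfect site
        transcripts["t1"] = (
            transcripts["t1"][:100] + revcomp(srnas["s0"]) + transcripts["t1"][121:]
        )
        concat_hits = {
            (a.srna_id, a.target_id, a.target_start, round(a.score, 4))
            for a in iter_candidates_concat(srnas, transcripts, scheme)
        }
        single_hits = set()
        for sid, seq in srnas.items():
            for tid, t in transcripts.items():
                for a in find_candidate_sites(seq, t, scheme, sid, tid):
                    single_hits.add((sid, tid, a.target_start, round(a.score, 4)))
        assert concat_hits == single_hits
        assert ("s0", "t1", 100, 0.0) in concat_hits

    def test_planted_perfect_sites_all_reported(self, rng):
        srnas = {}
        transcripts = {}
        for i in range(10):
            s = random_seq(rng, 21)
            t = random_seq(rng, 300)
            srnas[f"s{i}"] = s
            transcripts[f"t{i}"] = t[:120] + revcomp(s) + t[141:]
        df = predict_targets(srnas, transcripts)
        perfect = df[df["mispair_score"] == 0.0]
        assert len(perfect) >= 10
        for i in range(10):
            row = perfect[(perfect.srna_id == f"s{i}") & (perfect.transcript_id == f"t{i}")]
            assert len(row) == 1
            assert int(row.iloc[0]["cleavage_site"]) == 120 + 12

    def test_deterministic_and_empty(self, rng):
        srnas = {"s": random_seq(rng, 21)}
        transcripts = {"t": random_seq(rng, 500)}
        df1 = predict_targets(srnas, transcripts)
        df2 = predict_targets(srnas, transcripts)
        assert df1.equals(df2)
        assert len(predict_targets({}, transcripts)) == 0
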