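"""Ground-truth generator: determinism, planted structure, count models."""

import numpy as np
import pytest

from phasiscan.seqtools import revcomp
from phasiscan.synthetic import (
    SyntheticConfig,
    generate_reference,
    simulate_degradome_library,
    simulate_srna_library,
)


class TestConfigValidation:
    def test_precursor_too_short(self):
        with pytest.raises(ValueError):
            SyntheticConfig(precursor_len=150, cycles_per_locus=10, n_phas21=1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"five_prime_c_bias": 1.5},
            {"mutant_depletion_factor": 0.5},
            {"n_transcripts": -1},
            {"replicates": 0},
            {"triggers": {22: ("x", "ACGT" * 5)}},
        ],
    )
    def test_invalid_values(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestGenerateReference:
    def test_deterministic(self, small_config):
        r1, t1 = generate_reference(small_config)
        r2, t2 = generate_reference(small_config)
        assert r1.all() == r2.all()
        assert [x.sequence for x in t1.phasirnas] == [x.sequence for x in t2.phasirnas]
        assert [(x.transcript_id, x.cleavage_pos0) for x in t1.targets] == [
            (x.transcript_id, x.cleavage_pos0) for x in t2.targets
        ]

    def test_trigger_site_is_exact_complement(self, small_config):
        refs, truth = generate_reference(small_config)
        for locus in truth.loci:
            trig = small_config.triggers[locus.period][1]
            site = refs.precursors[locus.ref_id][locus.trigger_start : locus.trigger_end]
            assert site == revcomp(trig)
            # cleavage position pairs trigger position 10
            assert locus.cleavage_pos0 == locus.trigger_end - 10
            assert locus.register == locus.cleavage_pos0 % locus.period

    def test_phased_registers(self, small_config):
        _refs, truth = generate_reference(small_config)
        for locus in truth.loci:
            for pos in locus.plus_positions:
                assert pos % locus.period == locus.register
            for pos in locus.minus_positions:
                assert (pos + 2) % locus.period == locus.register

    def test_planted_target_geometry(self, small_config):
        refs, truth = generate_reference(small_config)
        assert len(truth.targets) == small_config.n_planted_targets
        transcripts_used = [t.transcript_id for t in truth.targets]
        assert len(set(transcripts_used)) == len(transcripts_used)
        for t in truth.targets:
            seq = refs.transcripts[t.transcript_id]
            site = seq[t.site_start0 : t.site_start0 + 21]
            assert site == revcomp(t.srna_sequence)
            assert t.cleavage_pos0 == t.site_start0 + 11

    def test_full_c_bias_forces_all_21nt_starts(self):
        cfg = SyntheticConfig(
            seed=2, five_prime_c_bias=1.0, n_phas21=5, n_phas24=1,
            n_transcripts=8, n_planted_targets=4, n_intergenic=0,
        )
        _refs, truth = generate_reference(cfg)
        for x in truth.phasirnas:
            if x.period == 21:
                assert x.sequence.startswith("C")


class TestSimulateSrnaLibrary:
    def test_deterministic(self, small_config):
        refs, truth = generate_reference(small_config)
        libs1 = simulate_srna_library(refs, truth, small_config)
        libs2 = simulate_srna_library(refs, truth, small_config)
        assert libs1 == libs2

    def test_no_background_reads_all_phased(self):
        cfg = SyntheticConfig(
            seed=4, background_read_rate=0.0, n_phas21=3, n_phas24=0,
            n_transcripts=5, n_planted_targets=0, n_intergenic=0,
        )
        refs, truth = generate_reference(cfg)
        libs = simulate_srna_library(refs, truth, cfg)
        planted = {x.sequence for x in truth.phasirnas}
        for lib in libs.values():
            assert set(lib) <= planted

    def test_mutant_depletion_and_calibration(self):
        cfg = SyntheticConfig(
            seed=9, n_phas21=25, n_transcripts=5, n_planted_targets=0,
            n_intergenic=0, background_read_rate=0.0,
        )
        refs, truth = generate_reference(cfg)
        libs = simulate_srna_library(refs, truth, cfg)
        # 25 loci x 10 cycles x 2 strands x 3 replicates = 1500 samples/condition
        wt, mut = [], []
        for (condition, _rep), lib in libs.items():
            for x in truth.phasirnas:
                (wt if condition == "wildtype" else mut).append(lib.get(x.sequence, 0))
        assert np.mean(wt) == pytest.approx(cfg.phased_read_mean, rel=0.05)
        assert np.mean(mut) == pytest.approx(
            cfg.phased_read_mean / cfg.mutant_depletion_factor, rel=0.1
        )
        assert truth.phasirnas[0].mean_wildtype == cfg.phased_read_mean
        assert truth.phasirnas[0].mean_mutant == cfg.phased_read_mean / 4

    def test_reads_are_exact_reference_matches(self, small_config):
        refs, truth = generate_reference(small_config)
        libs = simulate_srna_library(refs, truth, small_config)
        merged = "#".join(refs.all().values())
        lib = libs[("wildtype", 1)]
        for seq in list(lib)[:200]:
            assert seq in merged or revcomp(seq) in merged


class TestSimulateDegradome:
    def test_tags_are_transcript_substrings(self, small_config):
        refs, truth = generate_reference(small_config)
        tags = simulate_degradome_library(refs, truth, small_config)
        assert tags
        for t in tags[:300]:
            seq = refs.transcripts[t.transcript_id]
            assert t.sequence == seq[t.position - 1 : t.position - 1 + 20]
            assert len(t.sequence) == 20

    def test_empty_when_everything_off(self):
        cfg = SyntheticConfig(
            seed=3, degradome_spike_mean=0.0, degradome_background_mean=0.0,
            n_phas21=2, n_transcripts=5, n_planted_targets=2, n_intergenic=0,
        )
        refs, truth = generate_reference(cfg)
        assert simulate_degradome_library(refs, truth, cfg) == []

    def test_planted_site_is_unique_maximum(self):
        """Monte-Carlo under the stated model: spike 50 vs decaying
        background of mean <= 1/position dominates in >= 95% of runs."""
        hits = total = 0
        for seed in range(1, 101):
            cfg = SyntheticConfig(
                seed=seed, n_phas21=2, n_transcripts=3, n_planted_targets=2,
                n_intergenic=0,
            )
            refs, truth = generate_reference(cfg)
            tags = simulate_degradome_library(refs, truth, cfg)
            by_transcript: dict[str, dict[int, int]] = {}
            for t in tags:
                by_transcript.setdefault(t.transcript_id, {})[t.position] = t.count
            for target in truth.targets:
                total += 1
                prof = by_transcript.get(target.transcript_id, {})
                site_count = prof.get(target.cleavage_site, 0)
                mx = max(prof.values(), default=0)
                if site_count == mx and list(prof.values()).count(mx) == 1:
                    hits += 1
        assert hits / total >= 0.95

    def test_unvalidatable_site_near_three_prime_end(self, small_config):
        refs, truth = generate_reference(small_config)
        victim = truth.targets[0]
        victim.cleavage_pos0 = len(refs.transcripts[victim.transcript_id]) - 5
        with pytest.warns(UserWarning):
            simulate_degradome_library(refs, truth, small_config)
        assert victim.validatable is False
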