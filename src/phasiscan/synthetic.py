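"""Synthetic sRNA / degradome data with planted, fully known ground truth.

The generator realizes the canonical phasiRNA biogenesis model: a trigger
miRNA cleaves a long non-coding precursor between the bases paired with
trigger positions 10 and 11; the downstream fragment is copied into
double-stranded RNA and diced processively into 21- or 24-nt siRNAs, so
siRNA 5' ends fall on a fixed register (mod period) downstream of the
cleavage site.  Emulated features of real libraries:

* phased read registers on both strands downstream of the planted
  trigger-cleavage site (minus-strand 5' ends offset by -2 nt from the
  register, matching the detector's +2 shift convention);
* a strong 5'-cytosine bias of 21-nt phasiRNAs (the precursor base at a
  phased 5' position is edited to C/G with probability
  ``five_prime_c_bias`` so reads remain exact reference matches);
* unphased background sRNAs of 18-30 nt scattered uniformly over the
  whole reference, including "intergenic" contigs that belong to the
  mapping reference but not to the target-prediction transcriptome;
* degradome tag profiles with a geometric background decay from the 5'
  end plus Poisson spikes at planted cleavage sites;
* replicate count variation between a wild-type and a depleted "mutant"
  condition (Poisson by default, negative binomial when ``dispersion``
  is set).

All randomness derives from ``config.seed``; a fixed configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .seqtools import random_seq, revcomp

CONDITIONS = ("wildtype", "mutant")

#: default trigger miRNAs (synthetic sequences).  The 21-nt trigger carries
#: G at position 10 and C at position 12 so that the cycle-0 phasiRNAs,
#: whose 5' bases fall inside the (never edited) trigger site, still begin
#: with C when the 5'-C bias is active.
DEFAULT_TRIGGERS: dict[int, tuple[str, str]] = {
    21: ("miR2118-like", "TTGCAATCCGTCACCAATCCT"),
    24: ("miR2275-like", "TTCAGTTTGTTCTCCTCCGATA"),
}


@dataclass
class SyntheticConfig:
    """Study conditions of a synthetic run; defaults define the benchmark."""

    seed: int = 1
    n_transcripts: int = 60
    transcript_len_range: tuple[int, int] = (900, 1600)
    n_intergenic: int = 10
    intergenic_len: int = 50_000
    n_phas21: int = 20
    n_phas24: int = 0
    cycles_per_locus: int = 10
    precursor_len: int | None = None
    triggers: dict[int, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_TRIGGERS)
    )
    five_prime_c_bias: float = 0.9
    phased_read_mean: float = 20.0
    background_read_rate: float = 0.05
    n_planted_targets: int = 50
    degradome_spike_mean: float = 50.0
    degradome_background_mean: float = 1.0
    degradome_decay_rate: float = 0.005
    replicates: int = 3
    mutant_depletion_factor: float = 4.0
    dispersion: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = (
            self.n_transcripts,
            self.n_intergenic,
            self.n_phas21,
            self.n_phas24,
            self.n_planted_targets,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.five_prime_c_bias <= 1.0:
            raise ValueError("five_prime_c_bias must be a probability")
        if self.cycles_per_locus < 3:
            raise ValueError("cycles_per_locus must be at least 3")
        if self.replicates < 1:
            raise ValueError("at least one replicate required")
        if self.mutant_depletion_factor < 1.0:
            raise ValueError("mutant_depletion_factor must be >= 1")
        if min(self.phased_read_mean, self.background_read_rate) < 0:
            raise ValueError("rates must be non-negative")
        for period in self.triggers:
            if period not in (21, 24):
                raise ValueError(f"phase period must be 21 or 24, got {period}")
        if self.precursor_len is not None:
            for period, n in ((21, self.n_phas21), (24, self.n_phas24)):
                if n == 0:
                    continue
                site = len(self.triggers[period][1])
                if self.precursor_len < site + self.cycles_per_locus * period:
                    raise ValueError(
                        f"precursor length {self.precursor_len} shorter than "
                        f"trigger site + {self.cycles_per_locus} x {period} nt"
                    )


@dataclass
class PlantedLocus:
    ref_id: str
    period: int
    trigger_name: str
    trigger_start: int  # 0-based, half-open site coordinates
    trigger_end: int
    cleavage_pos0: int
    register: int
    plus_positions: list[int]
    minus_positions: list[int]


@dataclass
class PlantedPhasiRNA:
    ref_id: str
    strand: str
    position: int  # forward coordinate of the 5' end
    period: int
    sequence: str
    forced_c: bool
    mean_wildtype: float = 0.0
    mean_mutant: float = 0.0


@dataclass
class PlantedTarget:
    transcript_id: str
    srna_sequence: str
    source_ref: str
    source_position: int
    site_start0: int
    cleavage_pos0: int
    validatable: bool = True

    @property
    def cleavage_site(self) -> int:
        """1-based cleavage (+1) coordinate on the target."""
        return self.cleavage_pos0 + 1


@dataclass
class GroundTruth:
    loci: list[PlantedLocus] = field(default_factory=list)
    phasirnas: list[PlantedPhasiRNA] = field(default_factory=list)
    targets: list[PlantedTarget] = field(default_factory=list)


@dataclass
class RefSet:
    """The synthetic reference: precursors + transcriptome + intergenic."""

    precursors: dict[str, str] = field(default_factory=dict)
    transcripts: dict[str, str] = field(default_factory=dict)
    intergenic: dict[str, str] = field(default_factory=dict)

    def all(self) -> dict[str, str]:
        merged: dict[str, str] = {}
        merged.update(self.precursors)
        merged.update(self.transcripts)
        merged.update(self.intergenic)
        return merged

    def total_length(self) -> int:
        return sum(len(s) for s in self.all().values())


def _phased_positions(c0: int, period: int, cycles: int) -> tuple[list[int], list[int]]:
    plus = [c0 + j * period for j in range(cycles)]
    minus = [c0 + j * period - 2 for j in range(cycles)]
    return plus, minus


def generate_reference(config: SyntheticConfig) -> tuple[RefSet, GroundTruth]:
    """Build the reference set and the ground-truth skeleton.

    Each precursor embeds one exact reverse complement of its trigger
    miRNA; the implied cleavage position (precursor base paired with
    trigger position 10) fixes the phase register.  For 21-nt loci the
    5'-C bias is realized here by editing the precursor base at phased 5'
    positions (plus strand -> C, minus strand -> G), never inside the
    trigger site.  Planted targets copy the exact reverse complement of a
    plus-strand 21-nt phasiRNA into a transcript (at most one per
    transcript) and record the implied cleavage coordinate.
    """
    rng = np.random.default_rng([config.seed, 0])
    refs = RefSet()
    truth = GroundTruth()
    for period, n_loci in ((21, config.n_phas21), (24, config.n_phas24)):
        if n_loci == 0:
            continue
        name, trig = config.triggers[period]
        site = revcomp(trig)
        lt = len(site)
        for i in range(n_loci):
            if config.precursor_len is None:
                trig_off = int(rng.integers(15, 41))
                length = trig_off + lt + config.cycles_per_locus * period + 40
            else:
                length = config.precursor_len
                max_off = length - lt - config.cycles_per_locus * period
                trig_off = int(rng.integers(0, min(41, max_off + 1)))
            ref_id = f"PRE{period}_{i + 1:04d}"
            seq = list(random_seq(rng, length))
            seq[trig_off : trig_off + lt] = site
            c0 = trig_off + lt - 10
            register = c0 % period
            plus, minus = _phased_positions(c0, period, config.cycles_per_locus)
            phas_records = []
            for strand, positions, base in (("+", plus, "C"), ("-", minus, "G")):
                for pos in positions:
                    forced = False
                    if period == 21 and rng.random() < config.five_prime_c_bias:
                        if not (trig_off <= pos < trig_off + lt):
                            seq[pos] = base
                        forced = True
                    phas_records.append((strand, pos, forced))
            seqstr = "".join(seq)
            refs.precursors[ref_id] = seqstr
            truth.loci.append(
                PlantedLocus(
                    ref_id,
                    period,
                    name,
                    trig_off,
                    trig_off + lt,
                    c0,
                    register,
                    plus,
                    minus,
                )
            )
            for strand, pos, forced in phas_records:
                if strand == "+":
                    s = seqstr[pos : pos + period]
                else:
                    s = revcomp(seqstr[pos - period + 1 : pos + 1])
                truth.phasirnas.append(
                    PlantedPhasiRNA(ref_id, strand, pos, period, s, forced)
                )
    lo, hi = config.transcript_len_range
    t_lens = rng.integers(lo, hi + 1, config.n_transcripts)
    t_ids = [f"T{i + 1:04d}" for i in range(config.n_transcripts)]
    t_seqs = {tid: list(random_seq(rng, int(L))) for tid, L in zip(t_ids, t_lens)}
    if config.n_planted_targets:
        eligible = [
            x for x in truth.phasirnas if x.period == 21 and x.strand == "+"
        ]
        if config.n_planted_targets > len(eligible):
            raise ValueError("not enough planted 21-nt phasiRNAs for targets")
        if config.n_planted_targets > config.n_transcripts:
            raise ValueError("more planted targets than transcripts")
        srna_idx = rng.choice(len(eligible), config.n_planted_targets, replace=False)
        tr_idx = rng.choice(config.n_transcripts, config.n_planted_targets, replace=False)
        for si, ti in zip(srna_idx, tr_idx):
            phas = eligible[int(si)]
            tid = t_ids[int(ti)]
            tlen = len(t_seqs[tid])
            if tlen < 100:
                raise ValueError("transcripts must be >= 100 nt to plant targets")
            u = int(rng.integers(30, tlen - 60))
            site = revcomp(phas.sequence)
            t_seqs[tid][u : u + len(site)] = site
            truth.targets.append(
                PlantedTarget(
                    transcript_id=tid,
                    srna_sequence=phas.sequence,
                    source_ref=phas.ref_id,
                    source_position=phas.position,
                    site_start0=u,
                    cleavage_pos0=u + len(site) - 10,
                )
            )
    refs.transcripts = {tid: "".join(s) for tid, s in t_seqs.items()}
    for i in range(config.n_intergenic):
        refs.intergenic[f"IG{i + 1:02d}"] = random_seq(rng, config.intergenic_len)
    return refs, truth


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float | None) -> int:
    if mean <= 0:
        return 0
    if dispersion is None:
        return int(rng.poisson(mean))
    # negative binomial as gamma-Poisson with shape 1/dispersion
    lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    return int(rng.poisson(lam))


def simulate_srna_library(
    refs: RefSet, truth: GroundTruth, config: SyntheticConfig
) -> dict[tuple[str, int], dict[str, int]]:
    """Draw collapsed sRNA libraries for every condition and replicate.

    Phased reads get independent per-replicate counts around
    ``phased_read_mean`` (divided by the depletion factor in the mutant);
    background reads of 18-30 nt are scattered uniformly over the whole
    reference at ``background_read_rate`` expected reads per nucleotide.
    True condition-wise means are recorded on the ground truth.
    """
    rng = np.random.default_rng([config.seed, 1])
    allrefs = refs.all()
    ref_ids = list(allrefs)
    lengths = np.array([len(allrefs[r]) for r in ref_ids])
    starts = np.concatenate(([0], np.cumsum(lengths)))
    total_len = int(starts[-1])
    for phas in truth.phasirnas:
        phas.mean_wildtype = config.phased_read_mean
        phas.mean_mutant = config.phased_read_mean / config.mutant_depletion_factor
    libraries: dict[tuple[str, int], dict[str, int]] = {}
    for condition in CONDITIONS:
        depletion = config.mutant_depletion_factor if condition == "mutant" else 1.0
        for rep in range(1, config.replicates + 1):
            lib: dict[str, int] = {}
            for phas in truth.phasirnas:
                c = _draw_count(
                    rng, config.phased_read_mean / depletion, config.dispersion
                )
                if c > 0:
                    lib[phas.sequence] = lib.get(phas.sequence, 0) + c
            n_bg = int(rng.poisson(config.background_read_rate * total_len))
            if n_bg:
                offs = rng.integers(0, total_len, n_bg)
                lens = rng.integers(18, 31, n_bg)
                strands = rng.integers(0, 2, n_bg)
                ridx = np.searchsorted(starts, offs, side="right") - 1
                for o, L, st, ri in zip(offs, lens, strands, ridx):
                    local = int(o - starts[ri])
                    seq = allrefs[ref_ids[int(ri)]]
                    if local + int(L) > len(seq):
                        continue
                    sub = seq[local : local + int(L)]
                    if st == 1:
                        sub = revcomp(sub)
                    lib[sub] = lib.get(sub, 0) + 1
            libraries[(condition, rep)] = lib
    return libraries


def simulate_degradome_library(
    refs: RefSet, truth: GroundTruth, config: SyntheticConfig
):
    """Draw degradome tags over the transcriptome.

    Background tag counts at position i (0-based) are Poisson with mean
    ``degradome_background_mean * (1 - degradome_decay_rate)**i``; planted
    cleavage coordinates receive an extra Poisson spike.  Tags are the
    20-nt transcript substring starting at their 5' position; positions
    within 20 nt of the 3' end emit no tag, and a planted site falling
    there is marked unvalidatable with a warning.
    """
    from .degradome import DegradomeTag

    rng = np.random.default_rng([config.seed, 2])
    counts: dict[tuple[str, int], int] = {}
    for tid in sorted(refs.transcripts):
        seq = refs.transcripts[tid]
        n_pos = len(seq) - 20 + 1
        if n_pos <= 0:
            continue
        lam = config.degradome_background_mean * (
            1.0 - config.degradome_decay_rate
        ) ** np.arange(n_pos)
        draws = rng.poisson(lam)
        for pos in np.nonzero(draws)[0]:
            counts[(tid, int(pos))] = counts.get((tid, int(pos)), 0) + int(draws[pos])
    for target in truth.targets:
        seq = refs.transcripts[target.transcript_id]
        if target.cleavage_pos0 > len(seq) - 20:
            warnings.warn(
                f"planted cleavage site {target.transcript_id}:{target.cleavage_site} "
                "within 20 nt of the 3' end; skipped"
            )
            target.validatable = False
            continue
        spike = int(rng.poisson(config.degradome_spike_mean))
        if spike > 0:
            key = (target.transcript_id, target.cleavage_pos0)
            counts[key] = counts.get(key, 0) + spike
    tags = [
        DegradomeTag(
            transcript_id=tid,
            position=pos + 1,
            count=c,
            sequence=refs.transcripts[tid][pos : pos + 20],
        )
        for (tid, pos), c in sorted(counts.items())
    ]
    return tags
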