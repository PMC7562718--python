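"""Phased siRNA (PHAS) locus detection from small-RNA position profiles.

A PHAS locus emits siRNAs whose 5' ends fall on a fixed register modulo
the phasing period (21 or 24 nt), set by the trigger-miRNA cleavage site
on the precursor.  Detection slides a nine-cycle window (9 x period nt)
along each reference and contrasts in-register against off-register
abundance of period-length reads with the log phase score

    score = ln[(1 + 10 * P / (1 + U)) ** (k - 2)],   k >= 3, else 0

where P is the summed read count at occupied phase positions, U the
summed count at off-phase positions, and k the number of occupied
(position, strand) phase slots (at most 18: nine cycles on two strands).
Minus-strand reads are counted in-register when their 5' position shifted
by +2 nt matches the register, the 2-nt 3'-overhang convention of dicer
duplex products.

Loci are reported from overlapping qualifying windows of equal register,
named with a period-tagged prefix (e.g. 21PHAS0007), and their member
phasiRNAs as "<locus>_<offset><strand>" where offset is the 5'-end
distance from the locus start on the forward strand.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .seqtools import revcomp
from .srna import PositionProfile
from .targets import DuplexAlignment, PenaltyScheme, find_candidate_sites

PERIODS = (21, 24)
MINUS_STRAND_SHIFT = 2  # nt added to minus-strand 5' positions before register test
CYCLES_PER_WINDOW = 9


@dataclass
class PhaseWindowStat:
    """Phase statistics of one nine-cycle window at one register."""

    reference_id: str
    start: int
    period: int
    register: int
    k: int
    phased_abundance: float  # P
    unphased_abundance: float  # U
    score: float


@dataclass
class TriggerAnnotation:
    mirna: str
    site_start: int  # 0-based on the precursor
    site_end: int
    score: float
    cleavage_pos0: int | None
    register_consistent: bool
    secondary: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class PhasLocus:
    locus_id: str
    reference_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    period: int
    register: int
    strand: str
    max_score: float
    max_k: int
    trigger: TriggerAnnotation | None = None
    n_offlength_inregister: int = 0


@dataclass
class PhasiRNA:
    name: str
    locus_id: str
    offset: int
    strand: str
    position: int  # forward coordinate of the 5' end
    sequence: str
    count: float
    abundances: dict[str, float] = field(default_factory=dict)


_NAME_RE = re.compile(r"^(\d+PHAS\d+)_(\d+)([+-])$")


def parse_phasirna_name(name: str) -> tuple[str, int, str]:
    """Split "<locus>_<offset><strand>" back into its parts."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a phasiRNA name: {name}")
    return m.group(1), int(m.group(2)), m.group(3)


def phase_score(k: int, phased: float, unphased: float) -> float:
    """The nine-cycle-window phase score; zero when fewer than 3 slots occupied."""
    if k < 3:
        return 0.0
    return (k - 2) * math.log1p(10.0 * phased / (1.0 + unphased))


def effective_position(strand: str, pos: int) -> int:
    """5' position used for register comparison (+2 shift on the minus strand)."""
    return pos if strand == "+" else pos + MINUS_STRAND_SHIFT


def phase_score_window(
    profile: PositionProfile,
    reference_id: str,
    start: int,
    period: int,
    register: int,
    reference_length: int | None = None,
) -> PhaseWindowStat:
    """Score one nine-cycle window at a fixed register.

    Only reads of length == period contribute; k counts occupied
    (position, strand) phase slots.
    """
    if period not in PERIODS:
        raise ValueError(f"period must be one of {PERIODS}, got {period}")
    window = CYCLES_PER_WINDOW * period
    if start < 0 or (reference_length is not None and start + window > reference_length):
        raise ValueError("window overruns the reference")
    k = 0
    P = 0.0
    U = 0.0
    for strand, pos, _ln, c in profile.positions(reference_id, period):
        e = effective_position(strand, pos)
        if not (start <= e < start + window):
            continue
        if e % period == register % period:
            k += 1
            P += c
        else:
            U += c
    return PhaseWindowStat(
        reference_id, start, period, register % period, k, P, U, phase_score(k, P, U)
    )


def _rolling(a: np.ndarray, w: int) -> np.ndarray:
    cs = np.concatenate(([0.0], np.cumsum(a)))
    return cs[w:] - cs[:-w]


def _window_scores(
    profile: PositionProfile, reference_id: str, period: int, ref_len: int
):
    """Vectorized (best-register) window scores over one reference.

    Returns (starts considered implicitly 0..n_s-1, best_score, best_k,
    best_register) or None when the reference is shorter than one window
    or carries no period-length reads.
    """
    W = CYCLES_PER_WINDOW * period
    n_s = ref_len - W + 1
    if n_s <= 0:
        return None
    pad = ref_len + MINUS_STRAND_SHIFT + 1
    eff = np.zeros(pad)
    occ_p = np.zeros(pad, dtype=bool)
    occ_m = np.zeros(pad, dtype=bool)
    any_read = False
    for strand, pos, _ln, c in profile.positions(reference_id, period):
        e = effective_position(strand, pos)
        if e >= pad:
            continue
        eff[e] += c
        if strand == "+":
            occ_p[e] = True
        else:
            occ_m[e] = True
        any_read = True
    if not any_read:
        return None
    occ = occ_p.astype(np.float64) + occ_m.astype(np.float64)
    tot = _rolling(eff, W)[:n_s]
    s_arr = np.arange(n_s)
    scores = np.zeros((period, n_s))
    ks = np.zeros((period, n_s))
    for r in range(period):
        c_r = eff[r::period]
        o_r = occ[r::period]
        if len(c_r) < CYCLES_PER_WINDOW:
            continue
        P9 = _rolling(c_r, CYCLES_PER_WINDOW)
        K9 = _rolling(o_r, CYCLES_PER_WINDOW)
        idx = (s_arr - r + period - 1) // period
        idx = np.clip(idx, 0, len(P9) - 1)
        P = P9[idx]
        K = ks[r] = K9[idx]
        U = np.maximum(tot - P, 0.0)
        with np.errstate(divide="ignore"):
            scores[r] = np.where(
                K >= 3, (K - 2) * np.log1p(10.0 * P / (1.0 + U)), 0.0
            )
    best_r = scores.argmax(axis=0)
    best_score = scores[best_r, s_arr]
    best_k = ks[best_r, s_arr]
    return best_score, best_k, best_r


def scan_phas_loci(
    profile: PositionProfile,
    period: int,
    score_threshold: float = 15.0,
    min_phased_positions: int = 4,
    reference_lengths: Mapping[str, int] | None = None,
) -> list[PhasLocus]:
    """Slide the nine-cycle window over every reference and call loci.

    For each window start the best register is taken; windows with
    score >= threshold and k >= min_phased_positions are merged when they
    overlap with equal register.  Each locus spans from the first to the
    last in-register read and reports the maximal window score.  Locus ids
    are assigned in (reference, start) order as <period>PHAS<number>.
    """
    if period not in PERIODS:
        raise ValueError(f"period must be one of {PERIODS}, got {period}")
    W = CYCLES_PER_WINDOW * period
    refs = sorted({key[0] for key in profile.counts})
    raw: list[PhasLocus] = []
    for ref in refs:
        if reference_lengths is not None and ref in reference_lengths:
            ref_len = reference_lengths[ref]
        else:
            ref_len = (
                max(pos for _s, pos, _l, _c in profile.positions(ref)) + period + 1
            )
        res = _window_scores(profile, ref, period, ref_len)
        if res is None:
            continue
        best_score, best_k, best_r = res
        passing = np.nonzero(
            (best_score >= score_threshold) & (best_k >= min_phased_positions)
        )[0]
        if len(passing) == 0:
            continue
        groups: list[list[int]] = []
        for s in passing:
            if (
                groups
                and s - groups[-1][-1] <= W - 1
                and best_r[s] == best_r[groups[-1][-1]]
            ):
                groups[-1].append(int(s))
            else:
                groups.append([int(s)])
        for g in groups:
            r = int(best_r[g[0]])
            span_lo, span_hi = g[0], g[-1] + W
            members = _member_reads(profile, ref, period, r, span_lo, span_hi)
            if not members:
                continue
            left = min(m[3] for m in members)
            right = max(m[4] for m in members)
            raw.append(
                PhasLocus(
                    locus_id="",
                    reference_id=ref,
                    start=left,
                    end=right + 1,
                    period=period,
                    register=r,
                    strand=_dominant_strand(members),
                    max_score=float(best_score[g].max()),
                    max_k=int(best_k[g].max()),
                )
            )
    raw.sort(key=lambda L: (L.reference_id, L.start))
    for i, locus in enumerate(raw, start=1):
        locus.locus_id = f"{period}PHAS{i:04d}"
    return raw


def _member_reads(profile, ref, period, register, span_lo, span_hi):
    """In-register period-length reads with effective 5' in [span_lo, span_hi)."""
    members = []
    for strand, pos, _ln, c in profile.positions(ref, period):
        e = effective_position(strand, pos)
        if span_lo <= e < span_hi and e % period == register:
            left = pos if strand == "+" else pos - period + 1
            right = pos + period - 1 if strand == "+" else pos
            members.append((strand, pos, c, left, right))
    return members


def _dominant_strand(members) -> str:
    plus = sum(c for s, _p, c, _l, _r in members if s == "+")
    minus = sum(c for s, _p, c, _l, _r in members if s == "-")
    return "+" if plus >= minus else "-"


def enumerate_phasirnas(
    locus: PhasLocus,
    profile: PositionProfile,
    reference: Mapping[str, str],
    sample_profiles: Mapping[str, PositionProfile] | None = None,
) -> list[PhasiRNA]:
    """Name and sequence every in-register period-length read of a locus.

    Reads that sit in register but have a length other than the locus
    period are excluded and counted in ``locus.n_offlength_inregister``.
    Per-sample raw counts are attached when ``sample_profiles`` is given.
    """
    refseq = reference[locus.reference_id]
    p = locus.period
    out: list[PhasiRNA] = []
    excluded = 0
    for strand, pos, ln, c in profile.positions(locus.reference_id):
        e = effective_position(strand, pos)
        if not (locus.start <= e < locus.end) or e % p != locus.register:
            continue
        if ln != p:
            excluded += 1
            continue
        if strand == "+":
            seq = refseq[pos : pos + p]
        else:
            seq = revcomp(refseq[pos - p + 1 : pos + 1])
        offset = pos - locus.start
        name = f"{locus.locus_id}_{offset}{strand}"
        abund = {}
        if sample_profiles:
            for lib, sp in sample_profiles.items():
                abund[lib] = sp.get(locus.reference_id, strand, pos, p)
        out.append(PhasiRNA(name, locus.locus_id, offset, strand, pos, seq, c, abund))
    locus.n_offlength_inregister = excluded
    out.sort(key=lambda x: (x.position, x.strand))
    return out


def annotate_trigger(
    locus: PhasLocus,
    precursor_sequence: str,
    trigger_mirnas: Mapping[str, str],
    max_score: float = 3.5,
    scheme: PenaltyScheme | None = None,
) -> TriggerAnnotation | None:
    """Find the best trigger-miRNA site on the locus precursor.

    Each trigger is aligned with the mispair scheme; if the best site
    scores <= max_score the annotation reports the site, the implied
    cleavage position (the precursor base paired with trigger position
    10), and whether the locus register is consistent with phasing
    initiated at that cleavage site.  Lower score wins; other qualifying
    triggers are listed as secondary.
    """
    scheme = scheme or PenaltyScheme()
    hits: list[tuple[float, int, str, DuplexAlignment]] = []
    for order, (name, seq) in enumerate(trigger_mirnas.items()):
        sites = find_candidate_sites(
            seq, precursor_sequence, scheme, srna_id=name, transcript_id=locus.reference_id
        )
        sites = [s for s in sites if s.score <= max_score]
        if sites:
            best = min(sites, key=lambda s: (s.score, s.target_start))
            hits.append((best.score, order, name, best))
    if not hits:
        return None
    hits.sort(key=lambda h: (h[0], h[1]))
    score, _order, name, site = hits[0]
    consistent = (
        site.cleavage_pos0 is not None
        and site.cleavage_pos0 % locus.period == locus.register
    )
    return TriggerAnnotation(
        mirna=name,
        site_start=site.target_start,
        site_end=site.target_end,
        score=score,
        cleavage_pos0=site.cleavage_pos0,
        register_consistent=consistent,
        secondary=[(h[2], h[0]) for h in hits[1:]],
    )
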