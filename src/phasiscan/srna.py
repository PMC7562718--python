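"""Small-RNA read filtering, exact mapping, and descriptive summaries.

Reads are collapsed (unique sequence + count).  Mapping is exact-match
only, on both strands, mirroring a no-mismatch short-read aligner run in
report-all mode.  Coordinates are 0-based internally; the 5' position of a
minus-strand placement is the forward coordinate of its biological 5' end,
i.e. ``leftmost + length - 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .seqtools import is_unambiguous, normalize, revcomp


@dataclass(frozen=True)
class SmallRNARead:
    """A collapsed small-RNA read: unique sequence with a library count."""

    sequence: str
    count: int = 1

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignedRead:
    """One exact placement of a read on the reference.

    ``start`` is the forward-strand coordinate of the read's 5' end
    (0-based).  ``weight`` implements the multi-mapping policy; with
    ``n_placements`` recorded, ``count / n_placements`` sums to the read's
    library count over all its placements regardless of policy.
    """

    reference_id: str
    start: int
    strand: str
    length: int
    count: int
    weight: float
    n_placements: int
    sequence: str

    @property
    def leftmost(self) -> int:
        return self.start if self.strand == "+" else self.start - self.length + 1

    @property
    def rightmost(self) -> int:
        """Inclusive rightmost forward coordinate covered by the read."""
        return self.start + self.length - 1 if self.strand == "+" else self.start


class PositionProfile:
    """Per-reference, per-strand 5'-end counts stratified by read length.

    ``library_total`` is the total mapped read count with every read copy
    counted once (multi-mapping placements share the count), which is the
    reads-per-million denominator used throughout.
    """

    def __init__(self) -> None:
        self.counts: dict[tuple[str, str, int, int], float] = {}
        self.library_total: float = 0.0
        self._by_ref: dict[str, list[tuple[str, int, int, float]]] | None = None

    def add(self, ref: str, strand: str, pos: int, length: int, value: float) -> None:
        key = (ref, strand, pos, length)
        self.counts[key] = self.counts.get(key, 0.0) + value
        self._by_ref = None

    def get(self, ref: str, strand: str, pos: int, length: int) -> float:
        return self.counts.get((ref, strand, pos, length), 0.0)

    def total(self) -> float:
        return sum(self.counts.values())

    def positions(self, ref: str, length: int | None = None):
        """Yield (strand, pos, length, count) tuples on one reference."""
        if self._by_ref is None:
            by_ref: dict[str, list[tuple[str, int, int, float]]] = {}
            for (r, strand, pos, ln), c in self.counts.items():
                by_ref.setdefault(r, []).append((strand, pos, ln, c))
            self._by_ref = by_ref
        for strand, pos, ln, c in self._by_ref.get(ref, ()):
            if length is None or ln == length:
                yield strand, pos, ln, c


def collapse_reads(reads: Iterable[SmallRNARead]) -> list[SmallRNARead]:
    """Merge duplicate sequences, summing counts (deterministic order)."""
    acc: dict[str, int] = {}
    for r in reads:
        s = normalize(r.sequence)
        acc[s] = acc.get(s, 0) + r.count
    return [SmallRNARead(s, c) for s, c in acc.items()]


def filter_reads(
    reads: Sequence[SmallRNARead], min_len: int = 18, max_len: int = 30
) -> list[SmallRNARead]:
    """Retain reads with min_len <= length <= max_len (counts preserved)."""
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    return [r for r in reads if min_len <= r.length <= max_len]


def align_exact(
    reads: Sequence[SmallRNARead],
    reference: Mapping[str, str],
    policy: str = "count-all",
) -> tuple[list[AlignedRead], list[SmallRNARead]]:
    """Report every exact occurrence of each read on either strand.

    Returns (placements, unmapped).  ``policy`` is "count-all" (weight 1 at
    every placement) or "fractional" (weight 1/n over a read's placements).
    Reads containing ambiguity codes are skipped with a warning.
    """
    if policy not in ("count-all", "fractional"):
        raise ValueError(f"unknown multi-mapping policy: {policy}")
    import numpy as np

    from .seqtools import encode

    clean: list[SmallRNARead | None] = []
    # seed index: collision-free base-4 code of the k-mer prefix of each
    # read orientation, with k = shortest read length
    seed_index: dict[int, list[tuple[int, str, str]]] = {}
    min_len = None
    oriented: list[tuple[int, str, str]] = []  # (read idx, orientation seq, strand)
    for i, r in enumerate(reads):
        s = normalize(r.sequence)
        if not is_unambiguous(s):
            warnings.warn(f"skipping read with ambiguous bases: {r.sequence}")
            clean.append(None)
            continue
        clean.append(SmallRNARead(s, r.count))
        min_len = len(s) if min_len is None else min(min_len, len(s))
        oriented.append((i, s, "+"))
        oriented.append((i, revcomp(s), "-"))
    hits: dict[int, list[tuple[str, str, int]]] = {}
    if oriented:
        k = min(min_len, 31)  # 4**31 < 2**63
        prefix_mat = encode("".join(s[:k] for _i, s, _st in oriented)).reshape(-1, k)
        vals = np.zeros(len(oriented), dtype=np.int64)
        for j in range(k):
            vals = vals * 4 + prefix_mat[:, j]
        vals[(prefix_mat >= 4).any(axis=1)] = -1
        for code, rec in zip(vals, oriented):
            seed_index.setdefault(int(code), []).append(rec)
        seed_index.pop(-1, None)
        keys = np.array(sorted(seed_index), dtype=np.int64)
        for ref_id, refseq in reference.items():
            S = normalize(refseq)
            n = len(S)
            if n < k or not keys.size:
                continue
            codes = encode(S).astype(np.int64)
            npos = n - k + 1
            H = np.zeros(npos, dtype=np.int64)
            for j in range(k):
                H = H * 4 + codes[j : j + npos]
            bad = codes >= 4
            if bad.any():  # windows containing ambiguity codes never match
                cs = np.concatenate(([0], np.cumsum(bad)))
                H[(cs[k:] - cs[:-k]) > 0] = -1
            # sorted-key membership (keys are exact k-mer codes, no collisions)
            idx = np.searchsorted(keys, H)
            idx[idx == len(keys)] = 0
            cand = np.nonzero(keys[idx] == H)[0]
            for p in cand:
                p = int(p)
                for i, s, strand in seed_index.get(int(H[p]), ()):
                    L = len(s)
                    if p + L <= n and S[p : p + L] == s:
                        pos5 = p if strand == "+" else p + L - 1
                        hits.setdefault(i, []).append((ref_id, strand, pos5))
    placements: list[AlignedRead] = []
    unmapped: list[SmallRNARead] = []
    for i, r in enumerate(clean):
        if r is None:
            continue
        locs = hits.get(i)
        if not locs:
            unmapped.append(r)
            continue
        n_loc = len(locs)
        w = 1.0 if policy == "count-all" else 1.0 / n_loc
        for ref_id, strand, pos in locs:
            placements.append(
                AlignedRead(ref_id, pos, strand, r.length, r.count, w, n_loc, r.sequence)
            )
    return placements, unmapped


def build_position_profile(aligned: Iterable[AlignedRead]) -> PositionProfile:
    """Accumulate weighted 5'-end counts into a PositionProfile."""
    prof = PositionProfile()
    for a in aligned:
        prof.add(a.reference_id, a.strand, a.start, a.length, a.count * a.weight)
        prof.library_total += a.count / a.n_placements
    return prof


def size_distribution(reads: Sequence[SmallRNARead]) -> dict[int, float]:
    """Count-weighted fraction of reads per length; fractions sum to 1."""
    totals: dict[int, int] = {}
    for r in reads:
        totals[r.length] = totals.get(r.length, 0) + r.count
    grand = sum(totals.values())
    if grand == 0:
        return {}
    return {ln: totals[ln] / grand for ln in sorted(totals)}


def five_prime_composition(
    reads: Sequence[SmallRNARead], length_class: int
) -> dict[str, float]:
    """Count-weighted 5'-nucleotide fractions within one length class.

    Keys use the RNA alphabet (A, C, G, U); empty dict when no reads match.
    """
    totals = {"A": 0, "C": 0, "G": 0, "U": 0}
    grand = 0
    for r in reads:
        if r.length != length_class:
            continue
        first = normalize(r.sequence)[0]
        first = "U" if first == "T" else first
        if first in totals:
            totals[first] += r.count
            grand += r.count
    if grand == 0:
        return {}
    return {b: c / grand for b, c in totals.items()}


def normalize_rpm(count: float, library_total: float) -> float:
    """Reads-per-million: count / library_total * 1e6."""
    if library_total <= 0:
        raise ValueError("library_total must be positive for RPM normalization")
    return count / library_total * 1e6


def normalize_rp10m(count: float, library_total: float) -> float:
    """Reads-per-ten-million, the degradome-tag normalization."""
    if library_total <= 0:
        raise ValueError("library_total must be positive for RP10M normalization")
    return count / library_total * 1e7
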