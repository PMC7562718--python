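"""sRNA:target complementarity scoring with the mispair penalty scheme.

The scheme is the plant-miRNA target-prediction convention: a mismatch,
gap or bulged nucleotide costs 1, a G:U wobble pair costs 0.5, and any
penalty incurred outside the core base-paired region (sRNA positions
2-17, 1-based from the 5' end) is halved.  Candidate sites are duplexes
with total score <= 3.5.  AGO slices its target between the nucleotides
paired with sRNA positions 10 and 11, so each alignment carries the
target coordinate paired with position 10 (the degradome "+1" site).

Two engines implement the same model and must agree exactly:

* :func:`score_duplex` - a small dynamic program over one target window
  with full traceback (global in the window);
* :func:`find_candidate_sites` / :func:`predict_targets` - a vectorized
  semi-global scan that scores every possible site end on a transcript in
  one pass and refines qualifying ends through :func:`score_duplex`.

Bulges are capped at ``max_bulges`` total nucleotides (default 2): with
each bulge costing at least 0.5 the cap already spends most of the 3.5
budget, and it keeps exhaustive enumeration (the test oracle) tractable.
Penalty attribution for a bulged target nucleotide uses the sRNA index of
the 5'-adjacent paired nucleotide (clamped to [1, n]); a bulged sRNA
nucleotide uses its own index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .seqtools import encode, normalize

BIG = 1e9

#: pair penalties indexed [sRNA base, target base]; column 5 is the
#: concatenation sentinel (never pairable), column 4 is N (mismatch).
PAIR_PENALTY = np.ones((5, 6))
for _s, _t in ((0, 3), (1, 2), (2, 1), (3, 0)):  # Watson-Crick
    PAIR_PENALTY[_s, _t] = 0.0
PAIR_PENALTY[2, 3] = 0.5  # sRNA G : target U
PAIR_PENALTY[3, 2] = 0.5  # sRNA U : target G
PAIR_PENALTY[:, 5] = BIG
PAIR_PENALTY[4, :] = 1.0
PAIR_PENALTY[4, 5] = BIG


@dataclass(frozen=True)
class PenaltyScheme:
    """Constants of the mispair scoring scheme."""

    mismatch_or_gap: float = 1.0
    gu_wobble: float = 0.5
    core_start: int = 2
    core_end: int = 17
    outside_core_multiplier: float = 0.5
    max_score: float = 3.5
    max_bulges: int = 2

    def __post_init__(self) -> None:
        if not (1 <= self.core_start <= self.core_end):
            raise ValueError("invalid core region")
        if min(self.mismatch_or_gap, self.gu_wobble) < 0:
            raise ValueError("penalties must be non-negative")

    def weight(self, srna_pos: int) -> float:
        """Positional multiplier for a penalty at 1-based sRNA position."""
        if self.core_start <= srna_pos <= self.core_end:
            return 1.0
        return self.outside_core_multiplier

    def gap_index(self, consumed: int, n: int) -> int:
        """sRNA index attributed to a target bulge after ``consumed`` bases."""
        return min(max(consumed, 1), n)


#: one duplex column: (kind, srna_pos or 0, target_pos or -1)
#: kinds: '|' Watson-Crick, 'o' G:U wobble, 'x' mismatch,
#:        '^' bulged sRNA nucleotide, '-' bulged target nucleotide
Column = tuple[str, int, int]


@dataclass
class DuplexAlignment:
    """An sRNA:target alignment under the mispair scheme.

    Target coordinates are 0-based on the transcript's forward strand;
    ``cleavage_pos0`` is the target base paired with sRNA position 10
    (None when that position is bulged or the sRNA is shorter than 10 nt).
    """

    srna_id: str
    srna_sequence: str
    target_id: str
    target_start: int
    target_end: int
    score: float
    columns: tuple[Column, ...]
    cleavage_pos0: int | None

    @property
    def cleavage_site(self) -> int | None:
        """1-based cleavage (+1) coordinate on the target."""
        return None if self.cleavage_pos0 is None else self.cleavage_pos0 + 1

    @property
    def states(self) -> str:
        return "".join(k for k, _, _ in self.columns)

    def recomputed_score(self, scheme: PenaltyScheme) -> float:
        """Re-derive the score from the paired-state columns."""
        n = len(self.srna_sequence)
        total = 0.0
        for kind, spos, _tpos in self.columns:
            if kind == "|":
                pen = 0.0
            elif kind == "o":
                pen = scheme.gu_wobble
            else:  # mismatch or either bulge
                pen = scheme.mismatch_or_gap
            idx = min(max(spos, 1), n)
            total += pen * scheme.weight(idx)
        return total


def _pair_kind(s: int, t: int) -> str:
    p = PAIR_PENALTY[s, t]
    if p == 0.0:
        return "|"
    if p == 0.5:
        return "o"
    return "x"


def score_duplex(
    srna: str,
    target_window: str,
    scheme: PenaltyScheme | None = None,
    srna_id: str = "sRNA",
    target_id: str = "window",
) -> DuplexAlignment:
    """Optimal (minimum-score) duplex of an sRNA against one target window.

    The sRNA pairs antiparallel to the window (sRNA position 1 against the
    window's 3'-most base).  The whole sRNA and the whole window must be
    consumed; total bulged nucleotides are capped by ``scheme.max_bulges``,
    so the window length must be within that cap of the sRNA length.
    """
    scheme = scheme or PenaltyScheme()
    s = encode(normalize(srna))
    w = encode(normalize(target_window))
    n, m = len(s), len(w)
    cap = scheme.max_bulges
    if not (n - cap <= m <= n + cap):
        raise ValueError(
            f"window length {m} incompatible with sRNA length {n} (bulge cap {cap})"
        )
    wr = w[::-1]  # wr[j-1] is the window base pairing sRNA position j-ish
    # D[i][j][b]: best score aligning sRNA[:i] with reversed-window[:j], b bulges
    D = [[[BIG] * (cap + 1) for _ in range(m + 1)] for _ in range(n + 1)]
    ptr: dict[tuple[int, int, int], tuple[int, int, int, str]] = {}
    D[0][0][0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            for b in range(cap + 1):
                cur = D[i][j][b]
                if cur >= BIG:
                    continue
                if i < n and j < m:  # pair sRNA i+1 with window base
                    pen = PAIR_PENALTY[s[i], wr[j]] * scheme.weight(i + 1)
                    if cur + pen < D[i + 1][j + 1][b]:
                        D[i + 1][j + 1][b] = cur + pen
                        ptr[(i + 1, j + 1, b)] = (i, j, b, "pair")
                if i < n and b < cap:  # bulged sRNA nucleotide i+1
                    pen = scheme.mismatch_or_gap * scheme.weight(i + 1)
                    if cur + pen < D[i + 1][j][b + 1]:
                        D[i + 1][j][b + 1] = cur + pen
                        ptr[(i + 1, j, b + 1)] = (i, j, b, "sbulge")
                if j < m and b < cap:  # bulged target nucleotide
                    pen = scheme.mismatch_or_gap * scheme.weight(scheme.gap_index(i, n))
                    if cur + pen < D[i][j + 1][b + 1]:
                        D[i][j + 1][b + 1] = cur + pen
                        ptr[(i, j + 1, b + 1)] = (i, j, b, "tbulge")
    best_b = min(range(cap + 1), key=lambda b: D[n][m][b])
    score = D[n][m][best_b]
    # traceback
    cols: list[Column] = []
    i, j, b = n, m, best_b
    while (i, j, b) != (0, 0, 0):
        pi, pj, pb, move = ptr[(i, j, b)]
        if move == "pair":
            tpos = m - 1 - pj  # 0-based window coordinate of the paired base
            cols.append((_pair_kind(s[pi], wr[pj]), pi + 1, tpos))
        elif move == "sbulge":
            cols.append(("^", pi + 1, -1))
        else:
            cols.append(("-", scheme.gap_index(pi, n), m - 1 - pj))
        i, j, b = pi, pj, pb
    cols.reverse()
    cleavage = None
    for kind, spos, tpos in cols:
        if spos == 10 and kind in "|ox":
            cleavage = tpos
            break
    return DuplexAlignment(
        srna_id=srna_id,
        srna_sequence=normalize(srna),
        target_id=target_id,
        target_start=0,
        target_end=m,
        score=float(score),
        columns=tuple(cols),
        cleavage_pos0=cleavage,
    )


def _end_scores(
    srna_codes: np.ndarray, target_codes: np.ndarray, scheme: PenaltyScheme
) -> np.ndarray:
    """Best alignment score for every possible site end on the target.

    Semi-global DP: the target is traversed 5'->3' while the sRNA is
    consumed 3'->5' (antiparallel pairing), the site start is free, and
    entry ``j`` of the result is the best full-sRNA alignment whose site
    ends at target index ``j - 1`` (0-based, inclusive).
    """
    n = len(srna_codes)
    T = len(target_codes)
    cap = scheme.max_bulges
    rs = srna_codes[::-1]
    D = np.full((cap + 1, T + 1), BIG)
    D[0, :] = 0.0
    for i in range(1, n + 1):
        p = n - i + 1  # 1-based sRNA position consumed at this row
        w_pair = scheme.weight(p)
        w_sbulge = scheme.mismatch_or_gap * scheme.weight(p)
        w_tbulge = scheme.mismatch_or_gap * scheme.weight(max(1, p - 1))
        pen = PAIR_PENALTY[rs[i - 1], target_codes] * w_pair
        New = np.full_like(D, BIG)
        for b in range(cap + 1):
            best = np.full(T + 1, BIG)
            best[1:] = D[b, :-1] + pen  # diagonal
            if b > 0:
                np.minimum(best, D[b - 1, :] + w_sbulge, out=best)
                np.minimum(best[1:], New[b - 1, :-1] + w_tbulge, out=best[1:])
            New[b] = best
        D = New
    return D.min(axis=0)


def _resolve_overlaps(sites: list[DuplexAlignment]) -> list[DuplexAlignment]:
    """Keep non-overlapping sites, preferring lower score then leftmost."""
    kept: list[DuplexAlignment] = []
    for cand in sorted(sites, key=lambda a: (a.score, a.target_start, a.target_end)):
        if all(
            cand.target_end <= k.target_start or cand.target_start >= k.target_end
            for k in kept
            if k.target_id == cand.target_id
        ):
            kept.append(cand)
    kept.sort(key=lambda a: (a.target_id, a.target_start))
    return kept


def _refine_end(
    srna: str,
    transcript: str,
    end: int,
    scheme: PenaltyScheme,
    srna_id: str,
    target_id: str,
) -> DuplexAlignment | None:
    """Best window-level alignment among windows ending at ``end`` (exclusive)."""
    n = len(srna)
    best: DuplexAlignment | None = None
    for L in range(n - scheme.max_bulges, n + scheme.max_bulges + 1):
        start = end - L
        if start < 0 or L <= 0:
            continue
        aln = score_duplex(srna, transcript[start:end], scheme, srna_id, target_id)
        if best is None or aln.score < best.score:
            aln.target_start = start
            aln.target_end = end
            aln.columns = tuple(
                (k, sp, tp + start if tp >= 0 else tp) for k, sp, tp in aln.columns
            )
            if aln.cleavage_pos0 is not None:
                aln.cleavage_pos0 += start
            best = aln
    return best


def find_candidate_sites(
    srna: str,
    transcript: str,
    scheme: PenaltyScheme | None = None,
    srna_id: str = "sRNA",
    transcript_id: str = "transcript",
) -> list[DuplexAlignment]:
    """All non-overlapping candidate sites with score <= scheme.max_score.

    Overlapping qualifying windows are resolved to the lower-scoring one
    (leftmost on ties); results are sorted by position.
    """
    scheme = scheme or PenaltyScheme()
    t = normalize(transcript)
    if len(t) < len(srna) - scheme.max_bulges:
        return []
    ends = _end_scores(encode(normalize(srna)), encode(t), scheme)
    sites: list[DuplexAlignment] = []
    for j in np.nonzero(ends <= scheme.max_score)[0]:
        aln = _refine_end(srna, t, int(j), scheme, srna_id, transcript_id)
        if aln is not None and aln.score <= scheme.max_score:
            sites.append(aln)
    return _resolve_overlaps(sites)


def iter_candidates_concat(
    srnas: Mapping[str, str],
    transcriptome: Mapping[str, str],
    scheme: PenaltyScheme | None = None,
) -> Iterator[DuplexAlignment]:
    """Scan every sRNA against a whole transcriptome in one concatenated pass.

    Transcripts are joined with sentinel runs longer than the bulge cap so
    no alignment can bridge two transcripts; each qualifying end is mapped
    back to its transcript and refined exactly as in
    :func:`find_candidate_sites`.
    """
    scheme = scheme or PenaltyScheme()
    ids = list(transcriptome)
    seqs = [normalize(transcriptome[i]) for i in ids]
    sep = scheme.max_bulges + 2
    starts: list[int] = []
    pos = 0
    chunks = []
    for s in seqs:
        starts.append(pos)
        chunks.append(encode(s))
        chunks.append(np.full(sep, 5, dtype=np.int8))
        pos += len(s) + sep
    if not chunks:
        return
    concat = np.concatenate(chunks)
    starts_arr = np.array(starts)
    for sid, sseq in srnas.items():
        sseq = normalize(sseq)
        ends = _end_scores(encode(sseq), concat, scheme)
        hits: list[DuplexAlignment] = []
        for j in np.nonzero(ends <= scheme.max_score)[0]:
            t_idx = int(np.searchsorted(starts_arr, int(j) - 1, side="right") - 1)
            local_end = int(j) - starts[t_idx]
            if local_end > len(seqs[t_idx]):
                continue  # end inside a sentinel run
            aln = _refine_end(sseq, seqs[t_idx], local_end, scheme, sid, ids[t_idx])
            if aln is not None and aln.score <= scheme.max_score:
                hits.append(aln)
        yield from _resolve_overlaps(hits)


def predict_targets(
    srnas: Mapping[str, str],
    transcriptome: Mapping[str, str],
    scheme: PenaltyScheme | None = None,
):
    """Candidate-target table over all sRNA x transcript pairs.

    Returns a pandas DataFrame with 1-based site coordinates, the mispair
    score, the predicted cleavage (+1) coordinate, and the duplex state
    string; deterministic given its inputs.
    """
    import pandas as pd

    rows = []
    for aln in iter_candidates_concat(srnas, transcriptome, scheme):
        rows.append(
            {
                "srna_id": aln.srna_id,
                "srna_seq": aln.srna_sequence,
                "transcript_id": aln.target_id,
                "site_start": aln.target_start + 1,
                "site_end": aln.target_end,
                "mispair_score": aln.score,
                "cleavage_site": aln.cleavage_site,
                "duplex": aln.states,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "srna_id",
            "srna_seq",
            "transcript_id",
            "site_start",
            "site_end",
            "mispair_score",
            "cleavage_site",
            "duplex",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["srna_id", "transcript_id", "site_start"], kind="mergesort"
        ).reset_index(drop=True)
    return df
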