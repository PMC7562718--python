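"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

from phasiscan.seqtools import encode, normalize

WC = {(0, 3), (3, 0), (1, 2), (2, 1)}
WOBBLE = {(2, 3), (3, 2)}  # sRNA G : target U, sRNA U : target G


def enumerate_duplex_scores(srna: str, window: str, scheme):
    """Yield the score of every complete alignment with <= max_bulges bulges.

    Pure enumeration: walks every interleaving of pair / sRNA-bulge /
    target-bulge moves that consumes the whole sRNA and the whole window.
    Penalty rules are applied move by move, independently of the dynamic
    program under test.
    """
    s = encode(normalize(srna))
    w = encode(normalize(window))[::-1]
    n, m = len(s), len(w)

    def weight(pos: int) -> float:
        return 1.0 if scheme.core_start <= pos <= scheme.core_end else scheme.outside_core_multiplier

    def pair_penalty(i: int, j: int) -> float:
        key = (int(s[i]), int(w[j]))
        if key in WC:
            return 0.0
        if key in WOBBLE:
            return scheme.gu_wobble * weight(i + 1)
        return scheme.mismatch_or_gap * weight(i + 1)

    out: list[float] = []

    def rec(i: int, j: int, bulges: int, acc: float) -> None:
        if i == n and j == m:
            out.append(acc)
            return
        if i < n and j < m:
            rec(i + 1, j + 1, bulges, acc + pair_penalty(i, j))
        if bulges < scheme.max_bulges:
            if i < n:
                rec(i + 1, j, bulges + 1, acc + scheme.mismatch_or_gap * weight(i + 1))
            if j < m:
                gap_pos = min(max(i, 1), n)
                rec(i, j + 1, bulges + 1, acc + scheme.mismatch_or_gap * weight(gap_pos))
    rec(0, 0, 0, 0.0)
    return out


def brute_force_duplex_score(srna: str, window: str, scheme) -> float:
    scores = enumerate_duplex_scores(srna, window, scheme)
    return min(scores) if scores else float("inf")


def category_oracle(counts: dict[int, float], site: int) -> int:
    """Literal transcription of the five category rules."""
    c = counts[site]
    values = list(counts.values())
    maximum = max(values)
    average = sum(values) / len(values)
    n_at_max = sum(1 for v in values if v == maximum)
    if c == 1:
        return 4
    if c > 1 and c == maximum and n_at_max == 1:
        return 0
    if c > 1 and c == maximum and n_at_max > 1:
        return 1
    if c > 1 and c > average and c != maximum:
        return 2
    return 3


def recount_phase_window(entries, start: int, period: int, register: int):
    """Direct recount of (k, P, U) over profile entries in one window.

    ``entries`` is an iterable of (strand, pos, length, count); minus
    strand 5' positions are shifted by +2 before the register comparison.
    """
    window = 9 * period
    k = 0
    P = 0.0
    U = 0.0
    for strand, pos, length, count in entries:
        if length != period:
            continue
        eff = pos + 2 if strand == "-" else pos
        if not (start <= eff < start + window):
            continue
        if eff % period == register % period:
            k += 1
            P += count
        else:
            U += count
    return k, P, U
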