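"""Low-level nucleotide-sequence helpers shared across the package.

Sequences are normalized to the DNA alphabet internally (U -> T, upper
case); writers that emit sRNA sequences may convert back to RNA for
display.  Encoded arrays use A=0, C=1, G=2, T=3, N(or any other code)=4.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

_ENC_LUT = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENC_LUT[ord(_c)] = _i
    _ENC_LUT[ord(_c.lower())] = _i
_ENC_LUT[ord("U")] = 3
_ENC_LUT[ord("u")] = 3

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def normalize(seq: str) -> str:
    """Upper-case and convert U to T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as an int8 array (A=0, C=1, G=2, T/U=3, else 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC_LUT[raw]


def decode(codes: np.ndarray) -> str:
    return bytes(_DEC[np.asarray(codes, dtype=np.int64)]).decode("ascii")


def random_seq(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, 4, n)
    return bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[idx]).decode("ascii")


def is_unambiguous(seq: str) -> bool:
    return not (set(normalize(seq)) - set("ACGT"))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle ``seq`` preserving its exact dinucleotide composition.

    Altschul-Erikson algorithm: the sequence is viewed as an Eulerian walk
    on the graph whose vertices are nucleotides and whose edges are the
    observed dinucleotides; a random last-out-edge assignment that forms an
    arborescence into the final vertex is drawn by rejection, the remaining
    out-edges are permuted, and the walk is replayed from the first base.
    """
    s = normalize(seq)
    if len(s) < 3:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = list(edges.keys())
    # vertices needing a designated final out-edge (all with out-edges except `last`)
    need_last = [v for v in vertices if v != last]
    for _ in range(10_000):
        chosen = {v: edges[v][rng.integers(0, len(edges[v]))] for v in need_last}
        # check every vertex reaches `last` through chosen edges
        ok = True
        for v in need_last:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in chosen:
                    ok = False
                    break
                seen.add(cur)
                cur = chosen[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - rejection loop essentially always terminates
        return s
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        out = list(edges[v])
        if v != last:
            out.remove(chosen[v])
        perm = rng.permutation(len(out))
        out = [out[i] for i in perm]
        if v != last:
            out.append(chosen[v])
        shuffled[v] = out
    walk = [s[0]]
    ptr = {v: 0 for v in vertices}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)
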