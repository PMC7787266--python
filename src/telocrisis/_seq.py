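"""Low-level DNA string helpers shared by the simulator and the fusion caller.

Sequences are plain upper-case ACGT Python strings throughout; coordinates are
0-based half-open.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# translate ASCII -> 2-bit code; 255 marks non-ACGT
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute bases independently at `rate`, never to the same base."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    codes = _CODE[arr]
    hit = rng.random(arr.size) < rate
    idx = np.nonzero(hit)[0]
    if idx.size:
        shift = rng.integers(1, 4, size=idx.size).astype(np.uint8)
        codes[idx] = (codes[idx] + shift) % 4
        arr[idx] = _BASES[codes[idx]]
    return arr.tobytes().decode("ascii")


def encode_kmers(seq: str, k: int) -> np.ndarray:
    """2-bit packed codes of every k-mer of `seq` as int64 (k <= 31)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out = (out << 2) | arr[j : j + n]
    return out


def encode_kmer(seq: str, start: int, k: int) -> int:
    """Code of seq[start:start+k]; -1 if out of range."""
    if start < 0 or start + k > len(seq):
        return -1
    code = 0
    for ch in seq[start : start + k]:
        code = (code << 2) | int(_CODE[ord(ch)])
    return code


def first_mismatch(a: str, ai: int, b: str, bi: int, limit: int) -> int:
    """Offset of the first mismatch of a[ai:ai+limit] vs b[bi:bi+limit].

    Returns `limit` when the stretch matches entirely.  Chunked compares keep
    the common all-match case at C speed.
    """
    if a[ai : ai + limit] == b[bi : bi + limit]:
        return limit
    off = 0
    chunk = 64
    while off < limit:
        step = min(chunk, limit - off)
        if a[ai + off : ai + off + step] == b[bi + off : bi + off + step]:
            off += step
            continue
        for j in range(step):
            if a[ai + off + j] != b[bi + off + j]:
                return off + j
        off += step
    return limit


def extend_right(a: str, ai: int, b: str, bi: int, max_mm: int) -> tuple[int, int, int]:
    """Maximal ungapped rightward extension of a[ai:] against b[bi:].

    Tolerates up to `max_mm` mismatches; the reported length ends on the last
    *matching* base.  Returns (length, mismatches_used, perfect_length) where
    perfect_length is the exact-match run up to the first mismatch.
    """
    limit = min(len(a) - ai, len(b) - bi)
    pos = 0
    mm = 0
    last_match_end = 0
    perfect = -1
    while pos < limit:
        adv = first_mismatch(a, ai + pos, b, bi + pos, limit - pos)
        pos += adv
        if adv:
            last_match_end = pos
        if pos >= limit:
            break
        if perfect < 0:
            perfect = pos
        mm += 1
        if mm > max_mm:
            break
        pos += 1  # step over the mismatching base
    if perfect < 0:
        perfect = limit  # no mismatch encountered
    return last_match_end, min(mm, max_mm), perfect


def extend_left(a: str, a_end: int, b: str, b_end: int, max_mm: int) -> tuple[int, int, int]:
    """Maximal ungapped leftward extension of a[:a_end] against b[:b_end]."""
    limit = min(a_end, b_end)
    pos = 0
    mm = 0
    last_match_end = 0
    perfect = -1
    while pos < limit:
        # compare backwards in chunks
        adv = _first_mismatch_back(a, a_end - pos, b, b_end - pos, limit - pos)
        pos += adv
        if adv:
            last_match_end = pos
        if pos >= limit:
            break
        if perfect < 0:
            perfect = pos
        mm += 1
        if mm > max_mm:
            break
        pos += 1
    if perfect < 0:
        perfect = limit  # no mismatch encountered
    return last_match_end, min(mm, max_mm), perfect


def _first_mismatch_back(a: str, a_end: int, b: str, b_end: int, limit: int) -> int:
    if a[a_end - limit : a_end] == b[b_end - limit : b_end]:
        return limit
    off = 0
    chunk = 64
    while off < limit:
        step = min(chunk, limit - off)
        if a[a_end - off - step : a_end - off] == b[b_end - off - step : b_end - off]:
            off += step
            continue
        for j in range(step):
            if a[a_end - off - j - 1] != b[b_end - off - j - 1]:
                return off + j
        off += step
    return limit


def substream(seed: int, stream: int) -> np.random.Generator:
    """Named independent RNG stream derived from one integer seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))
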