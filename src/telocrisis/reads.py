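"""Paired-read container and overlapping-mate merging."""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import first_mismatch, revcomp


@dataclass
class PairedReads:
    """In-memory paired read set; mate 2 is stored as sequenced (reverse strand)."""

    ids: list[str] = field(default_factory=list)
    r1: list[str] = field(default_factory=list)
    r2: list[str] = field(default_factory=list)

    def append(self, read_id: str, seq1: str, seq2: str) -> None:
        self.ids.append(read_id)
        self.r1.append(seq1)
        self.r2.append(seq2)

    def extend(self, other: "PairedReads") -> None:
        self.ids.extend(other.ids)
        self.r1.extend(other.r1)
        self.r2.extend(other.r2)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.r1, self.r2))


def merge_pair(r1: str, r2: str, min_overlap: int = 20,
               max_mismatch: int = 2) -> str | None:
    """Reconstruct the sequenced fragment from overlapping mates.

    The fragment is ``r1[:off] + revcomp(r2)`` for the smallest offset whose
    implied overlap (>= min_overlap) matches with at most `max_mismatch`
    substitutions; None when no acceptable overlap exists (fragment longer
    than the two reads combined, or too many errors in the overlap).
    """
    s2 = revcomp(r2)
    n1, n2 = len(r1), len(s2)
    max_off = n1 - min_overlap
    # seed from two regions of s2 so a single sequencing error cannot
    # defeat candidate finding; candidate offsets are verified in full
    for seed_start in (0, 16):
        if seed_start + 12 > n2:
            break
        seed = s2[seed_start : seed_start + 12]
        hit = r1.find(seed)
        while hit >= 0:
            off = hit - seed_start
            if 0 <= off <= max_off:
                ov = min(n1 - off, n2)
                if _mismatches(r1, off, s2, 0, ov, max_mismatch) <= max_mismatch:
                    return r1[:off] + s2
            hit = r1.find(seed, hit + 1)
    return None


def _mismatches(a: str, ai: int, b: str, bi: int, length: int, cap: int) -> int:
    mm = 0
    pos = 0
    while pos < length:
        adv = first_mismatch(a, ai + pos, b, bi + pos, length - pos)
        pos += adv
        if pos >= length:
            break
        mm += 1
        if mm > cap:
            return mm
        pos += 1
    return mm
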