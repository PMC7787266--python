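"""Brute-force reference implementations used for validation.

These deliberately naive routines re-derive junction microhomology and exact
test probabilities by full enumeration.  They are independent of the
production code paths (`fusioncall.resolve_junction` uses anchored maximal
extensions; `enrich.fisher_exact_2x2` uses integer-weight comparisons) and
exist so tests and the acceptance script can cross-check results.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def enumerate_split_placements(seq: str, ref_a: str, a_start: int,
                               ref_b: str, b_end: int) -> dict:
    """Enumerate every perfect split placement of a junction sequence.

    The sequence is anchored with its first base at ``ref_a[a_start]`` and
    its last base at ``ref_b[b_end - 1]``.  A split at position p is valid
    when ``seq[:p]`` matches reference A and ``seq[p:]`` matches reference B
    exactly.  Returns the placement set, the MH width (max - min valid
    placement) and, when no perfect placement exists, the maximal middle
    segment matching neither flank (the insertion).
    """
    n = len(seq)
    valid = []
    for p in range(n + 1):
        if a_start + p > len(ref_a):
            break
        if b_end - (n - p) < 0:
            continue
        if (seq[:p] == ref_a[a_start : a_start + p]
                and seq[p:] == ref_b[b_end - (n - p) : b_end]):
            valid.append(p)
    if valid:
        return {"placements": valid, "mh_bp": max(valid) - min(valid),
                "leftmost": min(valid), "ins_seq": ""}
    la = 0
    while la < n and a_start + la < len(ref_a) and seq[la] == ref_a[a_start + la]:
        la += 1
    lb = 0
    while (lb < n and b_end - lb - 1 >= 0
           and seq[n - lb - 1] == ref_b[b_end - lb - 1]):
        lb += 1
    lb = min(lb, n - la)
    return {"placements": [], "mh_bp": 0, "leftmost": la,
            "ins_seq": seq[la : n - lb]}


def fisher_exact_oracle(table) -> Fraction:
    """Two-sided Fisher's exact p by exact-rational hypergeometric summation."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1, n = a + c, a + b + c + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return Fraction(1)
    denom = comb(n, c1)
    pmf = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pmf[k] = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
    p_obs = pmf[a]
    return sum((p for p in pmf.values() if p <= p_obs), Fraction(0))
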