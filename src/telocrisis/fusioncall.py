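"""Resolve telomere-fusion amplicon reads into classified junction calls.

The caller turns paired amplicon reads into deduplicated fusion events with
per-junction microhomology (MH), insertion (INS) and subtelomeric-deletion
metrics.  Fusions are classified as

* ``genomic``  - a subtelomere fused to a non-telomeric genomic locus,
* ``intra``    - sister-chromatid fusion within one chromosome end,
* ``inter``    - fusion between two different chromosome ends.

Alignment is a built-in seed-and-extend split aligner (exact k-mer seeds,
ungapped extension, bounded substitutions per segment) so no external mapper
is needed; externally produced split alignments in SAM format are accepted as
an alternative input path.

Coordinates are 0-based half-open; junction breakpoints are reported at the
leftmost valid placement, with ``mh_bp`` giving the width of the placement
ambiguity.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._seq import (
    encode_kmer,
    encode_kmers,
    extend_left,
    extend_right,
    revcomp,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("genomic", "intra", "inter")
STAGES = ("Early", "Deep", "Late")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubtelomereRef:
    """One primer-targeted chromosome-end reference.

    ``primer_offset`` is the 0-based position where the fusion primer lands
    (amplicons start there); ``telomere_boundary`` is the position where the
    telomere repeat array begins.  Junction breakpoints live in
    ``(primer_offset, telomere_boundary]`` and the subtelomeric deletion of a
    fused end is ``telomere_boundary - breakpoint``.

    Members of a homologous family (e.g. the 21q group) share ``family_id``;
    exactly one member per family is flagged ``archetype``.
    """

    end_id: str
    family_id: str
    sequence: str
    primer_offset: int
    telomere_boundary: int
    ltr_intervals: tuple[tuple[int, int], ...] = ()
    archetype: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.primer_offset < self.telomere_boundary <= len(self.sequence)):
            raise ValueError(
                f"subtelomere {self.end_id}: require primer_offset < telomere_boundary "
                f"<= sequence length"
            )

    @property
    def zone(self) -> tuple[int, int]:
        """Breakpoint zone (primer_offset, telomere_boundary]."""
        return self.primer_offset, self.telomere_boundary


@dataclass
class FusionCall:
    """One resolved, deduplicated fusion event."""

    sample: str
    stage: str
    end_id: str
    subtel_breakpoint: int
    partner: tuple[str, int, str]          # (chrom or end_id, 0-based pos, strand)
    category: str
    mh_bp: int | None = 0
    ins_seq: str = ""
    ins_templated: str | None = None       # "templated" | "untemplated" | None (NA)
    deletion_bp: tuple[int, int | None] = (0, None)
    delta_deletion_bp: int | None = None   # intra only
    support: int = 1
    resolution: str = "base"               # "base" | "interval"
    call_id: str = ""


@dataclass
class SplitAlignment:
    """A read split between a subtelomere anchor (A) and a partner locus (B).

    ``a_len``/``b_len`` are the mismatch-tolerant segment lengths from the
    read's two ends (each ending on a matching base); `resolve_junction`
    re-derives the junction from *perfect* matches locally, so MH stays a
    statement about exact split placements.  Reference coordinates for B are
    in the oriented frame of the matched strand; ``forward_coord`` converts
    back.
    """

    read_id: str
    seq: str
    a_target: int                 # index into ReferenceIndex.targets
    a_ref_start: int
    a_len: int                    # read matches seq[0:a_len] exactly
    b_target: int
    b_ref_start: int              # oriented coords of B exact-match start
    b_len: int                    # read matches seq[n-b_len:n] exactly
    mismatches: tuple[int, int] = (0, 0)

    @property
    def middle(self) -> tuple[int, int]:
        """Read interval explained by neither flank (empty when overlapping)."""
        return (self.a_len, max(self.a_len, len(self.seq) - self.b_len))


# ---------------------------------------------------------------------------
# reference index
# ---------------------------------------------------------------------------

@dataclass
class _Target:
    name: str
    strand: str
    seq: str
    kind: str                      # "subtel" | "genome"
    subtel: SubtelomereRef | None = None


class ReferenceIndex:
    """Exact k-mer index over subtelomeres and genome, both strands."""

    def __init__(self, subtelomeres, minigenome: dict[str, str], k: int = 21):
        if k < 11:
            raise ValueError("seed length k must be >= 11")
        if not subtelomeres and not minigenome:
            raise ValueError("empty reference set")
        self.k = k
        self.subtelomeres = list(subtelomeres)
        self.by_end = {s.end_id: s for s in self.subtelomeres}
        self.targets: list[_Target] = []
        for s in self.subtelomeres:
            self.targets.append(_Target(s.end_id, "+", s.sequence, "subtel", s))
            self.targets.append(_Target(s.end_id, "-", revcomp(s.sequence), "subtel", s))
        for name, seq in minigenome.items():
            self.targets.append(_Target(name, "+", seq, "genome"))
            self.targets.append(_Target(name, "-", revcomp(seq), "genome"))
        code_chunks = []
        packed_chunks = []
        for ti, t in enumerate(self.targets):
            codes = encode_kmers(t.seq, k)
            code_chunks.append(codes)
            packed_chunks.append((np.int64(ti) << 40)
                                 | np.arange(codes.size, dtype=np.int64))
        all_codes = np.concatenate(code_chunks)
        all_packed = np.concatenate(packed_chunks)
        order = np.argsort(all_codes, kind="stable")
        self._codes = all_codes[order]
        self._packed = all_packed[order]

    def lookup(self, code: int) -> list[tuple[int, int]]:
        if code < 0:
            return []
        lo = int(np.searchsorted(self._codes, code, side="left"))
        hi = int(np.searchsorted(self._codes, code, side="right"))
        if hi - lo > 50:          # hyper-repetitive seed; unusable anchor
            return []
        return [(int(p) >> 40, int(p) & 0xFFFFFFFFFF)
                for p in self._packed[lo:hi]]

    def forward_coord(self, ti: int, oriented_pos: int) -> tuple[str, int, str]:
        """Map an oriented-frame breakpoint to (name, forward pos, strand)."""
        t = self.targets[ti]
        if t.strand == "+":
            return t.name, oriented_pos, "+"
        return t.name, len(t.seq) - oriented_pos, "-"

    def family_members(self, family_id: str) -> list[SubtelomereRef]:
        return [s for s in self.subtelomeres if s.family_id == family_id]


def _as_index(refs, k: int = 21) -> ReferenceIndex:
    if isinstance(refs, ReferenceIndex) or hasattr(refs, "targets"):
        return refs
    # SyntheticReference-like duck type
    return ReferenceIndex(refs.subtelomeres, refs.minigenome, k=k)


# ---------------------------------------------------------------------------
# split alignment
# ---------------------------------------------------------------------------

def _best_hit(seq, start_offsets, index, max_mm, leftward):
    """Best anchored maximal extension among seed hits; None if no seed hits.

    Returns (ti, ref_anchor, length, mm, tie, perfect) where `tie` flags an
    equal-length best extension on a second target and `perfect` is the
    exact-match run length from the read end.
    """
    k = index.k
    n = len(seq)
    for off in start_offsets:
        code = encode_kmer(seq, off, k)
        hits = index.lookup(code)
        if not hits:
            continue
        best = None
        tie = False
        for ti, pos in hits:
            t = index.targets[ti]
            if leftward:
                ref_end = pos + (n - off)
                if ref_end > len(t.seq):
                    continue
                length, mm, perfect = extend_left(seq, n, t.seq, ref_end, max_mm)
                anchor = ref_end
            else:
                ref_start = pos - off
                if ref_start < 0:
                    continue
                length, mm, perfect = extend_right(seq, 0, t.seq, ref_start, max_mm)
                anchor = ref_start
            cand = (length, -mm, ti, anchor, perfect)
            if best is None or cand[:2] > best[:2]:
                best = cand
                tie = False
            elif cand[:2] == best[:2] and ti != best[2]:
                tie = True
        if best is not None:
            length, neg_mm, ti, anchor, perfect = best
            return ti, anchor, length, -neg_mm, tie, perfect
    return None


def split_align(reads, refs, k: int = 21, max_mismatch: int = 2,
                stats: dict | None = None) -> list[SplitAlignment]:
    """Split-align sequences against subtelomere + genome references.

    `reads` is an iterable of ``(read_id, sequence)`` in amplicon (primer)
    orientation; use `call_fusions` for paired FASTQ-style input.  Sequences
    mapping entirely within one reference yield no alignment.  The A segment
    must be anchored on the forward strand of a subtelomere.
    """
    index = _as_index(refs, k)
    k = index.k
    st = stats if stats is not None else {}
    for key in ("aligned", "unanchored", "contained", "no_partner", "split", "ambiguous"):
        st.setdefault(key, 0)
    out: list[SplitAlignment] = []
    for read_id, seq in reads:
        n = len(seq)
        if n < 2 * k:
            st["unanchored"] += 1
            continue
        st["aligned"] += 1
        left = _best_hit(seq, (0, 7, 14, 21), index, max_mismatch, leftward=False)
        if left is None:
            st["unanchored"] += 1
            continue
        a_ti, a_start, a_len_tol, a_mm, a_tie, a_perfect = left
        if n - a_len_tol <= max_mismatch - a_mm:
            st["contained"] += 1
            continue
        a_t = index.targets[a_ti]
        if a_t.kind != "subtel" or a_t.strand != "+" or a_tie:
            # not a primer-anchored read (or ambiguous anchor)
            st["unanchored"] += 1
            continue
        offs = [n - k - d for d in (0, 7, 14, 21) if n - k - d > 0]
        right = _best_hit(seq, offs, index, max_mismatch, leftward=True)
        if right is None:
            st["no_partner"] += 1
            continue
        b_ti, b_end, b_len_tol, b_mm, b_tie, b_perfect = right
        if b_ti == a_ti and (b_end - n) == a_start:
            # collinear with the A anchor: junction too close to the read end
            st["no_partner"] += 1
            continue
        if b_tie:
            tie_targets = _tie_targets(seq, n, index, max_mismatch, b_len_tol)
            fams = {index.targets[ti].subtel.family_id
                    for ti in tie_targets
                    if index.targets[ti].kind == "subtel"}
            if len(tie_targets) > 1 and (len(fams) != 1 or any(
                    index.targets[ti].kind == "genome" for ti in tie_targets)):
                # equal-score placements on unrelated references
                st["ambiguous"] += 1
                continue
        st["split"] += 1
        out.append(SplitAlignment(read_id, seq, a_ti, a_start, a_len_tol,
                                  b_ti, b_end - b_len_tol, b_len_tol,
                                  (a_mm, b_mm)))
    return out


def _tie_targets(seq, n, index, max_mm, best_len) -> list[int]:
    """Targets achieving the best leftward extension for the read suffix."""
    k = index.k
    out = []
    for off in (n - k, n - k - 7, n - k - 14, n - k - 21):
        if off <= 0:
            continue
        for ti, pos in index.lookup(encode_kmer(seq, off, k)):
            t = index.targets[ti]
            ref_end = pos + (n - off)
            if ref_end > len(t.seq):
                continue
            length, _, _ = extend_left(seq, n, t.seq, ref_end, max_mm)
            if length == best_len and ti not in out:
                out.append(ti)
        if out:
            break
    return out


# ---------------------------------------------------------------------------
# junction resolution
# ---------------------------------------------------------------------------

# A single substitution inside a flank is only treated as a sequencing error
# (and stepped over during junction resolution) when followed by this many
# perfectly matching bases; junction-defining mismatches never are, because
# the sequence beyond a junction matches the flank only by chance.
MISMATCH_RUN_GUARD = 10


def resolve_junction(sa: SplitAlignment, refs) -> tuple[tuple[int, int], int, str]:
    """Resolve a split alignment into leftmost breakpoints, MH and INS.

    MH is the width of the set of perfect split placements of the
    junction-spanning sequence against both references; when no perfect
    placement exists the unexplained middle of the read is the insertion and
    MH is 0.  Breakpoints are reported at the leftmost valid placement:
    ``(subtelomere breakpoint, partner breakpoint in oriented frame)``.

    Each flank's exact-match end is found by chasing perfect runs from the
    read end, stepping over an isolated mismatch only when the following run
    is at least `MISMATCH_RUN_GUARD` bases (a mid-flank sequencing error).
    For error-free reads this coincides with full split-placement
    enumeration.
    """
    index = _as_index(refs)
    seq = sa.seq
    n = len(seq)
    a_seq = index.targets[sa.a_target].seq
    b_seq = index.targets[sa.b_target].seq
    a0 = sa.a_ref_start
    b_end = sa.b_ref_start + sa.b_len     # oriented index aligned to read end
    guard = MISMATCH_RUN_GUARD

    def a_match(i):
        return 0 <= a0 + i < len(a_seq) and seq[i] == a_seq[a0 + i]

    def b_match(i):  # read index i against the oriented B frame
        j = b_end - n + i
        return 0 <= j < len(b_seq) and seq[i] == b_seq[j]

    e_a = 0
    while e_a < n and a_match(e_a):
        e_a += 1
    while e_a < n:
        j = e_a + 1
        while j < n and a_match(j):
            j += 1
        if j - (e_a + 1) >= guard:
            e_a = j               # isolated substitution inside the A flank
        else:
            break

    s_b = n
    while s_b > 0 and b_match(s_b - 1):
        s_b -= 1
    while s_b > 0:
        j = s_b - 1
        while j > 0 and b_match(j - 1):
            j -= 1
        if (s_b - 1) - j >= guard:
            s_b = j
        else:
            break

    if e_a >= s_b:
        mh = e_a - s_b
        p = s_b  # leftmost valid placement
        return (a0 + p, b_end - n + p), mh, ""
    ins = seq[e_a:s_b]
    return (a0 + e_a, b_end - n + s_b), 0, ins


def insertion_is_templated(ins_seq: str, ref_a: str, bp_a: int, ref_b: str,
                           bp_b: int, window: int = 100,
                           include_revcomp: bool = True) -> bool:
    """True if `ins_seq` occurs within +/-window of either breakpoint.

    Both references are searched in the orientation their flank joins the
    junction; the reverse complement of the insertion is included by default
    (strand-agnostic templated synthesis).
    """
    if not ins_seq:
        raise ValueError("empty insertion has no templating status")
    probes = [ins_seq]
    if include_revcomp:
        probes.append(revcomp(ins_seq))
    m = len(ins_seq)
    for ref, bp in ((ref_a, bp_a), (ref_b, bp_b)):
        lo = max(0, bp - window)
        hi = min(len(ref), bp + window + m)
        region = ref[lo:hi]
        if any(p in region for p in probes):
            return True
    return False


def classify_insertion(ins_seq: str, ref_a: str, ref_b: str,
                       breakpoints: tuple[int, int], window: int = 100,
                       include_revcomp: bool = True) -> str | None:
    """Classify a junction insertion as templated/untemplated; empty -> NA."""
    if not ins_seq:
        return None
    bp_a, bp_b = breakpoints
    if insertion_is_templated(ins_seq, ref_a, bp_a, ref_b, bp_b, window,
                              include_revcomp):
        return "templated"
    return "untemplated"


def _window_identity(seq1: str, seq2: str, center: int, half: int = 50) -> float:
    lo = max(0, center - half)
    hi = min(len(seq1), len(seq2), center + half)
    if hi <= lo:
        return 1.0
    w1, w2 = seq1[lo:hi], seq2[lo:hi]
    same = sum(a == b for a, b in zip(w1, w2))
    return same / (hi - lo)


def classify_fusion(sa: SplitAlignment, refs, family_margin: float = 0.02) -> str:
    """Assign the fusion category of a resolved split alignment.

    Within a homologous subtelomere family, intra-chromosomal status is
    assigned only where identity to the archetype exceeds identity to every
    sibling by at least `family_margin`; otherwise the conservative ``inter``
    label is used.
    """
    index = _as_index(refs)
    a_sub = index.targets[sa.a_target].subtel
    b_t = index.targets[sa.b_target]
    if b_t.kind == "genome":
        return "genomic"
    b_sub = b_t.subtel
    if b_sub.family_id != a_sub.family_id:
        return "inter"
    members = index.family_members(a_sub.family_id)
    if len(members) == 1:
        return "intra"
    if not b_sub.archetype or a_sub.end_id != b_sub.end_id:
        return "inter"
    _, fwd_bp, _ = index.forward_coord(sa.b_target, sa.b_ref_start)
    for sib in members:
        if sib.end_id == b_sub.end_id:
            continue
        ident = _window_identity(b_sub.sequence, sib.sequence, fwd_bp)
        if 1.0 - ident < family_margin:
            return "inter"
    return "intra"


# ---------------------------------------------------------------------------
# deletions
# ---------------------------------------------------------------------------

def compute_deletion(breakpoint: int, ref: SubtelomereRef) -> int:
    """Subtelomeric sequence lost relative to the telomere-repeat boundary."""
    if breakpoint > ref.telomere_boundary:
        raise ValueError(
            f"breakpoint {breakpoint} beyond telomere boundary "
            f"{ref.telomere_boundary} on {ref.end_id}"
        )
    if breakpoint <= ref.primer_offset:
        raise ValueError(f"breakpoint {breakpoint} not downstream of primer on {ref.end_id}")
    return ref.telomere_boundary - breakpoint


def delta_deletion(deletions: tuple[int, int]) -> int:
    """|d1 - d2| for the two fused chromatid ends of an intra call."""
    d1, d2 = deletions
    return abs(int(d1) - int(d2))


# ---------------------------------------------------------------------------
# dedupe + summaries
# ---------------------------------------------------------------------------

def dedupe_calls(calls: list[FusionCall], tol: int = 5) -> list[FusionCall]:
    """Merge calls agreeing in category, end and both breakpoints within tol.

    Support is summed; junction metrics are taken from the highest-support
    member (first by coordinate on ties).  Never merges across categories,
    ends, partner references or strands.
    """
    groups: dict[tuple, list[FusionCall]] = defaultdict(list)
    for c in calls:
        key = (c.sample, c.category, c.end_id, c.partner[0], c.partner[2], c.resolution)
        groups[key].append(c)
    out: list[FusionCall] = []
    for key in sorted(groups):
        members = sorted(groups[key],
                         key=lambda c: (c.subtel_breakpoint, c.partner[1]))
        cluster: list[FusionCall] = []

        def _flush():
            if not cluster:
                return
            rep = max(cluster, key=lambda c: c.support)
            merged = replace(rep, support=sum(c.support for c in cluster))
            out.append(merged)

        for c in members:
            if cluster and (abs(c.subtel_breakpoint - cluster[0].subtel_breakpoint) <= tol
                            and abs(c.partner[1] - cluster[0].partner[1]) <= tol):
                cluster.append(c)
            else:
                _flush()
                cluster = [c]
        _flush()
    for i, c in enumerate(out):
        c.call_id = f"{c.sample}.{i:05d}"
    return out


def junction_histogram(calls: list[FusionCall], end_id: str,
                       subtel: SubtelomereRef, bin: int = 100) -> pd.Series:
    """Per-bin junction frequency along a subtelomere (primer -> boundary)."""
    if bin <= 0:
        raise ValueError("bin must be positive")
    lo, hi = subtel.primer_offset, subtel.telomere_boundary
    edges = np.arange(lo, hi + bin, bin)
    pts = [c.subtel_breakpoint for c in calls if c.end_id == end_id]
    counts, _ = np.histogram(pts, bins=edges)
    return pd.Series(counts, index=edges[:-1], name=end_id)


def summarize_junctions(calls: list[FusionCall], group_by: str = "stage") -> pd.DataFrame:
    """Per-group MH/INS summaries and class proportions (base calls only)."""
    if not calls:
        raise ValueError("no calls to summarize")
    rows = []
    base = [c for c in calls if c.resolution == "base"]
    groups: dict[str, list[FusionCall]] = defaultdict(list)
    for c in base:
        groups[getattr(c, group_by)].append(c)
    for g in sorted(groups):
        cs = groups[g]
        if not cs:
            logger.warning("group %s has no base-resolution calls; omitted", g)
            continue
        mh = np.array([c.mh_bp for c in cs], dtype=float)
        ins_len = np.array([len(c.ins_seq) for c in cs if c.ins_seq], dtype=float)
        ins_calls = [c for c in cs if c.ins_seq]
        row = {
            group_by: g,
            "n": len(cs),
            "mean_mh_bp": float(mh.mean()),
            "median_mh_bp": float(np.median(mh)),
            "frac_with_mh": float((mh > 0).mean()),
            "mean_ins_bp": float(ins_len.mean()) if ins_len.size else 0.0,
            "frac_with_ins": len(ins_calls) / len(cs),
            "frac_ins_templated": (
                sum(c.ins_templated == "templated" for c in ins_calls) / len(ins_calls)
                if ins_calls else float("nan")
            ),
        }
        for cat in CATEGORIES:
            row[f"prop_{cat}"] = sum(c.category == cat for c in cs) / len(cs)
        rows.append(row)
    return pd.DataFrame(rows).set_index(group_by)


def fusion_frequency_per_genome(mean_amplicons_per_reaction: float,
                                input_ng: float,
                                pg_per_diploid_genome: float = 6.6) -> float:
    """Fusion frequency per diploid genome from amplicon yield and DNA input."""
    if input_ng <= 0:
        raise ValueError("input_ng must be positive")
    genomes = input_ng * 1000.0 / pg_per_diploid_genome
    return mean_amplicons_per_reaction / genomes


# ---------------------------------------------------------------------------
# end-to-end calling
# ---------------------------------------------------------------------------

def call_fusions(reads, refs, sample: str = "S1", stage: str = "Early",
                 k: int = 21, max_mismatch: int = 2, tol: int = 5,
                 family_margin: float = 0.02, ins_window: int = 100,
                 merge_min_overlap: int = 20,
                 stats: dict | None = None) -> list[FusionCall]:
    """Full pipeline: paired reads -> merged fragments -> unique fusion calls.

    `reads` is a `telocrisis.reads.PairedReads` (mates are merged into full
    fragments where they overlap; unmergeable mates are aligned singly) or an
    iterable of ``(read_id, sequence)`` in amplicon orientation.
    """
    from .reads import PairedReads, merge_pair

    index = _as_index(refs, k)
    st = stats if stats is not None else {}
    seqs: list[tuple[str, str]] = []
    if isinstance(reads, PairedReads):
        merged = 0
        for rid, r1, r2 in reads:
            frag = merge_pair(r1, r2, min_overlap=merge_min_overlap,
                              max_mismatch=max_mismatch)
            if frag is not None:
                merged += 1
                seqs.append((rid, frag))
            else:
                seqs.append((rid + "/1", r1))
                seqs.append((rid + "/2", revcomp(r2)))
        st["pairs"] = len(reads)
        st["merged_pairs"] = merged
    else:
        seqs = list(reads)
    sas = split_align(seqs, index, k=k, max_mismatch=max_mismatch, stats=st)

    records: list[FusionCall] = []
    st.setdefault("out_of_zone", 0)
    st.setdefault("unclassifiable", 0)
    for sa in sas:
        (subtel_bp, b_bp), mh, ins = resolve_junction(sa, index)
        a_sub = index.targets[sa.a_target].subtel
        if not (a_sub.primer_offset < subtel_bp <= a_sub.telomere_boundary):
            st["out_of_zone"] += 1
            continue
        category = classify_fusion(sa, index, family_margin)
        partner = index.forward_coord(sa.b_target, b_bp)
        ins_templated = None
        if ins:
            b_seq = index.targets[sa.b_target].seq
            ins_templated = classify_insertion(
                ins, a_sub.sequence, b_seq, (subtel_bp, b_bp), window=ins_window)
        records.append(FusionCall(
            sample=sample, stage=stage, end_id=a_sub.end_id,
            subtel_breakpoint=subtel_bp, partner=partner, category=category,
            mh_bp=mh, ins_seq=ins, ins_templated=ins_templated))

    calls = dedupe_calls(records, tol=tol)
    for c in calls:
        sub = index.by_end[c.end_id]
        d1 = compute_deletion(c.subtel_breakpoint, sub)
        d2: int | None = None
        if c.category in ("intra", "inter") and c.partner[0] in index.by_end:
            psub = index.by_end[c.partner[0]]
            if psub.primer_offset < c.partner[1] <= psub.telomere_boundary:
                d2 = compute_deletion(c.partner[1], psub)
        c.deletion_bp = (d1, d2)
        if c.category == "intra" and d2 is not None:
            c.delta_deletion_bp = delta_deletion((d1, d2))
    st["events"] = len(calls)
    logger.info("call_fusions: %s", {k_: v for k_, v in st.items()})
    return calls


def split_alignments_from_sam(path, refs, min_len: int = 21) -> list[SplitAlignment]:
    """Build split alignments from a SAM file with supplementary alignments.

    Accepts reads whose primary alignment lies on a subtelomere reference and
    that carry an ``SA`` tag pointing at the partner locus.  This is the
    alternative input path for externally mapped data; the built-in aligner
    (`split_align`) is the default route.
    """
    import pysam

    index = _as_index(refs)
    name_to_ti = {(t.name, t.strand): i for i, t in enumerate(index.targets)}
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_supplementary or not rec.has_tag("SA"):
                continue
            if (rec.reference_name, "+") not in name_to_ti:
                continue
            a_ti = name_to_ti[(rec.reference_name, "+")]
            if index.targets[a_ti].kind != "subtel" or rec.is_reverse:
                continue
            sa_tag = rec.get_tag("SA").split(";")[0]
            rname, pos, strand, cigar, _, _ = sa_tag.split(",")
            if (rname, strand) not in name_to_ti:
                continue
            b_ti = name_to_ti[(rname, strand)]
            seq = rec.query_sequence
            a_len = rec.query_alignment_end
            b_len = len(seq) - _clip_left(cigar)
            b_fwd = int(pos) - 1
            t = index.targets[b_ti]
            b_start = b_fwd if strand == "+" else len(t.seq) - b_fwd - b_len
            if a_len < min_len or b_len < min_len:
                continue
            out.append(SplitAlignment(rec.query_name, seq, a_ti,
                                      rec.reference_start - rec.query_alignment_start,
                                      a_len, b_ti, b_start, b_len))
    return out


def _clip_left(cigar: str) -> int:
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "SH":
                return int(num)
            return 0
    return 0
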