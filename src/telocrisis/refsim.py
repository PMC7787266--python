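"""Synthetic references, fusions, simulants, reads, nuclei bins and counts.

This module generates every data layer of a desk-scale telomere-crisis
experiment with recorded ground truth:

* a minigenome plus primer-targeted subtelomere references (17p, XpYp and a
  homologous 21q family with one archetype), with annotation tracks;
* biological fusion events with parameterized microhomology (MH), templated
  or untemplated insertions (INS) and per-end subtelomeric deletions;
* "simulant" null fusions - breakpoints uniform along each subtelomere and
  over the genome, MH 0, no insertions - rendered into reads through the
  identical machinery so downstream calling is methodology-matched;
* paired-end amplicon reads with substitution errors;
* single-nucleus bin counts against a pooled-nuclei bulk baseline;
* stage-labelled gene x sample count matrices with programmed fold changes.

Every generator is a pure function of (config, seed); independent named RNG
streams are derived from the single seed by stable sub-seeding.

Microhomology is injected by overwriting the k junction-proximal bases of
the partner *reference* with the subtelomere-side continuation, so the k
bases at the junction genuinely match both references and breakpoint
enumeration recovers k.  Junction-critical bases of every planned event are
tracked, and later edits are never allowed to land on them: the recorded
truth stays exact by construction.  Insertions and MH are mutually exclusive
per junction (exact-match model), keeping truth unambiguous.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import random_dna, mutate, revcomp, substream
from .enrich import FeatureTrack
from .exprlink import ExpressionMatrix
from .cnacall import BinProfile, CnaSegment
from .fusioncall import SubtelomereRef, insertion_is_templated
from .reads import PairedReads

logger = logging.getLogger(__name__)

_COMP_B = bytes.maketrans(b"ACGT", b"TGCA")

# RNG stream ids (stable sub-seeding)
_STREAM_REFERENCE = 0
_STREAM_FUSIONS = 1
_STREAM_READS = 2
_STREAM_SIMULANTS = 3
_STREAM_NUCLEI = 4
_STREAM_COUNTS = 5


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic experiment.

    Distances are bp.  `coverage` is the mean per-base fragment depth over an
    amplicon (the expected read-pair count of an amplicon of length L is
    coverage * L / frag_mean).  `class_mix` is the (genomic, intra, inter)
    probability vector.  `mh_mean` parameterizes a geometric MH-length law on
    {0, 1, 2, ...}; `deletion_range` bounds the uniform per-end subtelomeric
    deletion.  `subtel_ltr_avoidance` is the probability that a biological
    breakpoint landing in a subtelomeric LTR interval is redrawn, emulating
    the depletion of fusion junctions in those elements (simulants never
    avoid them).
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_lengths: tuple[int, ...] = (120_000, 120_000, 120_000, 120_000)
    subtel_length: int = 11_000
    primer_offset: int = 100
    telomere_boundary: int = 10_100
    class_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)
    mh_mean: float = 2.0
    ins_prob: float = 0.3
    ins_len_range: tuple[int, int] = (1, 12)
    ins_templated_prob: float = 0.5
    deletion_range: tuple[int, int] = (0, 9_000)
    partner_len_range: tuple[int, int] = (500, 3_000)
    read_len: int = 250
    frag_mean: float = 450.0
    frag_sd: float = 40.0
    error_rate: float = 0.001
    coverage: float = 10.0
    n_family_siblings: int = 2
    sibling_divergence: float = 0.15
    subtel_ltr_avoidance: float = 0.9
    ins_window: int = 100
    gene_length_mean: float = 8000.0
    feature_density: dict = field(default_factory=lambda: {
        "genes": 0.30, "promoters": 0.02, "enhancers": 0.02,
        "fragile_sites": 0.30, "ltr": 0.03,
    })

    def validate(self) -> "SimConfig":
        probs = {"ins_prob": self.ins_prob,
                 "ins_templated_prob": self.ins_templated_prob,
                 "error_rate": self.error_rate,
                 "sibling_divergence": self.sibling_divergence,
                 "subtel_ltr_avoidance": self.subtel_ltr_avoidance}
        for name, v in probs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.class_mix) != 3 or any(p < 0 for p in self.class_mix):
            raise ValueError("class_mix needs 3 non-negative probabilities")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if len(self.chrom_lengths) != self.n_chroms:
            raise ValueError("chrom_lengths length must equal n_chroms")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chrom_lengths must be positive")
        if not (0 <= self.primer_offset < self.telomere_boundary
                <= self.subtel_length):
            raise ValueError(
                "require primer_offset < telomere_boundary <= subtel_length")
        if self.mh_mean < 0:
            raise ValueError("mh_mean must be non-negative")
        lo, hi = self.ins_len_range
        if not (1 <= lo <= hi):
            raise ValueError("ins_len_range must be a positive interval")
        dlo, dhi = self.deletion_range
        if not (0 <= dlo <= dhi):
            raise ValueError("deletion_range must be a non-negative interval")
        if dhi >= self.telomere_boundary - self.primer_offset:
            raise ValueError("deletion_range exceeds the breakpoint zone")
        plo, phi = self.partner_len_range
        if not (0 < plo <= phi):
            raise ValueError("partner_len_range must be a positive interval")
        if self.read_len > self.frag_mean:
            raise ValueError("read_len must not exceed frag_mean")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        return self


@dataclass
class TrueFusion:
    """Ground truth for one simulated fusion event."""

    id: str
    category: str                           # genomic | intra | inter
    end_id: str
    breakpoint: int                         # subtelomere side, leftmost
    partner: tuple[str, int, str]           # (chrom or end_id, pos, strand)
    partner_len: int
    mh_bp: int = 0
    ins_seq: str = ""
    ins_templated: bool | None = None
    deletion_bp: tuple[int, int | None] = (0, None)

    def __post_init__(self) -> None:
        if self.ins_seq and self.mh_bp != 0:
            raise ValueError("insertion and MH are mutually exclusive")
        if self.category == "intra" and self.partner[0] != self.end_id:
            raise ValueError("intra fusion must stay on one chromosome end")

    @property
    def endA(self) -> tuple[str, int]:
        return self.end_id, self.breakpoint

    @property
    def delta_deletion_bp(self) -> int | None:
        d1, d2 = self.deletion_bp
        if d2 is None:
            return None
        return abs(d1 - d2)


@dataclass
class SyntheticReference:
    """Minigenome + subtelomeres + annotation, regenerable from (cfg, seed)."""

    minigenome: dict[str, str]
    subtelomeres: list[SubtelomereRef]
    annotation: dict[str, FeatureTrack]
    seed: int

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.minigenome.items()}

    @property
    def by_end(self) -> dict[str, SubtelomereRef]:
        return {s.end_id: s for s in self.subtelomeres}

    @property
    def primer_ends(self) -> list[SubtelomereRef]:
        """Ends targeted by fusion primers (family archetypes + unique ends)."""
        return [s for s in self.subtelomeres if s.archetype]

    def subtel_ltr_track(self) -> FeatureTrack:
        iv = [(s.end_id, a, b) for s in self.subtelomeres
              for a, b in s.ltr_intervals]
        return FeatureTrack("subtel_ltr", iv)


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def build_reference(cfg: SimConfig) -> SyntheticReference:
    """Deterministically build minigenome, subtelomeres and annotation."""
    cfg.validate()
    rng = substream(cfg.seed, _STREAM_REFERENCE)
    minigenome = {f"chr{i + 1}": random_dna(rng, L)
                  for i, L in enumerate(cfg.chrom_lengths)}

    def _subtel(end_id, family_id, archetype=True, base_seq=None):
        if base_seq is None:
            core = random_dna(rng, cfg.telomere_boundary)
            tail_len = cfg.subtel_length - cfg.telomere_boundary
            tail = ("TTAGGG" * (tail_len // 6 + 1))[:tail_len]
            seq = core + tail
        else:
            seq = mutate(base_seq, cfg.sibling_divergence, rng)
        mid = (cfg.primer_offset + cfg.telomere_boundary) // 2
        ltr_start = mid + int(rng.integers(-500, 500))
        ltr = ((ltr_start, ltr_start + 400),)
        return SubtelomereRef(end_id, family_id, seq, cfg.primer_offset,
                              cfg.telomere_boundary, ltr, archetype)

    subtels = [_subtel("17p", "17p"), _subtel("XpYp", "XpYp")]
    arch = _subtel("21q", "21qfam")
    subtels.append(arch)
    for i in range(cfg.n_family_siblings):
        subtels.append(_subtel(f"21q-{i + 1}", "21qfam", archetype=False,
                               base_seq=arch.sequence))

    annotation = _build_annotation(cfg, minigenome, rng)
    ref = SyntheticReference(minigenome, subtels, annotation, cfg.seed)
    for track in annotation.values():
        track.compute_fraction(ref.chrom_sizes)
    return ref


def _build_annotation(cfg, minigenome, rng) -> dict[str, FeatureTrack]:
    dens = cfg.feature_density
    tracks: dict[str, FeatureTrack] = {}

    gene_iv, gene_names, gene_strands = [], [], []
    exon_iv = []
    prom_iv = []
    f_gene = dens.get("genes", 0.0)
    if f_gene > 0:
        mean_len = cfg.gene_length_mean
        gap_mean = mean_len * (1 - f_gene) / f_gene
        gi = 0
        for chrom, seq in minigenome.items():
            L = len(seq)
            pos = int(rng.exponential(gap_mean))
            while True:
                glen = int(np.clip(rng.lognormal(math.log(mean_len) - 0.32, 0.8),
                                   mean_len / 8, mean_len * 5))
                if pos + glen >= L:
                    break
                gene_iv.append((chrom, pos, pos + glen))
                gene_names.append(f"g{gi:04d}")
                gene_strands.append("+" if rng.random() < 0.5 else "-")
                # exon tiling: 150 bp every ~1.5 kb
                for es in range(pos, pos + glen - 150, 1500):
                    exon_iv.append((chrom, es, es + 150))
                if pos >= 500:
                    prom_iv.append((chrom, pos - 500, pos))
                gi += 1
                pos += glen + max(200, int(rng.exponential(gap_mean)))
    tracks["genes"] = FeatureTrack("genes", gene_iv, names=gene_names,
                                   strands=gene_strands)
    tracks["exons"] = FeatureTrack("exons", exon_iv)
    tracks["promoters"] = FeatureTrack("promoters", prom_iv)

    def _random_track(name, frac, width):
        iv = []
        if frac > 0:
            total = sum(len(s) for s in minigenome.values())
            count = max(1, int(frac * total / width))
            chroms = list(minigenome)
            sizes = np.array([len(minigenome[c]) for c in chroms], dtype=float)
            picks = rng.choice(len(chroms), size=count, p=sizes / sizes.sum())
            for ci in picks:
                L = len(minigenome[chroms[ci]])
                s = int(rng.integers(0, max(1, L - width)))
                iv.append((chroms[ci], s, s + width))
        return FeatureTrack(name, iv)

    tracks["enhancers"] = _random_track("enhancers", dens.get("enhancers", 0.0), 200)
    tracks["fragile_sites"] = _random_track("fragile_sites",
                                            dens.get("fragile_sites", 0.0), 20_000)
    tracks["ltr"] = _random_track("ltr", dens.get("ltr", 0.0), 300)
    return tracks


# ---------------------------------------------------------------------------
# fusion simulation
# ---------------------------------------------------------------------------

class _Workspace:
    """Editable view of the reference with junction-window bookkeeping."""

    def __init__(self, ref: SyntheticReference):
        self.ref = ref
        self.bufs: dict[str, bytearray] = {}
        for s in ref.subtelomeres:
            self.bufs[s.end_id] = bytearray(s.sequence, "ascii")
        for c, seq in ref.minigenome.items():
            self.bufs[c] = bytearray(seq, "ascii")
        self.protected: set[tuple[str, int]] = set()

    def oriented_base(self, key: str, strand: str, i: int) -> str:
        buf = self.bufs[key]
        if strand == "+":
            return chr(buf[i])
        return chr(_COMP_B[buf[len(buf) - 1 - i]])

    def oriented_slice(self, key: str, strand: str, lo: int, hi: int) -> str:
        buf = self.bufs[key]
        if strand == "+":
            return buf[lo:hi].decode("ascii")
        n = len(buf)
        return revcomp(buf[n - hi : n - lo].decode("ascii"))

    def forward_span(self, key: str, strand: str, lo: int, hi: int) -> range:
        if strand == "+":
            return range(lo, hi)
        n = len(self.bufs[key])
        return range(n - hi, n - lo)

    def is_free(self, key: str, strand: str, lo: int, hi: int) -> bool:
        return not any((key, p) in self.protected
                       for p in self.forward_span(key, strand, lo, hi))

    def protect(self, key: str, strand: str, lo: int, hi: int) -> None:
        for p in self.forward_span(key, strand, lo, hi):
            self.protected.add((key, p))

    def write_oriented(self, key: str, strand: str, lo: int, bases: str) -> None:
        buf = self.bufs[key]
        if strand == "+":
            buf[lo : lo + len(bases)] = bases.encode("ascii")
        else:
            n = len(buf)
            buf[n - lo - len(bases) : n - lo] = revcomp(bases).encode("ascii")

    def finalize(self) -> None:
        """Push edited sequences back into the SyntheticReference."""
        new_subtels = []
        for s in self.ref.subtelomeres:
            new_subtels.append(replace(s, sequence=self.bufs[s.end_id].decode("ascii")))
        self.ref.subtelomeres = new_subtels
        for c in self.ref.minigenome:
            self.ref.minigenome[c] = self.bufs[c].decode("ascii")


def _geometric_mh(rng, mean: float) -> int:
    """Geometric MH length on {0,1,2,...} with the given mean."""
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (1.0 + mean))) - 1


def _in_ltr(sub: SubtelomereRef, pos: int) -> bool:
    return any(a <= pos < b for a, b in sub.ltr_intervals)


def simulate_fusions(ref: SyntheticReference, cfg: SimConfig, n: int,
                     rng: np.random.Generator | None = None) -> list[TrueFusion]:
    """Draw `n` biological fusion events and inject their junctions.

    Categories follow `class_mix`; subtelomere breakpoints are telomere
    boundary minus a uniform deletion; genomic partners are uniform over the
    minigenome; MH lengths are geometric with mean `mh_mean`; insertions
    occur with `ins_prob` (forcing MH 0).  MH is injected by editing the
    partner reference, so `ref` is updated in place: render amplicons and
    build alignment indexes from the reference *after* this call.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    cfg.validate()
    rng = rng if rng is not None else substream(cfg.seed, _STREAM_FUSIONS)
    ws = _Workspace(ref)
    fusions = _plan_events(ws, cfg, n, rng, simulant=False)
    ws.finalize()
    # Templating truth is a statement about the *final* reference: a later
    # MH edit can land inside a +/-window flank and turn an unmatched
    # insertion into a templated one, so the flag is recomputed here with
    # the same search the caller applies.
    by_end = ref.by_end
    for f in fusions:
        if not f.ins_seq:
            continue
        key, pos, strand = f.partner
        seq = by_end[key].sequence if key in by_end else ref.minigenome[key]
        oriented = seq if strand == "+" else revcomp(seq)
        b0 = pos if strand == "+" else len(seq) - pos
        sub = by_end[f.end_id]
        f.ins_templated = insertion_is_templated(
            f.ins_seq, sub.sequence, f.breakpoint, oriented, b0,
            window=cfg.ins_window)
    return fusions


def generate_simulants(ref: SyntheticReference, n: int, cfg: SimConfig,
                       with_reads: bool = True,
                       rng: np.random.Generator | None = None):
    """Simulant null fusions: uniform breakpoints, MH 0, no insertions.

    Reads (when requested) are produced by the identical `generate_reads`
    path so that downstream calling is methodology-matched.  Returns
    (truth list, PairedReads or None).
    """
    if n < 1:
        raise ValueError("need n >= 1 simulants")
    cfg.validate()
    rng = rng if rng is not None else substream(cfg.seed, _STREAM_SIMULANTS)
    ws = _Workspace(ref)
    truth = _plan_events(ws, cfg, n, rng, simulant=True)
    # no edits are made for simulants; nothing to finalize
    reads = None
    if with_reads:
        amps = [(t.id, render_amplicon(t, ref)) for t in truth]
        reads, _ = generate_reads(amps, cfg, rng=rng)
    return truth, reads


def _plan_events(ws: _Workspace, cfg: SimConfig, n: int, rng,
                 simulant: bool) -> list[TrueFusion]:
    ref = ws.ref
    ends = ref.primer_ends
    all_subtels = ref.subtelomeres
    chroms = list(ref.minigenome)
    sizes = np.array([len(ref.minigenome[c]) for c in chroms], dtype=float)
    chrom_p = sizes / sizes.sum()
    prefix = "S" if simulant else "F"
    dlo, dhi = cfg.deletion_range
    plo, phi = cfg.partner_len_range
    boundary = cfg.telomere_boundary
    out: list[TrueFusion] = []
    for i in range(n):
        cat = ("genomic", "intra", "inter")[rng.choice(3, p=cfg.class_mix)]
        sub = ends[rng.integers(len(ends))]
        aseq = ws.bufs[sub.end_id]
        if simulant:
            has_ins, k, ins_len = False, 0, 0
        else:
            has_ins = rng.random() < cfg.ins_prob
            k = 0 if has_ins else _geometric_mh(rng, cfg.mh_mean)
            ins_len = int(rng.integers(cfg.ins_len_range[0],
                                       cfg.ins_len_range[1] + 1)) if has_ins else 0
        for attempt in range(2000):
            if simulant:
                bpA = int(rng.integers(cfg.primer_offset + 1, boundary + 1))
                delA = boundary - bpA
            else:
                delA = int(rng.integers(dlo, dhi + 1))
                bpA = boundary - delA
                if (cfg.subtel_ltr_avoidance > 0 and _in_ltr(sub, bpA)
                        and rng.random() < cfg.subtel_ltr_avoidance):
                    continue
            # --- partner draw ---
            if cat == "genomic":
                ci = int(rng.choice(len(chroms), p=chrom_p))
                key = chroms[ci]
                olen = int(sizes[ci])
                strand = "+" if rng.random() < 0.5 else "-"
                L = int(rng.integers(plo, phi + 1))
                if olen <= L + k + 2:
                    continue
                bpB = int(rng.integers(1, olen - L))
                partner_fwd = bpB if strand == "+" else olen - bpB
                delB: int | None = None
            else:
                if cat == "intra":
                    psub = sub
                else:
                    others = [s for s in all_subtels if s.end_id != sub.end_id]
                    psub = others[rng.integers(len(others))]
                key = psub.end_id
                olen = len(ws.bufs[key])
                strand = "-"
                if simulant:
                    bpB_f = int(rng.integers(cfg.primer_offset + 1, boundary + 1))
                    delB = boundary - bpB_f
                else:
                    delB = int(rng.integers(dlo, dhi + 1))
                    bpB_f = boundary - delB
                    if (cfg.subtel_ltr_avoidance > 0 and _in_ltr(psub, bpB_f)
                            and rng.random() < cfg.subtel_ltr_avoidance):
                        continue
                Lhi = min(phi, bpB_f)
                if Lhi < min(plo, bpB_f):
                    continue
                L = int(rng.integers(min(plo, Lhi), Lhi + 1))
                if L <= k + 1:
                    continue
                bpB = olen - bpB_f          # oriented coordinate
                partner_fwd = bpB_f
            if bpB < 1 or bpB + max(L, k + 1) > olen:
                continue
            # --- junction base conditions on the current sequences ---
            a_left = chr(aseq[bpA - 1])
            a_stop = chr(aseq[bpA + k]) if bpA + k < len(aseq) else None
            if a_stop is None:
                continue
            b_left = ws.oriented_base(key, strand, bpB - 1)
            b_stop = ws.oriented_base(key, strand, bpB + k)
            if b_left == a_left:
                continue                     # would allow leftward MH creep
            if not has_ins and b_stop == a_stop:
                continue                     # would extend MH past k
            if simulant:
                break
            # --- write-region conflicts ---
            # Windows of past events are protected from *writes*; reading
            # across them is harmless.  Only the MH edit needs a clear span.
            if k > 0:
                if not ws.is_free(key, strand, bpB, bpB + k):
                    continue
                if key == sub.end_id:
                    # intra self-conflict: the write must not touch the A window
                    wspan = set(ws.forward_span(key, strand, bpB, bpB + k))
                    aspan = set(range(bpA - 1, bpA + k + 1))
                    if wspan & aspan:
                        continue
            break
        else:
            raise RuntimeError("could not place fusion event; "
                               "reference too small for requested structure")

        ins_seq = ""
        ins_templated: bool | None = None
        if not simulant:
            if k > 0:
                mh_bases = aseq[bpA : bpA + k].decode("ascii")
                ws.write_oriented(key, strand, bpB, mh_bases)
            if has_ins:
                ins_seq, ins_templated, src = _draw_insertion(
                    ws, cfg, rng, sub, bpA, key, strand, bpB, ins_len)
                if src is not None:
                    skey, sstrand, slo, shi = src
                    ws.protect(skey, sstrand, slo, shi)
            ws.protect(sub.end_id, "+", bpA - 1, bpA + k + 1)
            ws.protect(key, strand, bpB - 1, bpB + k + 1)

        out.append(TrueFusion(
            id=f"{prefix}{i:06d}", category=cat, end_id=sub.end_id,
            breakpoint=bpA, partner=(key, partner_fwd, strand), partner_len=L,
            mh_bp=k, ins_seq=ins_seq, ins_templated=ins_templated,
            deletion_bp=(boundary - bpA, delB)))
    return out


def _draw_insertion(ws, cfg, rng, sub, bpA, bkey, bstrand, bpB, ins_len):
    """Insertion sequence honouring junction-stop and templating truth."""
    a_next = chr(ws.bufs[sub.end_id][bpA])
    b_left = ws.oriented_base(bkey, bstrand, bpB - 1)
    w = cfg.ins_window
    templated = rng.random() < cfg.ins_templated_prob
    for _ in range(2000):
        src = None
        if templated:
            side = rng.integers(2)
            key, strand, bp, olen = ((sub.end_id, "+", bpA, len(ws.bufs[sub.end_id]))
                                     if side == 0 else
                                     (bkey, bstrand, bpB, len(ws.bufs[bkey])))
            lo = max(0, bp - w)
            hi = min(olen - ins_len, bp + w)
            if hi <= lo:
                continue
            s = int(rng.integers(lo, hi))
            ins = ws.oriented_slice(key, strand, s, s + ins_len)
            if rng.random() < 0.5:
                ins = revcomp(ins)
            src = (key, strand, s, s + ins_len)
        else:
            ins = random_dna(rng, ins_len)
        if ins[0] == a_next or ins[-1] == b_left:
            continue
        if _insertion_mimics_read_error(ws, cfg, sub, bpA, bkey, bstrand,
                                        bpB, ins):
            continue
        if not templated and ins_len >= 4:
            ref_a = ws.bufs[sub.end_id].decode("ascii")
            ref_b_or = ws.oriented_slice(bkey, bstrand, max(0, bpB - w - ins_len),
                                         min(len(ws.bufs[bkey]), bpB + w + ins_len))
            # absence check against both +/-window flanks, both orientations
            if insertion_is_templated(ins, ref_a, bpA, ref_b_or,
                                      min(bpB, w + ins_len), window=w):
                continue
        return ins, templated, src
    raise RuntimeError("could not draw a junction insertion")


def _insertion_mimics_read_error(ws, cfg, sub, bpA, bkey, bstrand, bpB, ins):
    """True when the caller could step the insertion as a sequencing error.

    The caller treats an isolated flank mismatch followed by a long perfect
    run as a read error; an insertion templated from the bases immediately
    continuing either flank would reproduce exactly that signature, so such
    draws are rejected to keep the recorded truth resolvable.
    """
    from .fusioncall import MISMATCH_RUN_GUARD as guard

    olen_b = len(ws.bufs[bkey])
    a_cont = ws.bufs[sub.end_id][bpA + 1 : bpA + 1 + guard].decode("ascii")
    follow = (ins + ws.oriented_slice(bkey, bstrand, bpB,
                                      min(olen_b, bpB + guard)))[1 : 1 + guard]
    if len(a_cont) == guard and follow == a_cont:
        return True
    a_tail = ws.bufs[sub.end_id][max(0, bpA - guard) : bpA].decode("ascii")
    lead = (a_tail + ins)[:-1][-guard:]
    b_prec = ws.oriented_slice(bkey, bstrand, max(0, bpB - 1 - guard), bpB - 1)
    return len(b_prec) == guard and lead == b_prec


# ---------------------------------------------------------------------------
# amplicon + read rendering
# ---------------------------------------------------------------------------

def render_amplicon(f: TrueFusion, ref: SyntheticReference) -> str:
    """Amplicon sequence: primer->breakpoint segment + [INS] + partner segment.

    When ``mh_bp = k > 0`` the k bases at the junction match both references
    (by construction of `simulate_fusions`), so the partner segment begins
    with the single shared MH copy.
    """
    sub = ref.by_end[f.end_id]
    if not (sub.primer_offset < f.breakpoint <= sub.telomere_boundary):
        raise ValueError(f"breakpoint {f.breakpoint} outside the breakpoint "
                         f"zone of {f.end_id}")
    a_part = sub.sequence[sub.primer_offset : f.breakpoint]
    key, pos, strand = f.partner
    if key in ref.by_end:
        seq = ref.by_end[key].sequence
    else:
        seq = ref.minigenome[key]
    if strand == "+":
        b_part = seq[pos : pos + f.partner_len]
    else:
        b_part = revcomp(seq[pos - f.partner_len : pos])
    return a_part + f.ins_seq + b_part


def generate_reads(amplicons, cfg: SimConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[PairedReads, int]:
    """Paired-end reads from pooled amplicons.

    Fragments are Normal(frag_mean, frag_sd) truncated to the amplicon; the
    expected pair count of an amplicon is coverage * length / frag_mean.
    Mate 2 is the reverse complement end of the fragment.  Per-base
    substitution errors at `error_rate`.  Amplicons shorter than the read
    length are skipped with a warning; the skip count is returned.
    """
    if not amplicons:
        raise ValueError("no amplicons to sequence")
    cfg.validate()
    rng = rng if rng is not None else substream(cfg.seed, _STREAM_READS)
    pairs = PairedReads()
    skipped = 0
    rl = cfg.read_len
    for item in amplicons:
        amp_id, seq = item if isinstance(item, tuple) else (f"amp{id(item)}", item)
        L = len(seq)
        if L < rl:
            skipped += 1
            continue
        n_pairs = int(rng.poisson(cfg.coverage * L / cfg.frag_mean))
        if n_pairs == 0:
            continue
        flen = np.clip(np.rint(rng.normal(cfg.frag_mean, cfg.frag_sd, n_pairs)),
                       rl, L).astype(int)
        starts = (rng.random(n_pairs) * (L - flen + 1)).astype(int)
        for j in range(n_pairs):
            frag = seq[starts[j] : starts[j] + flen[j]]
            r1 = frag[:rl]
            r2 = revcomp(frag)[:rl]
            if cfg.error_rate > 0:
                r1 = mutate(r1, cfg.error_rate, rng)
                r2 = mutate(r2, cfg.error_rate, rng)
            pairs.append(f"{amp_id}|{j}", r1, r2)
    if skipped:
        logger.warning("generate_reads: skipped %d amplicons shorter than "
                       "read length", skipped)
    return pairs, skipped


# ---------------------------------------------------------------------------
# nuclei bins
# ---------------------------------------------------------------------------

def make_bins(ref: SyntheticReference, n_bins: int = 2000) -> pd.DataFrame:
    """Equal-width bins tiling the minigenome."""
    total = sum(ref.chrom_sizes.values())
    width = max(1, total // n_bins)
    rows = []
    for chrom, size in ref.chrom_sizes.items():
        for s in range(0, size - width + 1, width):
            rows.append({"chrom": chrom, "start": s, "end": s + width})
    return pd.DataFrame(rows)


def simulate_nuclei_bins(ref: SyntheticReference,
                         truth_segments: list[CnaSegment],
                         n_nuclei: int = 23, depth: float = 500.0,
                         n_bins: int = 2000, gain_ratio: float = 1.25,
                         loss_ratio: float = 0.75, bulk_pool: int = 500,
                         rng: np.random.Generator | None = None,
                         seed: int | None = None) -> BinProfile:
    """Poisson bin counts for 4N nuclei against a pooled neutral bulk.

    Per-bin counts are Poisson(depth x copy ratio), ratio 1 for neutral bins,
    `gain_ratio` (default 5/4, one extra copy on 4N) inside gain segments and
    `loss_ratio` (3/4) inside losses; the bulk is the aggregate of
    `bulk_pool` neutral nuclei.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    bins = make_bins(ref, n_bins)
    if bins.empty:
        raise ValueError("empty bin set")
    if rng is None:
        rng = substream(seed if seed is not None else ref.seed, _STREAM_NUCLEI)
    nb = len(bins)
    nuclei = [f"n{i:02d}" for i in range(n_nuclei)]
    lam = np.full((n_nuclei, nb), float(depth))
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    chrom_arr = bins["chrom"].to_numpy()
    for seg in truth_segments:
        ni = nuclei.index(seg.nucleus)
        ratio = gain_ratio if seg.call == "gain" else loss_ratio
        inside = (chrom_arr == seg.chrom) & (starts >= seg.start) & (ends <= seg.end)
        lam[ni, inside] = depth * ratio
    counts = rng.poisson(lam)
    bulk = rng.poisson(float(depth) * bulk_pool, size=nb)
    return BinProfile(bins,
                      pd.DataFrame(counts, index=nuclei),
                      pd.Series(bulk))


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def simulate_counts(ref: SyntheticReference, stage_effects: dict,
                    reps: int = 3, base_mean: float = 100.0,
                    base_sigma: float = 0.5, dispersion: float = 0.002,
                    libsize_range: tuple[float, float] = (0.5, 2.0),
                    stages: tuple[str, ...] = ("Early", "Deep", "Late"),
                    line: str = "sim",
                    rng: np.random.Generator | None = None,
                    seed: int | None = None) -> ExpressionMatrix:
    """Stage-labelled count matrix with programmed per-stage fold changes.

    Counts are negative-binomial (gamma-Poisson, variance mu + a*mu^2 with
    a = `dispersion`, default 0.002: tight technical-replicate noise so that
    triplicate null fold changes stay within ~|log2 FC| < 0.5 at mean 100);
    per-gene baselines are log-normal around `base_mean`;
    library sizes vary uniformly over `libsize_range`.  `stage_effects` maps
    gene id -> {stage: fold} (fold > 0) applied multiplicatively.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    genes_track = ref.annotation["genes"]
    genes = list(genes_track.names or [])
    if not genes:
        raise ValueError("reference has no gene annotation")
    for g, folds in stage_effects.items():
        if g not in set(genes):
            raise ValueError(f"unknown gene id in stage_effects: {g}")
        fmap = folds if isinstance(folds, dict) else {s: folds for s in stages}
        if any(f <= 0 for f in fmap.values()):
            raise ValueError("fold changes must be positive")
    if rng is None:
        rng = substream(seed if seed is not None else ref.seed, _STREAM_COUNTS)

    base = base_mean * rng.lognormal(mean=-base_sigma ** 2 / 2,
                                     sigma=base_sigma, size=len(genes))
    gene_ix = {g: i for i, g in enumerate(genes)}
    cols = {}
    sample_rows = []
    for stage in stages:
        for r in range(reps):
            sid = f"{line}_{stage}_{r}"
            lib = rng.uniform(*libsize_range)
            mu = base.copy()
            for g, folds in stage_effects.items():
                fmap = folds if isinstance(folds, dict) else {s: folds for s in stages}
                if stage in fmap:
                    mu[gene_ix[g]] *= fmap[stage]
            mu = mu * lib
            if dispersion > 0:
                lam = rng.gamma(shape=1.0 / dispersion,
                                scale=mu * dispersion)
            else:
                lam = mu
            cols[sid] = rng.poisson(lam)
            sample_rows.append({"sample": sid, "line": line, "stage": stage})
    counts = pd.DataFrame(cols, index=genes)
    samples = pd.DataFrame(sample_rows).set_index("sample")
    gi = pd.DataFrame(
        [{"gene": n, "chrom": c, "start": s, "end": e}
         for (c, s, e), n in zip(genes_track.intervals, genes_track.names)]
    ).set_index("gene")
    return ExpressionMatrix(counts, samples, gene_intervals=gi)
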