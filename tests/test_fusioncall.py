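"""Fusion caller: junction resolution, classification, dedupe, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from telocrisis._seq import random_dna, revcomp, substream
from telocrisis.fusioncall import (
    FusionCall,
    ReferenceIndex,
    SplitAlignment,
    SubtelomereRef,
    call_fusions,
    classify_fusion,
    classify_insertion,
    compute_deletion,
    dedupe_calls,
    delta_deletion,
    fusion_frequency_per_genome,
    junction_histogram,
    resolve_junction,
    split_align,
    summarize_junctions,
)
from telocrisis.reference import enumerate_split_placements
from telocrisis.refsim import (
    SimConfig,
    build_reference,
    generate_reads,
    render_amplicon,
    simulate_fusions,
)


def _mini_refs(seed=0, sub_len=3000):
    """Tiny single-subtelomere + single-chromosome reference set."""
    rng = substream(seed, 99)
    sub = SubtelomereRef("17p", "17p", random_dna(rng, sub_len), 50, sub_len - 200)
    genome = {"chr1": random_dna(rng, 20_000)}
    return sub, genome


# ---------------------------------------------------------------------------
# resolve_junction
# ---------------------------------------------------------------------------

def test_resolve_doc_example_mh3():
    """refA ...AAAACCTG | refB CTGGTTTT... -> fused AAAACCTGGTTTT has MH 3."""
    ref_a = "TTTTTTTTTTAAAACCTG"
    ref_b = "CTGGTTTTAAAAAAAAAA"
    read = "AAAACCTGGTTTT"
    res = enumerate_split_placements(read, ref_a, 10, ref_b, 8)
    assert len(res["placements"]) == 4
    assert res["mh_bp"] == 3
    sa = SplitAlignment("r", read, 0, 10, 8, 1, 0, 8)
    (bp_a, bp_b), mh, ins = resolve_junction(sa, _FakeIndex([ref_a, ref_b]))
    assert mh == 3 and ins == ""
    assert bp_a == 15  # leftmost valid placement
    assert bp_b == 0


class _FakeIndex:
    """Minimal stand-in carrying only target sequences."""

    def __init__(self, seqs):
        class T:
            def __init__(self, s):
                self.seq = s
        self.targets = [T(s) for s in seqs]


def test_resolve_no_shared_bases_gives_mh0():
    ref_a = "CCCCCCCCCCACGT"
    ref_b = "TTTACCCCCCCCCC"
    read = "ACGTTTTA"
    res = enumerate_split_placements(read, ref_a, 10, ref_b, 4)
    assert res["mh_bp"] == 0 and res["placements"] == [4]


def test_resolve_insertion_matching_neither_flank():
    rng = substream(4, 98)
    ref_a = random_dna(rng, 60)
    ref_b = random_dna(rng, 60)
    first = next(b for b in "ACGT" if b != ref_a[30])
    last = next(b for b in "ACGT" if b != ref_b[29])
    ins = first + "GC" + last
    read = ref_a[10:30] + ins + ref_b[30:50]
    res = enumerate_split_placements(read, ref_a, 10, ref_b, 50)
    if res["placements"]:  # astronomically unlikely with random flanks
        pytest.skip("random flanks admitted a perfect placement")
    assert res["ins_seq"] == ins
    sa = SplitAlignment("r", read, 0, 10, 20, 1, 30, 20)
    (_, _), mh, called_ins = resolve_junction(sa, _FakeIndex([ref_a, ref_b]))
    assert mh == 0 and called_ins == ins


def test_resolver_matches_enumeration_on_random_junctions():
    """Sampled MH junctions: anchored-extension result == brute force."""
    rng = substream(12, 97)
    for _ in range(300):
        k = int(rng.integers(0, 9))
        a = random_dna(rng, 120)
        b_tail = random_dna(rng, 60)
        b = a[60 : 60 + k] + b_tail
        # enforce the junction stop condition the generator guarantees
        if b_tail[0] == a[60 + k]:
            continue
        read = a[20:60] + b[:40]
        res = enumerate_split_placements(read, a, 20, b, 40)
        sa_a_len = 40 + k
        sa = SplitAlignment("r", read, 0, 20, sa_a_len, 1, 0, 40)
        (_, _), mh, ins = resolve_junction(sa, _FakeIndex([a, b]))
        assert mh == res["mh_bp"] == k
        assert ins == res["ins_seq"] == ""


# ---------------------------------------------------------------------------
# classify_insertion
# ---------------------------------------------------------------------------

def test_classify_insertion_cases():
    rng = substream(5, 96)
    ref_a = random_dna(rng, 400)
    ref_b = random_dna(rng, 400)
    assert classify_insertion("", ref_a, ref_b, (200, 200)) is None
    ins = ref_a[160:168]  # copied verbatim 40 bp upstream of breakpoint 200
    assert classify_insertion(ins, ref_a, ref_b, (200, 200)) == "templated"
    # exhaustively verified absent 8-mer
    for _ in range(1000):
        probe = random_dna(rng, 8)
        wa = ref_a[92:308]
        wb = ref_b[92:308]
        if all(p not in w for p in (probe, revcomp(probe)) for w in (wa, wb)):
            break
    else:
        pytest.fail("could not build absent probe")
    assert classify_insertion(probe, ref_a, ref_b, (200, 200)) == "untemplated"


# ---------------------------------------------------------------------------
# classify_fusion / split_align on constructed reads
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cfg_ref():
    cfg = SimConfig(seed=42, error_rate=0.0)
    ref = build_reference(cfg)
    return cfg, ref


def test_split_align_contained_read_no_call(cfg_ref):
    _, ref = cfg_ref
    sub = ref.by_end["17p"]
    read = sub.sequence[500:750]
    stats = {}
    sas = split_align([("r1", read)], ref, stats=stats)
    assert sas == [] and stats["contained"] == 1


def test_split_align_empty_reference_errors():
    with pytest.raises(ValueError):
        ReferenceIndex([], {})
    with pytest.raises(ValueError):
        ReferenceIndex([SubtelomereRef("x", "x", "ACGT" * 100, 10, 350)], {}, k=5)


def test_split_align_classification_cases(cfg_ref):
    cfg, ref = cfg_ref
    sub17 = ref.by_end["17p"]
    # genomic: subtel prefix + chr2 segment
    read = sub17.sequence[3000:3150] + ref.minigenome["chr2"][5000:5150]
    sas = split_align([("g", read)], ref)
    assert len(sas) == 1
    assert classify_fusion(sas[0], ref) == "genomic"
    # intra on the unique 17p end: partner is the same subtelomere, reversed
    read = sub17.sequence[3000:3150] + revcomp(sub17.sequence[7000:7150])
    sas = split_align([("i", read)], ref)
    assert len(sas) == 1
    assert classify_fusion(sas[0], ref) == "intra"
    # inter: 17p joined to XpYp
    subx = ref.by_end["XpYp"]
    read = sub17.sequence[3000:3150] + revcomp(subx.sequence[6000:6150])
    sas = split_align([("x", read)], ref)
    assert len(sas) == 1
    assert classify_fusion(sas[0], ref) == "inter"
    # family rule: 21q archetype partner -> intra; sibling partner -> inter
    sub21 = ref.by_end["21q"]
    sib = ref.by_end["21q-1"]
    read = sub21.sequence[3000:3150] + revcomp(sub21.sequence[7000:7150])
    sas = split_align([("a", read)], ref)
    assert classify_fusion(sas[0], ref) == "intra"
    read = sub21.sequence[3000:3150] + revcomp(sib.sequence[7000:7150])
    sas = split_align([("s", read)], ref)
    assert classify_fusion(sas[0], ref) == "inter"


def test_family_margin_blocks_conserved_loci(cfg_ref):
    """A locus identical across the family cannot be called intra."""
    _, ref = cfg_ref
    sub21 = ref.by_end["21q"]
    sa_like = split_align(
        [("a", sub21.sequence[3000:3150] + revcomp(sub21.sequence[7000:7150]))],
        ref)[0]
    # with an impossible margin every family locus is 'conserved'
    assert classify_fusion(sa_like, ref, family_margin=1.0) == "inter"


def test_single_substitution_still_resolved(cfg_ref):
    cfg, ref = cfg_ref
    sub = ref.by_end["17p"]
    read = sub.sequence[3000:3150] + ref.minigenome["chr2"][5000:5150]
    mutated = read[:70] + ("A" if read[70] != "A" else "C") + read[71:]
    sas = split_align([("m", mutated)], ref, max_mismatch=2)
    assert len(sas) == 1
    (bp_a, _), _, _ = resolve_junction(sas[0], ref)
    assert bp_a == 3150


def test_max_mismatch_monotonicity(cfg_ref):
    """Raising max_mismatch never reduces recovered alignments."""
    cfg, ref = cfg_ref
    err_cfg = SimConfig(seed=42, error_rate=0.01)
    truth = simulate_fusions(ref, cfg, 40, rng=substream(1, 1))
    amps = [(t.id, render_amplicon(t, ref)) for t in truth]
    reads, _ = generate_reads(amps, err_cfg, rng=substream(2, 2))
    seqs = [(i, r) for i, r, _ in zip(reads.ids, reads.r1, reads.r2)]
    counts = [len(split_align(seqs, ref, max_mismatch=m)) for m in (0, 1, 2, 3)]
    assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# deletions
# ---------------------------------------------------------------------------

def test_deletion_arithmetic():
    sub = SubtelomereRef("17p", "17p", "A" * 5000, 100, 4500)
    assert compute_deletion(4500, sub) == 0
    assert compute_deletion(3000, sub) == 1500
    with pytest.raises(ValueError):
        compute_deletion(4600, sub)
    assert delta_deletion((1200, 3400)) == 2200


@given(st.integers(0, 10_000), st.integers(0, 10_000))
@settings(max_examples=50, deadline=None)
def test_delta_deletion_symmetry(a, b):
    assert delta_deletion((a, b)) == delta_deletion((b, a))


# ---------------------------------------------------------------------------
# dedupe
# ---------------------------------------------------------------------------

def _call(bp=1000, partner=("chr1", 500, "+"), category="genomic", support=1,
          mh=2):
    return FusionCall("s1", "Early", "17p", bp, partner, category,
                      mh_bp=mh, support=support)


def test_dedupe_merges_and_conserves_support():
    calls = [_call(), _call()]
    out = dedupe_calls(calls)
    assert len(out) == 1 and out[0].support == 2
    out = dedupe_calls([_call(1000), _call(1003)], tol=5)
    assert len(out) == 1
    out = dedupe_calls([_call(partner=("chr1", 500, "+")),
                        _call(partner=("chr2", 500, "+"))])
    assert len(out) == 2
    out = dedupe_calls([_call(category="genomic"), _call(category="intra")])
    assert len(out) == 2


@given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50),
                          st.integers(1, 4)), min_size=1, max_size=30))
@settings(max_examples=60, deadline=None)
def test_dedupe_conservation(items):
    calls = [_call(bp=1000 + a, partner=("chr1", 500 + b, "+"), support=s)
             for a, b, s in items]
    out = dedupe_calls(calls, tol=5)
    assert len(out) <= len(calls)
    assert sum(c.support for c in out) == sum(c.support for c in calls)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_junction_histogram_conservation():
    sub = SubtelomereRef("17p", "17p", "A" * 5000, 100, 4500)
    assert junction_histogram([], "17p", sub).sum() == 0
    calls = [_call(bp=777) for _ in range(9)]
    h = junction_histogram(calls, "17p", sub, bin=100)
    assert h.sum() == 9
    assert (h > 0).sum() == 1 and h.loc[700] == 9


def test_summarize_junctions_single_call_and_proportions():
    with pytest.raises(ValueError):
        summarize_junctions([])
    calls = [_call(mh=4)]
    tab = summarize_junctions(calls)
    assert tab.loc["Early", "mean_mh_bp"] == 4.0
    calls = [_call(mh=1), _call(bp=2000, category="intra"),
             _call(bp=3000, category="inter")]
    tab = summarize_junctions(calls)
    props = tab.loc["Early", ["prop_genomic", "prop_intra", "prop_inter"]]
    assert abs(props.sum() - 1.0) < 1e-12


def test_stage_mh_ratio_recovery():
    """Cohorts with mh_mean 3 vs 2 give a ~1.5x mean-MH ratio in calls."""
    means = {}
    for stage, mu, seed in (("Early", 3.0, 61), ("Late", 2.0, 62)):
        cfg = SimConfig(seed=seed, mh_mean=mu, ins_prob=0.0, error_rate=0.0,
                        class_mix=(1.0, 0.0, 0.0), deletion_range=(0, 2000))
        ref = build_reference(cfg)
        truth = simulate_fusions(ref, cfg, 2000)
        amps = [(t.id, render_amplicon(t, ref)) for t in truth]
        reads, _ = generate_reads(amps, cfg)
        calls = call_fusions(reads, ref, stage=stage)
        means[stage] = summarize_junctions(calls).loc[stage, "mean_mh_bp"]
    ratio = means["Early"] / means["Late"]
    assert abs(ratio - 1.5) / 1.5 < 0.10


# ---------------------------------------------------------------------------
# fusion frequency
# ---------------------------------------------------------------------------

def test_fusion_frequency_per_genome():
    assert fusion_frequency_per_genome(0, 25) == 0
    assert fusion_frequency_per_genome(1, 0.0066) == pytest.approx(1.0)
    assert fusion_frequency_per_genome(3, 50) == pytest.approx(3 / 7575.7575757, rel=1e-6)
    with pytest.raises(ValueError):
        fusion_frequency_per_genome(1, 0)
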