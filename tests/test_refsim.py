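"""Synthetic-data generator: determinism, truth laws, read properties."""

import numpy as np
import pytest
from scipy import stats as sps

from telocrisis._seq import revcomp, substream
from telocrisis.refsim import (
    SimConfig,
    build_reference,
    generate_reads,
    generate_simulants,
    render_amplicon,
    simulate_counts,
    simulate_fusions,
    simulate_nuclei_bins,
)
from telocrisis.reference import enumerate_split_placements


def test_invalid_config_names_offending_field():
    with pytest.raises(ValueError, match="class_mix"):
        SimConfig(class_mix=(0.5, 0.5, 0.5)).validate()
    with pytest.raises(ValueError, match="telomere_boundary"):
        SimConfig(primer_offset=5000, telomere_boundary=400).validate()
    with pytest.raises(ValueError, match="read_len"):
        SimConfig(read_len=900, frag_mean=400.0).validate()


def test_reference_construction_and_determinism():
    cfg = SimConfig(seed=5, n_chroms=2, chrom_lengths=(100_000, 100_000))
    ref1 = build_reference(cfg)
    ref2 = build_reference(cfg)
    assert sum(ref1.chrom_sizes.values()) == 200_000
    # 3 primer-targeted ends + 21q family siblings
    assert len(ref1.primer_ends) == 3
    assert len(ref1.subtelomeres) == 3 + cfg.n_family_siblings
    for s in ref1.subtelomeres:
        assert set(s.sequence) <= set("ACGT")
        assert len(s.ltr_intervals) >= 1
    # byte-identical regeneration
    assert ref1.minigenome == ref2.minigenome
    assert [s.sequence for s in ref1.subtelomeres] == \
        [s.sequence for s in ref2.subtelomeres]
    assert ref1.annotation["genes"].intervals == ref2.annotation["genes"].intervals


def test_zero_gene_density_gives_empty_track():
    cfg = SimConfig(seed=5, feature_density={"genes": 0.0})
    ref = build_reference(cfg)
    assert ref.annotation["genes"].intervals == []


def test_annotation_within_bounds(std_ref):
    sizes = std_ref.chrom_sizes
    for track in std_ref.annotation.values():
        for chrom, s, e in track.intervals:
            assert 0 <= s < e <= sizes[chrom]
        assert 0.0 <= (track.genome_fraction or 0.0) <= 1.0


def test_simulate_fusions_basics(std_cfg):
    ref = build_reference(std_cfg)
    assert simulate_fusions(ref, std_cfg, 0) == []
    with pytest.raises(ValueError):
        simulate_fusions(ref, std_cfg, -1)
    cfg = SimConfig(seed=9, class_mix=(1.0, 0.0, 0.0), error_rate=0.0)
    ref = build_reference(cfg)
    fus = simulate_fusions(ref, cfg, 50)
    assert len(fus) == 50
    assert all(f.category == "genomic" for f in fus)


def test_truth_mh_mean_matches_geometric_law():
    """Empirical truth MH mean within 3 SE of the programmed geometric mean."""
    mu = 2.0
    cfg = SimConfig(seed=17, mh_mean=mu, ins_prob=0.0, error_rate=0.0,
                    class_mix=(1.0, 0.0, 0.0))
    ref = build_reference(cfg)
    fus = simulate_fusions(ref, cfg, 10_000)
    mh = np.array([f.mh_bp for f in fus], dtype=float)
    se = np.sqrt(mu * (1 + mu) / len(mh))
    assert abs(mh.mean() - mu) < 3 * se


def test_rendered_junction_recovers_truth_by_enumeration(std_cfg):
    """Brute-force split enumeration on rendered amplicons returns truth MH/INS."""
    ref = build_reference(std_cfg)
    fus = simulate_fusions(ref, std_cfg, 120)
    by_end = ref.by_end
    for f in fus:
        amp = render_amplicon(f, ref)
        sub = by_end[f.end_id]
        key, pos, strand = f.partner
        seq = by_end[key].sequence if key in by_end else ref.minigenome[key]
        oriented = seq if strand == "+" else revcomp(seq)
        b0 = pos if strand == "+" else len(seq) - pos
        res = enumerate_split_placements(amp, sub.sequence, sub.primer_offset,
                                         oriented, b0 + f.partner_len)
        assert res["mh_bp"] == f.mh_bp, f.id
        assert res["ins_seq"] == f.ins_seq, f.id
        if not f.ins_seq:
            assert res["leftmost"] == f.breakpoint - sub.primer_offset, f.id


def test_render_amplicon_exact_concatenation(std_cfg):
    ref = build_reference(std_cfg)
    fus = simulate_fusions(ref, std_cfg, 30)
    for f in fus:
        amp = render_amplicon(f, ref)
        sub = ref.by_end[f.end_id]
        a_part = sub.sequence[sub.primer_offset : f.breakpoint]
        assert amp.startswith(a_part)
        if f.mh_bp == 0 and not f.ins_seq:
            assert len(amp) == len(a_part) + f.partner_len
    bad = fus[0]
    bad.breakpoint = ref.by_end[bad.end_id].telomere_boundary + 5
    with pytest.raises(ValueError):
        render_amplicon(bad, ref)


def test_templated_insertion_occurs_near_junction(std_cfg):
    ref = build_reference(std_cfg)
    fus = simulate_fusions(ref, std_cfg, 300)
    checked = 0
    for f in fus:
        if not f.ins_seq or not f.ins_templated:
            continue
        sub = ref.by_end[f.end_id]
        key, pos, strand = f.partner
        seq = ref.by_end[key].sequence if key in ref.by_end else ref.minigenome[key]
        oriented = seq if strand == "+" else revcomp(seq)
        b0 = pos if strand == "+" else len(seq) - pos
        w = std_cfg.ins_window + len(f.ins_seq)
        region_a = sub.sequence[max(0, f.breakpoint - w) : f.breakpoint + w]
        region_b = oriented[max(0, b0 - w) : b0 + w]
        probes = (f.ins_seq, revcomp(f.ins_seq))
        assert any(p in region_a or p in region_b for p in probes)
        checked += 1
    assert checked >= 10


def test_reads_exact_substrings_and_determinism(std_cfg, std_ref):
    ref = build_reference(std_cfg)
    fus = simulate_fusions(ref, std_cfg, 10)
    amps = [(f.id, render_amplicon(f, ref)) for f in fus]
    r1, _ = generate_reads(amps, std_cfg, rng=substream(3, 2))
    r2, _ = generate_reads(amps, std_cfg, rng=substream(3, 2))
    assert r1.ids == r2.ids and r1.r1 == r2.r1 and r1.r2 == r2.r2
    seqs = {aid: s for aid, s in amps}
    for rid, a, b in list(zip(r1.ids, r1.r1, r1.r2))[:200]:
        amp = seqs[rid.split("|")[0]]
        assert a in amp
        assert revcomp(b) in amp


def test_read_count_tracks_coverage_expectation():
    """Total sequenced bases ~ coverage * L * (2*read_len/frag_mean)."""
    cfg = SimConfig(seed=21, coverage=30.0, error_rate=0.0)
    amp = ("a0", "ACGT" * 500)  # 2 kb
    reads, skipped = generate_reads([amp], cfg, rng=substream(8, 2))
    total = sum(len(s) for s in reads.r1) + sum(len(s) for s in reads.r2)
    expect = 30.0 * 2000 * (2 * cfg.read_len / cfg.frag_mean)
    assert skipped == 0
    assert abs(total - expect) / expect < 0.15


def test_short_amplicons_skipped_with_count(std_cfg):
    reads, skipped = generate_reads([("tiny", "ACGT" * 10)], std_cfg)
    assert skipped == 1 and len(reads) == 0


def test_simulants_counts_and_uniformity(std_cfg, std_ref):
    with pytest.raises(ValueError):
        generate_simulants(std_ref, 0, std_cfg)
    truth, reads = generate_simulants(std_ref, 1000, std_cfg, with_reads=False)
    assert len(truth) == 1000 and reads is None
    assert all(t.mh_bp == 0 and not t.ins_seq for t in truth)
    truth, _ = generate_simulants(std_ref, 10_000, std_cfg, with_reads=False)
    lo, hi = std_cfg.primer_offset + 1, std_cfg.telomere_boundary
    bp = np.array([t.breakpoint for t in truth], dtype=float)
    ks = sps.kstest((bp - lo) / (hi - lo), "uniform")
    assert ks.statistic < 0.02
    assert ks.pvalue > 0.01
    gp = np.array([t.partner[1] for t in truth
                   if t.category == "genomic" and t.partner[0] == "chr1"])
    ks2 = sps.kstest(gp / std_ref.chrom_sizes["chr1"], "uniform")
    assert ks2.pvalue > 0.01


def test_read_id_truth_closure(std_cfg):
    """Every read id maps back to exactly one truth record."""
    ref = build_reference(std_cfg)
    fus = simulate_fusions(ref, std_cfg, 20)
    amps = [(f.id, render_amplicon(f, ref)) for f in fus]
    reads, _ = generate_reads(amps, std_cfg)
    ids = {f.id for f in fus}
    assert all(rid.split("|")[0] in ids for rid in reads.ids)


def test_nuclei_bins_shapes_and_null_mean(std_ref):
    prof = simulate_nuclei_bins(std_ref, [], n_nuclei=23, depth=500,
                                n_bins=1000, rng=substream(4, 4))
    assert prof.counts.shape[0] == 23
    prof.normalize()
    r = prof.ratios.to_numpy()
    finite = np.isfinite(r)
    assert abs(r[finite].mean()) < 0.02
    with pytest.raises(ValueError):
        simulate_nuclei_bins(std_ref, [], depth=0)


def test_nuclei_gain_region_mean_ratio(std_ref):
    from telocrisis.cnacall import CnaSegment
    from telocrisis.refsim import make_bins
    bins = make_bins(std_ref, 1000)
    w = int(bins.iloc[0].end - bins.iloc[0].start)
    seg = CnaSegment("n00", "chr1", 50 * w, 60 * w, 0.32, "gain")
    prof = simulate_nuclei_bins(std_ref, [seg], n_nuclei=2, depth=500,
                                n_bins=1000, rng=substream(6, 4)).normalize()
    idx = bins.index[(bins.chrom == "chr1")
                     & (bins.start >= seg.start) & (bins.end <= seg.end)]
    mean = prof.ratios.loc["n00"].to_numpy()[idx].mean()
    assert abs(mean - np.log2(1.25)) < 0.06


def test_simulate_counts_validation(expr_ref):
    with pytest.raises(ValueError):
        simulate_counts(expr_ref, {}, reps=0)
    with pytest.raises(ValueError, match="unknown gene"):
        simulate_counts(expr_ref, {"nope": 2.0}, reps=2)
    with pytest.raises(ValueError, match="positive"):
        g = expr_ref.annotation["genes"].names[0]
        simulate_counts(expr_ref, {g: -1.0}, reps=2)


def test_null_counts_fold_within_sampling_band(std_ref):
    """All folds 1 -> per-gene Early->Late fold inside [0.8, 1.25] at mean 100."""
    mat = simulate_counts(std_ref, {}, reps=3, seed=77,
                          base_sigma=0.0).normalize()
    ma = mat.normalized[mat.stage_samples("Early")].mean(axis=1)
    mb = mat.normalized[mat.stage_samples("Late")].mean(axis=1)
    ratio = (mb + 1) / (ma + 1)
    assert (ratio.between(0.8, 1.25)).all()
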