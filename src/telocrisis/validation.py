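"""Validation experiments quantifying pipeline performance on known truth.

Each function runs a self-contained synthetic experiment - generation,
processing by the production code paths, and measurement against the
recorded truth or an independent brute-force oracle - and returns a dict of
summary numbers.  The test suite asserts on these numbers; the acceptance
script reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._seq import substream
from .cnacall import CnaSegment, call_nuclei
from .enrich import (
    chrom_enrichment,
    feature_coincidence,
    fisher_exact_2x2,
    ltr_depletion,
)
from .exprlink import fused_expression_link, size_factors, stage_fold_changes
from .fusioncall import call_fusions, resolve_junction, split_align
from .reference import enumerate_split_placements, fisher_exact_oracle
from .refsim import (
    SimConfig,
    build_reference,
    generate_reads,
    generate_simulants,
    render_amplicon,
    simulate_counts,
    simulate_fusions,
    simulate_nuclei_bins,
)


def _expr_config(seed: int) -> SimConfig:
    return SimConfig(seed=seed, chrom_lengths=(500_000,) * 4,
                     gene_length_mean=2000.0,
                     feature_density={"genes": 0.6, "promoters": 0.02,
                                      "enhancers": 0.02,
                                      "fragile_sites": 0.3, "ltr": 0.03})


# ---------------------------------------------------------------------------
# junction resolution vs enumeration oracle
# ---------------------------------------------------------------------------

def mh_oracle_agreement(seed: int, n: int = 1000) -> dict:
    """Resolve n random synthetic junctions and compare MH with brute force.

    Junction-spanning windows are cut from rendered amplicons, split-aligned,
    resolved with the production resolver, and checked base-for-base against
    full split-placement enumeration anchored at the same alignment frames.
    """
    from .fusioncall import ReferenceIndex

    cfg = SimConfig(seed=seed, error_rate=0.0)
    ref = build_reference(cfg)
    truth = simulate_fusions(ref, cfg, n)
    index = ReferenceIndex(ref.subtelomeres, ref.minigenome)
    reads = []
    for t in truth:
        amp = render_amplicon(t, ref)
        sub = ref.by_end[t.end_id]
        a_len = t.breakpoint - sub.primer_offset
        lo = max(0, a_len - 150)
        hi = min(len(amp), a_len + len(t.ins_seq) + 150)
        reads.append((t.id, amp[lo:hi]))
    sas = split_align(reads, index)
    agree = 0
    compared = 0
    for sa in sas:
        (bp_a, bp_b), mh, ins = resolve_junction(sa, index)
        a_seq = index.targets[sa.a_target].seq
        b_seq = index.targets[sa.b_target].seq
        oracle = enumerate_split_placements(
            sa.seq, a_seq, sa.a_ref_start, b_seq, sa.b_ref_start + sa.b_len)
        compared += 1
        if oracle["mh_bp"] == mh and oracle["ins_seq"] == ins:
            agree += 1
    return {"n": compared, "agreement_pct": 100.0 * agree / max(compared, 1)}


# ---------------------------------------------------------------------------
# end-to-end recovery
# ---------------------------------------------------------------------------

def end_to_end_recovery(seed: int, n: int = 2000) -> dict:
    """Simulate -> sequence -> call -> match against truth.

    Class mix 0.4/0.4/0.2, MH mean 2, insertion probability 0.3, error-free
    reads at coverage 10.  An event counts as recovered when a base-
    resolution call reproduces its end, category and both breakpoints at the
    leftmost placement; MH/INS metrics and templated/untemplated flags
    (insertions >= 6 bp) are compared exactly on recovered events.
    """
    cfg = SimConfig(seed=seed, error_rate=0.0)
    ref = build_reference(cfg)
    truth = simulate_fusions(ref, cfg, n)
    amps = [(t.id, render_amplicon(t, ref)) for t in truth]
    reads, _ = generate_reads(amps, cfg)
    calls = call_fusions(reads, ref)
    idx = {}
    for c in calls:
        if c.resolution == "base":
            idx.setdefault((c.end_id, c.subtel_breakpoint,
                            c.partner[0], c.partner[1]), c)
    rec = cat = mh = ins = 0
    fl_ok = fl_n = 0
    for t in truth:
        c = idx.get((t.end_id, t.breakpoint, t.partner[0], t.partner[1]))
        if c is None:
            continue
        rec += 1
        cat += c.category == t.category
        mh += c.mh_bp == t.mh_bp
        ins += c.ins_seq == t.ins_seq
        if t.ins_seq and len(t.ins_seq) >= 6:
            fl_n += 1
            want = "templated" if t.ins_templated else "untemplated"
            fl_ok += c.ins_templated == want
    return {
        "n": n,
        "recovery_pct": 100.0 * rec / n,
        "category_accuracy_pct": 100.0 * cat / max(rec, 1),
        "mh_exact_pct": 100.0 * mh / max(rec, 1),
        "ins_exact_pct": 100.0 * ins / max(rec, 1),
        "templated_flag_accuracy_pct": 100.0 * fl_ok / max(fl_n, 1),
        "n_flagged_insertions": fl_n,
    }


# ---------------------------------------------------------------------------
# deletion asymmetry
# ---------------------------------------------------------------------------

def asymmetry_recovery(seed: int, n: int = 1000,
                       early_range=(0, 4000), late_range=(0, 8000)) -> dict:
    """Recovered Early->Late mean delta-deletion ratio vs the programmed one.

    Intra-chromosomal cohorts with widened deletion ranges; |d1 - d2| of two
    independent Uniform(0, w) deletions has mean w/3, so the programmed
    ratio is the ratio of range widths.
    """
    means = {}
    for label, dr, sub_seed in (("early", early_range, seed),
                                ("late", late_range, seed + 1)):
        cfg = SimConfig(seed=sub_seed, error_rate=0.0,
                        class_mix=(0.0, 1.0, 0.0), deletion_range=dr)
        ref = build_reference(cfg)
        truth = simulate_fusions(ref, cfg, n)
        amps = [(t.id, render_amplicon(t, ref)) for t in truth]
        reads, _ = generate_reads(amps, cfg)
        calls = call_fusions(reads, ref)
        deltas = [c.delta_deletion_bp for c in calls
                  if c.category == "intra" and c.delta_deletion_bp is not None]
        means[label] = float(np.mean(deltas))
    programmed = (late_range[1] - late_range[0]) / (early_range[1] - early_range[0])
    ratio = means["late"] / means["early"]
    return {"n": n, "mean_delta_early_bp": means["early"],
            "mean_delta_late_bp": means["late"], "recovered_ratio": ratio,
            "programmed_ratio": programmed,
            "ratio_error_pct": 100.0 * abs(ratio - programmed) / programmed}


# ---------------------------------------------------------------------------
# simulant null calibration
# ---------------------------------------------------------------------------

def null_calibration(seed: int, n_simulants: int = 10_000, n_obs: int = 500,
                     reps: int = 200) -> dict:
    """False-positive rates of the enrichment tests under the simulant null.

    Each replicate draws an observed set from the same uniform law as the
    fixed simulant set and tests gene-track coincidence and subtelomeric LTR
    depletion at alpha = 0.05.  Also checks that chromosome-level expected
    counts sum exactly to the observed total.
    """
    cfg = SimConfig(seed=seed, error_rate=0.0)
    ref = build_reference(cfg)
    simulants, _ = generate_simulants(ref, n_simulants, cfg, with_reads=False)
    sim_gen = [(t.partner[0], t.partner[1]) for t in simulants
               if t.category == "genomic"]
    sim_sub = [(t.end_id, t.breakpoint) for t in simulants]
    genes = ref.annotation["genes"]
    ltr = ref.subtel_ltr_track()
    fp_feat = fp_ltr = 0
    for r in range(reps):
        obs, _ = generate_simulants(ref, n_obs, cfg, with_reads=False,
                                    rng=substream(seed + 1, 1000 + r))
        obs_gen = [(t.partner[0], t.partner[1]) for t in obs
                   if t.category == "genomic"]
        obs_sub = [(t.end_id, t.breakpoint) for t in obs]
        if feature_coincidence(obs_gen, genes, sim_gen).p_value < 0.05:
            fp_feat += 1
        if ltr_depletion(obs_sub, sim_sub, ltr).p_value < 0.05:
            fp_ltr += 1
    ce = chrom_enrichment(sim_gen, ref.chrom_sizes)
    return {"reps": reps, "n_simulants": n_simulants,
            "feature_fpr_pct": 100.0 * fp_feat / reps,
            "ltr_fpr_pct": 100.0 * fp_ltr / reps,
            "chrom_expected_sum_abs_error":
                abs(sum(r_.expected for r_ in ce) - len(sim_gen))}


# ---------------------------------------------------------------------------
# Fisher exactness
# ---------------------------------------------------------------------------

def fisher_exactness(max_margin: int = 30) -> dict:
    """Sweep all 2x2 tables with margins <= max_margin against enumeration."""
    max_err = 0.0
    n = 0
    for r1 in range(max_margin + 1):
        for c1 in range(max_margin + 1):
            for total in range(max(r1, c1),
                               min(2 * max_margin, r1 + max_margin,
                                   c1 + max_margin) + 1):
                r2, c2 = total - r1, total - c1
                if not (0 <= r2 <= max_margin and 0 <= c2 <= max_margin):
                    continue
                for a in range(max(0, c1 - r2), min(r1, c1) + 1):
                    table = [[a, r1 - a], [c1 - a, r2 - (c1 - a)]]
                    if min(table[0][1], table[1][0], table[1][1]) < 0:
                        continue
                    p = fisher_exact_2x2(table)
                    err = abs(p - float(fisher_exact_oracle(table)))
                    if err > max_err:
                        max_err = err
                    n += 1
    return {"tables": n, "max_abs_error": max_err,
            "example_3113_p": fisher_exact_2x2([[3, 1], [1, 3]])}


# ---------------------------------------------------------------------------
# CNA specificity / sensitivity
# ---------------------------------------------------------------------------

def cna_performance(seed: int, spec_runs: int = 10, sens_runs: int = 3,
                    n_nuclei: int = 23, n_bins: int = 2000,
                    depth: float = 500.0) -> dict:
    """Neutral-genome specificity and injected-CNA sensitivity.

    Specificity: total false segments across 23 neutral 4N nuclei per run.
    Sensitivity: per nucleus one 12-bin gain (ratio 5/4) and one 12-bin loss
    (ratio 3/4); a nucleus counts as recovered when both segments are called
    with the correct sign and both boundaries within one bin.
    """
    cfg = SimConfig(seed=seed)
    ref = build_reference(cfg)
    from .refsim import make_bins
    bins = make_bins(ref, n_bins)
    width = int(bins.iloc[0]["end"] - bins.iloc[0]["start"])
    false_per_run = []
    for r in range(spec_runs):
        prof = simulate_nuclei_bins(ref, [], n_nuclei=n_nuclei, depth=depth,
                                    n_bins=n_bins, rng=substream(seed, 2000 + r))
        false_per_run.append(len(call_nuclei(prof)))
    runs_ok = sum(f <= 2 for f in false_per_run)

    nuclei = [f"n{i:02d}" for i in range(n_nuclei)]
    truth = []
    for i, nm in enumerate(nuclei):
        gs = (100 + 3 * i) * width
        ls = (300 + 3 * i) * width
        truth.append(CnaSegment(nm, "chr2", gs, gs + 12 * width, 0.32, "gain"))
        truth.append(CnaSegment(nm, "chr3", ls, ls + 12 * width, -0.41, "loss"))
    ok = total = 0
    for r in range(sens_runs):
        prof = simulate_nuclei_bins(ref, truth, n_nuclei=n_nuclei, depth=depth,
                                    n_bins=n_bins, rng=substream(seed, 3000 + r))
        segs = call_nuclei(prof)
        by_n: dict[str, list[CnaSegment]] = {}
        for s in segs:
            by_n.setdefault(s.nucleus, []).append(s)
        for nm in nuclei:
            total += 1
            got = by_n.get(nm, [])
            want = [t for t in truth if t.nucleus == nm]
            good = len(got) == len(want) and all(
                any(s.chrom == w.chrom and s.call == w.call
                    and abs(s.start - w.start) <= width
                    and abs(s.end - w.end) <= width for s in got)
                for w in want)
            ok += good
    return {"spec_runs": spec_runs,
            "false_segments_per_run": false_per_run,
            "spec_runs_within_budget_pct": 100.0 * runs_ok / spec_runs,
            "sens_nuclei": total,
            "sensitivity_pct": 100.0 * ok / total}


# ---------------------------------------------------------------------------
# normalization closed form
# ---------------------------------------------------------------------------

def size_factor_closed_form() -> dict:
    """Proportional two-sample matrix: factors must be (1/sqrt2, sqrt2)."""
    a = pd.Series([11.0, 25.0, 40.0, 90.0, 130.0])
    counts = pd.DataFrame({"s1": a, "s2": 2.0 * a})
    fs, norm = size_factors(counts)
    err = max(abs(fs["s1"] - 1 / np.sqrt(2)), abs(fs["s2"] - np.sqrt(2)))
    norm_gap = float((norm["s1"] - norm["s2"]).abs().max())
    return {"factor_abs_error": float(err), "normalized_gap": norm_gap}


# ---------------------------------------------------------------------------
# expression linkage
# ---------------------------------------------------------------------------

def expression_linkage(seed: int, n_fused: int = 200,
                       programmed_fold: float = 2.0) -> dict:
    """Programmed 2x fused-gene expression and an 8.6x top-ranked gene."""
    cfg = _expr_config(seed)
    ref = build_reference(cfg)
    track = ref.annotation["genes"]
    genes = list(track.names)
    rng = substream(seed, 4000)
    fused = [genes[i] for i in rng.choice(len(genes), size=n_fused,
                                          replace=False)]
    mat = simulate_counts(ref, {g: programmed_fold for g in fused},
                          reps=3, rng=substream(seed, 4001))
    pos = {n: iv for iv, n in zip(track.intervals, track.names)}
    calls = [(pos[g][0], (pos[g][1] + pos[g][2]) // 2) for g in fused]
    link = fused_expression_link(calls, mat, "Deep")

    marked = genes[int(rng.integers(len(genes)))]
    mat2 = simulate_counts(ref, {marked: {"Late": 8.6}}, reps=3,
                           rng=substream(seed, 4002))
    _, top = stage_fold_changes(mat2, "Early", "Late")
    return {"n_fused": n_fused, "fused_fold": link["fold"],
            "programmed_fold": programmed_fold,
            "frac_expressed": link["frac_expressed"],
            "top_gene_is_programmed": int(top[0] == marked)}
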