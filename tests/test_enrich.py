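"""Enrichment statistics: Fisher, chi2 expectations, feature coincidence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from telocrisis._seq import substream
from telocrisis.enrich import (
    FeatureTrack,
    chrom_enrichment,
    compare_means,
    feature_coincidence,
    fisher_exact_2x2,
    fused_gene_stats,
    ltr_depletion,
)
from telocrisis.reference import fisher_exact_oracle


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def test_fisher_conventions_and_doc_example():
    assert fisher_exact_2x2([[0, 0], [0, 0]]) == 1.0
    assert fisher_exact_2x2([[5, 0], [7, 0]]) == 1.0
    assert fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(34 / 70)


@given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25),
       st.integers(0, 25))
@settings(max_examples=200, deadline=None)
def test_fisher_matches_scipy_and_symmetries(a, b, c, d):
    t = [[a, b], [c, d]]
    p = fisher_exact_2x2(t)
    assert p == pytest.approx(sps.fisher_exact(t)[1], rel=1e-9, abs=1e-12)
    assert p == pytest.approx(fisher_exact_2x2([[c, d], [a, b]]))
    assert p == pytest.approx(fisher_exact_2x2([[a, c], [b, d]]))
    assert p == pytest.approx(fisher_exact_2x2([[b, a], [d, c]]))


def test_fisher_exact_oracle_is_rational():
    from fractions import Fraction
    assert fisher_exact_oracle([[3, 1], [1, 3]]) == Fraction(34, 70)


# ---------------------------------------------------------------------------
# compare_means
# ---------------------------------------------------------------------------

def test_compare_means_examples():
    z, p = compare_means(5, 1, 10, 5, 1, 10)
    assert z == 0 and p == pytest.approx(1.0)
    z, p = compare_means(10, 2, 100, 9, 2, 100)
    assert z == pytest.approx(3.5355, abs=1e-4)
    assert p == pytest.approx(4.07e-4, rel=0.01)
    z2, p2 = compare_means(9, 2, 100, 10, 2, 100)
    assert z2 == pytest.approx(-z) and p2 == pytest.approx(p)
    with pytest.raises(ValueError):
        compare_means(1, 1, 1, 2, 1, 10)


# ---------------------------------------------------------------------------
# chrom_enrichment
# ---------------------------------------------------------------------------

def _pts(items):
    return [(c, p) for c, p in items]


def test_chrom_enrichment_degenerate_and_arithmetic():
    res = chrom_enrichment(_pts([("chr1", 5)] * 8), {"chr1": 1000})
    assert len(res) == 1 and res[0].p_value == 1.0
    assert res[0].expected == res[0].observed == 8
    res = chrom_enrichment(_pts([("chr1", 1)] * 2 + [("chr2", 1)] * 6),
                           {"chr1": 1000, "chr2": 3000})
    by = {r.unit: r for r in res}
    assert by["chr1"].expected == pytest.approx(2.0)
    assert by["chr2"].expected == pytest.approx(6.0)
    with pytest.raises(ValueError):
        chrom_enrichment(_pts([("chr1", 1)]), {"chr1": 0})


def test_chrom_enrichment_against_chi2_oracle():
    pts = _pts([("chr1", 1)] * 6 + [("chr2", 1)] * 2)
    res = {r.unit: r for r in chrom_enrichment(pts, {"chr1": 1000, "chr2": 3000})}
    stat, p = sps.chisquare([6, 2], [2, 6])
    assert res["chr1"].statistic == pytest.approx(stat)
    assert res["chr1"].p_value == pytest.approx(p)


def test_chrom_expected_sums_to_observed_total():
    rng = substream(3, 50)
    sizes = {f"chr{i}": int(rng.integers(10_000, 99_000)) for i in range(1, 7)}
    pts = [(f"chr{int(rng.integers(1, 7))}", 1) for _ in range(313)]
    res = chrom_enrichment(pts, sizes)
    assert sum(r.expected for r in res) == pytest.approx(313, abs=1e-9)


# ---------------------------------------------------------------------------
# feature_coincidence
# ---------------------------------------------------------------------------

def test_feature_coincidence_full_cover_and_oracle():
    track = FeatureTrack("all", [("chr1", 0, 1000)])
    res = feature_coincidence(_pts([("chr1", i) for i in range(10)]), track, 0.5)
    assert res.observed == 10  # whole-genome track contains every point
    track2 = FeatureTrack("half", [("chr1", 0, 500)])
    pts = _pts([("chr1", 10)] * 9 + [("chr1", 900)])
    res = feature_coincidence(pts, track2, 0.5)
    # expected-cell rule: min expected < 5 -> Fisher on [[9,1],[5,5]]
    assert res.test == "fisher"
    assert res.p_value == pytest.approx(fisher_exact_2x2([[9, 1], [5, 5]]))
    with pytest.raises(ValueError):
        feature_coincidence([], track2, 0.5)


def test_feature_coincidence_null_case():
    track = FeatureTrack("half", [("chr1", 0, 500)])
    pts = _pts([("chr1", 10)] * 50 + [("chr1", 900)] * 50)
    res = feature_coincidence(pts, track, 0.5)
    assert res.fold == pytest.approx(1.0)
    assert res.p_value >= 0.99


def test_feature_coincidence_null_calibration_small():
    """Uniform observed vs uniform simulants: ~5% false positives."""
    rng = substream(9, 51)
    track = FeatureTrack("t", [("chr1", 0, 30_000)])
    sim = [("chr1", int(p)) for p in rng.integers(0, 100_000, size=5000)]
    fp = 0
    for _ in range(100):
        obs = [("chr1", int(p)) for p in rng.integers(0, 100_000, size=400)]
        if feature_coincidence(obs, track, sim).p_value < 0.05:
            fp += 1
    assert fp <= 10


# ---------------------------------------------------------------------------
# fused_gene_stats
# ---------------------------------------------------------------------------

def _gene_track(rng, n=200):
    iv, names = [], []
    pos = 0
    for i in range(n):
        ln = int(rng.lognormal(np.log(10_000), 0.8))
        iv.append(("chr1", pos, pos + ln))
        names.append(f"g{i}")
        pos += ln + 500
    return FeatureTrack("genes", iv, names=names), pos


def test_fused_gene_stats_single_gene():
    track = FeatureTrack("genes", [("chr1", 0, 10_000)], names=["g0"])
    res = fused_gene_stats(_pts([("chr1", 5)]), track)
    assert res["genes"] == ["g0"]
    assert res["mean"] == 10_000 and res["sd"] == 0.0


def test_fused_gene_stats_null_z_calibration():
    """Uniformly drawn fused sets: |z| < 3 in >= 95% of replicates."""
    rng = substream(11, 52)
    track, _ = _gene_track(rng)
    lengths = {n: e - s for (c, s, e), n in zip(track.intervals, track.names)}
    ok = 0
    for _ in range(100):
        chosen = rng.choice(track.names, size=40, replace=False)
        pts = []
        for g in chosen:
            i = track.names.index(g)
            c, s, e = track.intervals[i]
            pts.append((c, int(rng.integers(s, e))))
        res = fused_gene_stats(pts, track)
        if abs(res.get("z_vs_genome", 0.0)) < 3:
            ok += 1
    assert ok >= 95


def test_fused_gene_stats_directional_bias():
    rng = substream(13, 53)
    track, _ = _gene_track(rng)
    lens = np.array([e - s for _, s, e in track.intervals])
    med = np.median(lens)
    pts = [(c, (s + e) // 2) for (c, s, e) in track.intervals if e - s > med]
    res = fused_gene_stats(pts, track)
    assert res["z_vs_genome"] > 0


# ---------------------------------------------------------------------------
# ltr_depletion
# ---------------------------------------------------------------------------

def test_ltr_depletion_directions():
    track = FeatureTrack("ltr", [("17p", 4000, 5000)])
    rng = substream(15, 54)
    sim = [("17p", int(p)) for p in rng.integers(0, 10_000, size=4000)]
    res = ltr_depletion(sim[:2000], sim[2000:], track)
    assert res.fold == pytest.approx(1.0, abs=0.25)
    obs = [("17p", int(p)) for p in rng.integers(5500, 10_000, size=1000)]
    res = ltr_depletion(obs, sim, track)
    assert res.direction == "depleted" and res.p_value < 1e-6
    # contingency table reproduced by the exact oracle when cells are small
    obs_small = [("17p", 4500)] + [("17p", 9000)] * 9
    sim_small = [("17p", 4500)] * 5 + [("17p", 9000)] * 5
    res = ltr_depletion(obs_small, sim_small, track)
    assert res.p_value == pytest.approx(fisher_exact_2x2([[1, 9], [5, 5]]))
    with pytest.raises(ValueError):
        ltr_depletion(obs, sim, FeatureTrack("empty", []))
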