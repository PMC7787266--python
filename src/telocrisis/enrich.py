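"""Enrichment of fusion junctions over chromosomes and annotation features.

Junctions are treated as points (the leftmost breakpoint); membership in a
feature is point containment.  Observed junction sets are compared either
with a predicted frequency (genome fraction, chromosome-length expectation)
or with a simulant null set resolved by the identical methodology.

Chi-squared statistics are used when every expected cell is >= 5, otherwise
Fisher's exact test; no continuity correction is applied (configurable).
Per-unit tests are reported without multiplicity correction by default; a
Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureTrack:
    """A named set of genomic intervals (0-based half-open)."""

    name: str
    intervals: list[tuple[str, int, int]]
    names: list[str] | None = None          # per-interval ids (e.g. gene ids)
    strands: list[str] | None = None
    genome_fraction: float | None = None

    def __post_init__(self) -> None:
        order = sorted(range(len(self.intervals)),
                       key=lambda i: self.intervals[i])
        self.intervals = [self.intervals[i] for i in order]
        if self.names is not None:
            self.names = [self.names[i] for i in order]
        if self.strands is not None:
            self.strands = [self.strands[i] for i in order]
        for chrom, start, end in self.intervals:
            if start >= end or start < 0:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        for chrom, s, e in _merge(self.intervals):
            starts.setdefault(chrom, []).append(s)
            ends.setdefault(chrom, []).append(e)
        for chrom in starts:
            self._by_chrom[chrom] = (np.asarray(starts[chrom]),
                                     np.asarray(ends[chrom]))

    def compute_fraction(self, chrom_sizes: dict[str, int]) -> float:
        total = sum(chrom_sizes.values())
        covered = 0
        for chrom, s, e in _merge(self.intervals):
            if chrom not in chrom_sizes:
                raise ValueError(f"interval on unknown chromosome {chrom}")
            if e > chrom_sizes[chrom]:
                raise ValueError(f"interval {chrom}:{s}-{e} beyond chromosome end")
            covered += e - s
        self.genome_fraction = covered / total
        return self.genome_fraction

    def contains(self, chrom: str, pos: int) -> bool:
        if chrom not in self._by_chrom:
            return False
        starts, ends = self._by_chrom[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]

    def count_inside(self, points: list[tuple[str, int]]) -> int:
        return sum(self.contains(c, p) for c, p in points)


def _merge(intervals):
    merged: list[list] = []
    for chrom, s, e in sorted(intervals):
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([chrom, s, e])
    return [tuple(m) for m in merged]


@dataclass
class EnrichmentResult:
    unit: str
    observed: float
    expected: float
    statistic: float | None
    p_value: float
    fold: float
    direction: str | None = None
    test: str = "chi2"

    def __post_init__(self) -> None:
        if self.observed < 0 or self.expected < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# basic tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of non-negative integers.

    p is the total hypergeometric probability (margins fixed) of all tables
    at most as probable as the observed one; probability comparisons are done
    in exact integer arithmetic.  A zero margin gives p = 1 by convention.
    """
    (a, b), (c, d) = table
    a, b, c, d = int(a), int(b), int(c), int(d)
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # unnormalized weights C(r1,k)*C(r2,c1-k); exact integers
    w_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    tail = 0
    for k in range(lo, hi + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        total += w
        if w <= w_obs:
            tail += w
    return tail / total


def compare_means(m1: float, sd1: float, n1: int,
                  m2: float, sd2: float, n2: int) -> tuple[float, float]:
    """Normal-approximation comparison of two means from summary statistics.

    z = (m1 - m2) / sqrt(sd1^2/n1 + sd2^2/n2); two-sided p from N(0, 1).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    se = math.sqrt(sd1 ** 2 / n1 + sd2 ** 2 / n2)
    if se == 0:
        return 0.0, 1.0
    z = (m1 - m2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return z, p


def _two_by_two(table: np.ndarray, use_chi2_when_ok: bool = True
                ) -> tuple[float | None, float, str]:
    """(statistic, p, test name) for a 2x2 count table, chi2-or-Fisher rule."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    if n == 0 or (row == 0).any() or (col == 0).any():
        return None, 1.0, "fisher"
    expected = np.outer(row, col) / n
    if use_chi2_when_ok and (expected >= 5).all():
        stat = float(((table - expected) ** 2 / expected).sum())
        return stat, float(sps.chi2.sf(stat, df=1)), "chi2"
    p = fisher_exact_2x2(np.rint(table).astype(int))
    return None, p, "fisher"


# ---------------------------------------------------------------------------
# enrichment analyses
# ---------------------------------------------------------------------------

def _genomic_points(calls) -> list[tuple[str, int]]:
    pts = []
    for c in calls:
        if isinstance(c, tuple):
            pts.append((c[0], int(c[1])))
        elif c.category == "genomic":
            pts.append((c.partner[0], c.partner[1]))
    return pts


def chrom_enrichment(calls, chrom_sizes: dict[str, int],
                     bh_adjust: bool = False) -> list[EnrichmentResult]:
    """Observed vs length-predicted fusion counts per chromosome.

    The predicted count is the mean overall fusion frequency (events/bp)
    multiplied by the chromosome size; each chromosome is tested with a
    two-cell goodness-of-fit statistic (on vs off the chromosome).
    """
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"zero-length chromosome {chrom}")
    pts = _genomic_points(calls)
    if not pts:
        raise ValueError("need at least one genomic call")
    total = len(pts)
    total_len = sum(chrom_sizes.values())
    counts = {chrom: 0 for chrom in chrom_sizes}
    for chrom, _ in pts:
        if chrom not in counts:
            raise ValueError(f"call on chromosome {chrom} absent from sizes")
        counts[chrom] += 1
    out = []
    for chrom in chrom_sizes:
        expected = total * chrom_sizes[chrom] / total_len
        obs = counts[chrom]
        if expected == total:  # single-chromosome degenerate case
            out.append(EnrichmentResult(chrom, obs, expected, 0.0, 1.0, 1.0))
            continue
        f_obs = [obs, total - obs]
        f_exp = [expected, total - expected]
        stat, p = sps.chisquare(f_obs, f_exp)
        fold = obs / expected if expected > 0 else math.inf
        out.append(EnrichmentResult(chrom, obs, expected, float(stat),
                                    float(p), fold))
    if bh_adjust:
        adj = sps.false_discovery_control([r.p_value for r in out])
        for r, q in zip(out, adj):
            r.p_value = float(q)
    return out


def feature_coincidence(calls, track: FeatureTrack,
                        control) -> EnrichmentResult:
    """Junction coincidence with a feature track vs a control proportion.

    `control` is either a genome fraction (float) or a simulant call/point
    set resolved with the identical methodology.  Builds a 2x2 in/out table
    and applies the chi2-or-Fisher rule.
    """
    if not track.intervals:
        raise ValueError("empty feature track")
    pts = _genomic_points(calls)
    if not pts:
        raise ValueError("empty call set")
    n = len(pts)
    inside = track.count_inside(pts)
    prop = inside / n
    if isinstance(control, (int, float)):
        f = float(control)
        if not (0 <= f <= 1):
            raise ValueError("control genome fraction outside [0,1]")
        table = np.array([[inside, n - inside], [n * f, n * (1 - f)]])
        ctrl_prop = f
        expected = n * f
    else:
        cpts = _genomic_points(control)
        cin = track.count_inside(cpts)
        table = np.array([[inside, n - inside], [cin, len(cpts) - cin]])
        ctrl_prop = cin / len(cpts)
        expected = n * ctrl_prop
    stat, p, test = _two_by_two(table)
    fold = prop / ctrl_prop if ctrl_prop > 0 else math.inf
    direction = "enriched" if prop >= ctrl_prop else "depleted"
    return EnrichmentResult(track.name, inside, expected, stat, p, fold,
                            direction=direction, test=test)


def fused_gene_stats(calls, gene_track: FeatureTrack,
                     simulant_calls=None) -> dict:
    """Unique genes overlapped by junctions and their length statistics.

    Returns the fused gene list, mean/SD length, and comparison-of-means
    z-tests against all annotated genes and (optionally) against genes
    captured by the simulant set.
    """
    if gene_track.names is None:
        raise ValueError("gene track must carry gene ids")
    lengths = {}
    for (chrom, s, e), name in zip(gene_track.intervals, gene_track.names):
        lengths[name] = e - s
    all_lengths = np.array(list(lengths.values()), dtype=float)

    def _fused_genes(call_set) -> list[str]:
        pts = _genomic_points(call_set)
        by_chrom: dict[str, list[int]] = {}
        for chrom, p in pts:
            by_chrom.setdefault(chrom, []).append(p)
        for chrom in by_chrom:
            by_chrom[chrom].sort()
        hit = []
        for (chrom, s, e), name in zip(gene_track.intervals, gene_track.names):
            ps = by_chrom.get(chrom)
            if ps and bisect_right(ps, e - 1) > bisect_right(ps, s - 1):
                hit.append(name)
        return sorted(set(hit))

    fused = _fused_genes(calls)
    if not fused:
        logger.warning("no fused genes found")
        return {"genes": [], "mean": float("nan"), "sd": float("nan")}
    flens = np.array([lengths[g] for g in fused], dtype=float)
    res = {
        "genes": fused,
        "mean": float(flens.mean()),
        "sd": float(flens.std(ddof=1)) if len(flens) > 1 else 0.0,
        "n": len(fused),
        "genome_mean": float(all_lengths.mean()),
        "genome_sd": float(all_lengths.std(ddof=1)) if len(all_lengths) > 1 else 0.0,
    }
    if len(flens) >= 2:
        z, p = compare_means(res["mean"], res["sd"], res["n"],
                             res["genome_mean"], res["genome_sd"],
                             len(all_lengths))
        res["z_vs_genome"], res["p_vs_genome"] = z, p
    if simulant_calls is not None:
        sim = _fused_genes(simulant_calls)
        if len(sim) >= 2 and len(flens) >= 2:
            slens = np.array([lengths[g] for g in sim], dtype=float)
            z, p = compare_means(res["mean"], res["sd"], res["n"],
                                 float(slens.mean()),
                                 float(slens.std(ddof=1)), len(slens))
            res["simulant_mean"] = float(slens.mean())
            res["z_vs_simulant"], res["p_vs_simulant"] = z, p
    return res


def ltr_depletion(calls, simulants, ltr_track: FeatureTrack,
                  scope: str = "subtelomere") -> EnrichmentResult:
    """In-LTR junction proportions, observed vs simulant, within a scope.

    scope="subtelomere" uses subtelomeric breakpoints against the end's LTR
    intervals (track chrom = end id); scope="genome" uses genomic partner
    coordinates against a genomic LTR track.
    """
    if not ltr_track.intervals:
        raise ValueError("LTR track empty in scope")
    if scope not in ("subtelomere", "genome"):
        raise ValueError(f"unknown scope {scope!r}")

    def _points(call_set):
        if scope == "genome":
            return _genomic_points(call_set)
        pts = []
        for c in call_set:
            if isinstance(c, tuple):
                pts.append((c[0], int(c[1])))
            else:
                pts.append((c.end_id, c.subtel_breakpoint))
        return pts

    opts, spts = _points(calls), _points(simulants)
    if not opts or not spts:
        raise ValueError("both call sets must be non-empty")
    o_in = ltr_track.count_inside(opts)
    s_in = ltr_track.count_inside(spts)
    table = np.array([[o_in, len(opts) - o_in], [s_in, len(spts) - s_in]])
    stat, p, test = _two_by_two(table)
    p_obs = o_in / len(opts)
    p_sim = s_in / len(spts)
    fold = p_obs / p_sim if p_sim > 0 else math.inf
    direction = "depleted" if p_obs < p_sim else "enriched"
    return EnrichmentResult(f"LTR[{scope}]", o_in, len(opts) * p_sim, stat, p,
                            fold, direction=direction, test=test)
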