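"""Single-nucleus copy-number calling from binned read counts.

Each 4N nucleus is normalized to a pooled-nuclei bulk baseline from the same
sample; per-bin log2 ratios are smoothed with a rolling median, thresholded,
and merged into gain/loss segments.  Thresholds of +/-0.25 are motivated by
single-copy changes on a 4N background: log2(5/4) = +0.32 for a gain and
log2(3/4) = -0.415 for a loss.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrich import fisher_exact_2x2

logger = logging.getLogger(__name__)


@dataclass
class CnaSegment:
    nucleus: str
    chrom: str
    start: int            # bp, 0-based half-open (bin indices when no grid)
    end: int
    mean_log2_ratio: float
    call: str             # "gain" | "loss"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must be < end")
        if self.call not in ("gain", "loss", "neutral"):
            raise ValueError(f"unknown call {self.call!r}")


@dataclass
class BinProfile:
    """Equal bin grids with per-nucleus counts, bulk counts and log2 ratios."""

    bins: pd.DataFrame                 # columns chrom, start, end
    counts: pd.DataFrame               # nuclei x bins
    bulk: pd.Series
    ratios: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        nbins = len(self.bins)
        if self.counts.shape[1] != nbins or len(self.bulk) != nbins:
            raise ValueError("bin grids differ between nuclei and bulk")

    def normalize(self) -> "BinProfile":
        rows = {n: normalize_bins(self.counts.loc[n].to_numpy(),
                                  self.bulk.to_numpy())
                for n in self.counts.index}
        self.ratios = pd.DataFrame.from_dict(rows, orient="index",
                                             columns=self.counts.columns)
        return self


def normalize_bins(nucleus_counts, bulk_counts) -> np.ndarray:
    """Depth-normalized per-bin log2 ratio of a nucleus against the bulk pool.

    r_i = log2((c_i / C) / (b_i / B)); bins with zero bulk coverage are
    masked (NaN) and their count is logged.
    """
    c = np.asarray(nucleus_counts, dtype=float)
    b = np.asarray(bulk_counts, dtype=float)
    if c.shape != b.shape:
        raise ValueError("nucleus and bulk vectors differ in length")
    if c.sum() <= 0:
        raise ValueError("all-zero nucleus")
    if b.sum() <= 0:
        raise ValueError("all-zero bulk")
    mask = b == 0
    if mask.any():
        logger.info("normalize_bins: %d bins masked (bulk == 0)", int(mask.sum()))
    with np.errstate(divide="ignore"):
        r = np.log2((c / c.sum())) - np.log2(b / b.sum())
    r[mask] = np.nan
    r[(~mask) & (c == 0)] = -np.inf
    return r


def segment_and_call(ratios, window: int = 5, gain_thr: float = 0.25,
                     loss_thr: float = -0.25, min_len: int = 5,
                     merge_gap: int = 2, nucleus: str = "n0",
                     chrom: str = "chr", bin_size: int | None = None,
                     bin_start: int = 0, refine: bool = True) -> list[CnaSegment]:
    """Rolling-median smoothing + thresholding + run merging on one vector.

    Runs of same-sign threshold exceedances separated by at most `merge_gap`
    bins are merged; runs shorter than `min_len` bins are dropped.  Segment
    edges are refined against the raw (unsmoothed) ratios.  Coordinates are
    bin indices unless `bin_size` is given.
    """
    r = np.asarray(ratios, dtype=float)
    if window > r.size:
        raise ValueError("window longer than profile")
    smooth = (pd.Series(r).rolling(window, center=True, min_periods=1)
              .median().to_numpy())
    state = np.zeros(r.size, dtype=int)
    state[smooth >= gain_thr] = 1
    state[smooth <= loss_thr] = -1
    state[np.isnan(smooth)] = 0

    runs = []  # (sign, start, end)
    i = 0
    while i < r.size:
        s = state[i]
        if s == 0:
            i += 1
            continue
        j = i
        while j < r.size and state[j] == s:
            j += 1
        runs.append([s, i, j])
        i = j
    merged = []
    for run in runs:
        if (merged and merged[-1][0] == run[0]
                and run[1] - merged[-1][2] <= merge_gap):
            merged[-1][2] = run[2]
        else:
            merged.append(run)

    refined = []
    for sign, lo, hi in merged:
        if refine:
            lo, hi = _refine_edges(r, lo, hi, sign, gain_thr, loss_thr)
        refined.append([sign, lo, hi])
    # refinement can make neighbouring same-sign runs touch; re-merge
    refined.sort(key=lambda x: x[1])
    final = []
    for run in refined:
        if final and final[-1][0] == run[0] and run[1] <= final[-1][2]:
            final[-1][2] = max(final[-1][2], run[2])
        else:
            final.append(run)

    out = []
    for sign, lo, hi in final:
        if hi - lo < min_len:                 # min_len=inf drops everything
            continue
        vals = r[lo:hi]
        mean = float(np.nanmean(vals[np.isfinite(vals)])) if np.isfinite(vals).any() else 0.0
        if bin_size is not None:
            start, end = bin_start + lo * bin_size, bin_start + hi * bin_size
        else:
            start, end = lo, hi
        out.append(CnaSegment(nucleus, chrom, start, end, mean,
                              "gain" if sign > 0 else "loss"))
    return out


def _refine_edges(r, lo, hi, sign, gain_thr, loss_thr, edge_factor=0.5):
    """Walk run edges outward against a softer raw-value threshold.

    Detection requires the full threshold on the smoothed core; edges are
    then extended while the raw ratios stay beyond `edge_factor` x threshold
    (two-bin lookahead tolerates an isolated low bin at a segment edge).
    """
    e_gain = gain_thr * edge_factor
    e_loss = loss_thr * edge_factor

    def beyond(i, soft=True):
        if i < 0 or i >= r.size or not np.isfinite(r[i]):
            return False
        if sign > 0:
            return r[i] >= (e_gain if soft else gain_thr)
        return r[i] <= (e_loss if soft else loss_thr)

    # trim inward first in case smoothing bled past the true edge
    while lo < hi and not beyond(lo):
        lo += 1
    while hi > lo and not beyond(hi - 1):
        hi -= 1
    # extend by one bin at the soft threshold; skip an isolated low bin
    # only when the landing bin clears the full threshold
    while lo > 0:
        if beyond(lo - 1):
            lo -= 1
        elif lo > 1 and beyond(lo - 2, soft=False):
            lo -= 2
        else:
            break
    n = r.size
    while hi < n:
        if beyond(hi):
            hi += 1
        elif hi < n - 1 and beyond(hi + 1, soft=False):
            hi += 2
        else:
            break
    return lo, hi


def call_nuclei(profile: BinProfile, **kwargs) -> list[CnaSegment]:
    """Segment every nucleus of a normalized profile, per chromosome."""
    if profile.ratios is None:
        profile.normalize()
    segs: list[CnaSegment] = []
    bins = profile.bins
    for nucleus in profile.ratios.index:
        row = profile.ratios.loc[nucleus].to_numpy()
        for chrom, idx in bins.groupby("chrom", sort=False).groups.items():
            idx = np.asarray(idx)
            sub = row[idx]
            starts = bins.loc[idx, "start"].to_numpy()
            bs = int(bins.loc[idx[0], "end"] - bins.loc[idx[0], "start"])
            segs.extend(segment_and_call(
                sub, nucleus=str(nucleus), chrom=str(chrom), bin_size=bs,
                bin_start=int(starts[0]), **kwargs))
    return segs


def intersect_cna_fusions(segments: list[CnaSegment], calls,
                          control_calls) -> dict:
    """Coincidence of fusion junction points with gain/loss segments.

    Counts junctions inside CNA segments for the observed and control
    (simulant) sets, tests the 2x2 with Fisher's exact test, and tallies
    overlaps by gain/loss.
    """
    from .enrich import _genomic_points

    pts = _genomic_points(calls)
    cpts = _genomic_points(control_calls)
    if not segments:
        return {"overlap": 0, "p_value": 1.0, "gains": 0, "losses": 0,
                "control_overlap": 0, "table": ((0, len(pts)), (0, len(cpts)))}

    by_chrom: dict[str, list[CnaSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda s: s.start)

    def _hits(points):
        gains = losses = 0
        hit = 0
        for chrom, p in points:
            for s in by_chrom.get(chrom, ()):  # few segments per chrom
                if s.start <= p < s.end:
                    hit += 1
                    if s.call == "gain":
                        gains += 1
                    else:
                        losses += 1
                    break
        return hit, gains, losses

    o_hit, o_gain, o_loss = _hits(pts)
    c_hit, _, _ = _hits(cpts)
    table = ((o_hit, len(pts) - o_hit), (c_hit, len(cpts) - c_hit))
    p = fisher_exact_2x2(table)
    return {"overlap": o_hit, "p_value": p, "gains": o_gain, "losses": o_loss,
            "control_overlap": c_hit, "table": table}


def per_chrom_intersections(results: dict[str, int],
                            chrom_sizes: dict[str, int],
                            per_chrom_fusion_counts: dict[str, int]
                            ) -> pd.DataFrame:
    """Per-chromosome intersection rates: raw, per-Mb and fusion-adjusted.

    `results` maps chromosome -> significant intersection count.  The mean
    over chromosomes of each normalization is appended as row "mean".
    """
    if not results:
        raise ValueError("no intersection results")
    rows = []
    for chrom, raw in results.items():
        if chrom not in chrom_sizes:
            raise ValueError(f"chromosome {chrom} absent from sizes")
        mb = chrom_sizes[chrom] / 1e6
        fus = per_chrom_fusion_counts.get(chrom, 0)
        rows.append({
            "chrom": chrom,
            "raw": raw,
            "per_mb": raw / mb,
            "fusion_adjusted": raw / fus if fus else math.nan,
        })
    df = pd.DataFrame(rows).set_index("chrom")
    df.loc["mean"] = df.mean()
    return df
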