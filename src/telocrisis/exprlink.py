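"""Link fused loci to expression in stage-labelled count matrices.

Raw gene x sample counts are normalized with median-of-ratios size factors
(the DESeq-style estimator), genes are classified as expressed / not /
ambiguous per crisis stage, fused genes are compared against unaffected
genes at the matched stage, and Early->Late fold changes yield top-k
regulated gene lists whose overlap across cell lines is summarized.

Full dispersion-modelled differential testing is deliberately out of scope;
fold-change ranking on normalized counts is the declared stand-in.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrich import compare_means

logger = logging.getLogger(__name__)

STAGES = ("Early", "Deep", "Late")


@dataclass
class ExpressionMatrix:
    """Gene x sample raw counts with stage labels and genomic intervals."""

    counts: pd.DataFrame                  # genes x samples, non-negative ints
    samples: pd.DataFrame                 # index sample id; columns line, stage
    gene_intervals: pd.DataFrame | None = None   # index gene; chrom,start,end
    size_factors: pd.Series | None = None
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without labels: {sorted(missing)}")
        if self.samples.loc[list(self.counts.columns), "stage"].isna().any():
            raise ValueError("every sample needs a stage label")

    def normalize(self) -> "ExpressionMatrix":
        self.size_factors, self.normalized = size_factors(self.counts)
        return self

    def stage_samples(self, stage: str) -> list[str]:
        sel = self.samples.index[self.samples["stage"] == stage]
        cols = [s for s in self.counts.columns if s in set(sel)]
        if not cols:
            raise ValueError(f"stage {stage!r} absent from sample sheet")
        return cols


def size_factors(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    The reference is the per-gene geometric mean across samples, computed
    over genes with no zero count; each sample's factor is the median of its
    count/reference ratios over those genes.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene with nonzero counts in every sample")
    log_ref = np.log(mat[allpos]).mean(axis=1)
    factors = np.exp(np.median(np.log(mat[allpos]) - log_ref[:, None], axis=0))
    fs = pd.Series(factors, index=counts.columns, name="size_factor")
    normalized = counts / fs
    return fs, normalized


def expression_status(gene: str, stage: str, normalized: pd.DataFrame,
                      samples: pd.DataFrame, t_lo: float = 1.0,
                      t_hi: float = 5.0) -> str:
    """Three-way expression status of one gene at one crisis stage.

    Mean normalized count over the stage's samples: >= t_hi -> "expressed",
    < t_lo -> "not_expressed", otherwise "ambiguous".
    """
    if gene not in normalized.index:
        raise KeyError(f"gene {gene!r} absent from matrix")
    cols = samples.index[samples["stage"] == stage]
    cols = [c for c in normalized.columns if c in set(cols)]
    if not cols:
        raise ValueError(f"stage {stage!r} has no samples")
    mean = float(normalized.loc[gene, cols].mean())
    if mean >= t_hi:
        return "expressed"
    if mean < t_lo:
        return "not_expressed"
    return "ambiguous"


def genes_hit_by_calls(calls, gene_intervals: pd.DataFrame) -> list[str]:
    """Genes whose interval contains a genomic fusion junction point."""
    pts: dict[str, list[int]] = {}
    for c in calls:
        if isinstance(c, tuple):
            chrom, pos = c[0], int(c[1])
        elif c.category == "genomic":
            chrom, pos = c.partner[0], c.partner[1]
        else:
            continue
        pts.setdefault(chrom, []).append(pos)
    for chrom in pts:
        pts[chrom].sort()
    hit = []
    for gene, row in gene_intervals.iterrows():
        ps = pts.get(row["chrom"])
        if ps and bisect_right(ps, int(row["end"]) - 1) > bisect_right(ps, int(row["start"]) - 1):
            hit.append(gene)
    return sorted(set(hit))


def fused_expression_link(calls, matrix: ExpressionMatrix, stage: str,
                          t_lo: float = 1.0, t_hi: float = 5.0,
                          include_fused_in_reference: bool = False) -> dict:
    """Stage-matched linkage of fused genes to their expression.

    Fusions sampled at crisis stage `stage` are intersected with the gene
    intervals of the matrix; returns the fraction of fused genes expressed at
    that stage, the fold of the mean normalized count of fused genes over the
    unaffected-gene mean, and a comparison-of-means p-value.
    """
    if matrix.gene_intervals is None:
        raise ValueError("matrix lacks gene intervals")
    if matrix.normalized is None:
        matrix.normalize()
    stage_calls = [c for c in calls
                   if isinstance(c, tuple) or c.stage == stage]
    fused = [g for g in genes_hit_by_calls(stage_calls, matrix.gene_intervals)
             if g in matrix.normalized.index]
    if not fused:
        raise ValueError("no fused gene mappable to the expression matrix")
    cols = matrix.stage_samples(stage)
    means = matrix.normalized[cols].mean(axis=1)
    fused_means = means.loc[fused]
    if include_fused_in_reference:
        ref_means = means
    else:
        ref_means = means.drop(index=fused)
    statuses = [expression_status(g, stage, matrix.normalized, matrix.samples,
                                  t_lo, t_hi) for g in fused]
    frac_expressed = sum(s == "expressed" for s in statuses) / len(fused)
    fold = float(fused_means.mean() / ref_means.mean())
    z = p = float("nan")
    if len(fused_means) >= 2 and len(ref_means) >= 2:
        z, p = compare_means(float(fused_means.mean()),
                             float(fused_means.std(ddof=1)), len(fused_means),
                             float(ref_means.mean()),
                             float(ref_means.std(ddof=1)), len(ref_means))
    return {"stage": stage, "n_fused_genes": len(fused),
            "fused_genes": fused, "frac_expressed": frac_expressed,
            "fold": fold, "z": z, "p_value": p,
            "status_counts": pd.Series(statuses).value_counts().to_dict()}


def stage_fold_changes(matrix: ExpressionMatrix, stage_a: str = "Early",
                       stage_b: str = "Late", pseudocount: float = 1.0,
                       min_mean: float = 10.0, top_k: int = 50,
                       ranking: str = "abs_log2fc"
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene log2 fold changes between two stages and the top-k list.

    FC = (mean_B + pseudocount) / (mean_A + pseudocount) on normalized
    counts; genes below `min_mean` in both stages are excluded; ranking is by
    |log2 FC| (or variance across all samples with ranking="variance").
    """
    if matrix.normalized is None:
        matrix.normalize()
    ca = matrix.stage_samples(stage_a)
    cb = matrix.stage_samples(stage_b)
    ma = matrix.normalized[ca].mean(axis=1)
    mb = matrix.normalized[cb].mean(axis=1)
    keep = (ma >= min_mean) | (mb >= min_mean)
    ma, mb = ma[keep], mb[keep]
    log2fc = np.log2((mb + pseudocount) / (ma + pseudocount))
    df = pd.DataFrame({f"mean_{stage_a}": ma, f"mean_{stage_b}": mb,
                       "log2_fc": log2fc})
    if ranking == "variance":
        df["rank_score"] = matrix.normalized.loc[keep[keep].index].var(axis=1)
    else:
        df["rank_score"] = log2fc.abs()
    df = df.sort_values("rank_score", ascending=False, kind="mergesort")
    if top_k > len(df):
        logger.warning("top_k=%d exceeds %d surviving genes; returning all",
                       top_k, len(df))
        top_k = len(df)
    return df, list(df.index[:top_k])


def overlap_across_lines(top_lists: dict[str, list[str]] | list[list[str]]
                         ) -> dict:
    """Partition of top-gene lists by how many lines share each gene.

    Returns counts of genes shared by exactly 1..k lists plus the full k-way
    intersection set; partition counts sum to the union size.
    """
    if isinstance(top_lists, dict):
        lists = list(top_lists.values())
    else:
        lists = list(top_lists)
    if len(lists) < 2:
        raise ValueError("need at least two gene lists")
    if any(not lst for lst in lists):
        raise ValueError("empty gene list")
    sets = [set(lst) for lst in lists]
    union = set().union(*sets)
    membership = {g: sum(g in s for s in sets) for g in union}
    counts = {k: sum(1 for v in membership.values() if v == k)
              for k in range(1, len(sets) + 1)}
    full = sorted(set.intersection(*sets))
    return {"shared_by": counts, "intersection": full, "union_size": len(union)}
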