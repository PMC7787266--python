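"""End-to-end pipeline driver: simulate -> call -> enrich -> cna -> expr.

The driver only orchestrates module operations and records their outputs;
every numeric in the machine-readable summary comes from a module call.  All
artifacts are reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import cnacall, enrich, exprlink, io, refsim
from .fusioncall import call_fusions
from .cnacall import CnaSegment

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed", "outdir", "stages", "sim", "n_fusions", "n_simulants",
    "caller", "cna", "expr", "log_level",
}
_DEFAULT_STAGES = ("simulate", "call", "enrich", "cna", "expr")


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "telocrisis_out"
    stages: tuple[str, ...] = _DEFAULT_STAGES
    sim: dict = dataclasses.field(default_factory=dict)
    n_fusions: int = 100
    n_simulants: int = 200
    caller: dict = dataclasses.field(default_factory=dict)
    cna: dict = dataclasses.field(default_factory=dict)
    expr: dict = dataclasses.field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.stages = tuple(cfg.stages)
        bad = set(cfg.stages) - set(_DEFAULT_STAGES)
        if bad:
            raise ValueError(f"unknown pipeline stages: {sorted(bad)}")
        return cfg

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def demo_config(outdir: str = "telocrisis_out", seed: int = 0) -> PipelineConfig:
    """Small end-to-end configuration that completes in well under a minute."""
    return PipelineConfig(seed=seed, outdir=outdir, n_fusions=100,
                          n_simulants=200)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the machine-readable summary."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level, logging.INFO))
    with open(out / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2, default=list)

    sim_cfg = refsim.SimConfig(seed=cfg.seed, **cfg.sim).validate()
    summary: dict = {"seed": cfg.seed}
    ref = truth = calls = sim_truth = sim_calls = None

    if "simulate" in cfg.stages:
        ref = refsim.build_reference(sim_cfg)
        truth = refsim.simulate_fusions(ref, sim_cfg, cfg.n_fusions)
        amps = [(t.id, refsim.render_amplicon(t, ref)) for t in truth]
        reads, _ = refsim.generate_reads(amps, sim_cfg)
        logger.info("simulate: %d fusions -> %d amplicons -> %d read pairs",
                    len(truth), len(amps), len(reads))
        io.write_fasta(ref.minigenome, out / "genome.fa")
        io.write_fasta({s.end_id: s.sequence for s in ref.subtelomeres},
                       out / "subtel.fa")
        io.write_subtel_meta(ref.subtelomeres, out / "subtel.tsv")
        for name, track in ref.annotation.items():
            io.write_annotation_bed(track, out / f"{name}.bed")
        io.write_fastq_pair(reads, out / "reads")
        io.write_truth(truth, out / "truth.tsv")
        summary["simulate"] = {"n_fusions": len(truth),
                               "n_read_pairs": len(reads)}

        sim_truth, sim_reads = refsim.generate_simulants(
            ref, cfg.n_simulants, sim_cfg)
        io.write_truth(sim_truth, out / "simulant_truth.tsv")

        if "call" in cfg.stages:
            stats: dict = {}
            calls = call_fusions(reads, ref, sample="demo", stage="Deep",
                                 stats=stats, **cfg.caller)
            io.write_calls(calls, out / "calls.tsv", "TSV")
            io.write_calls(calls, out / "calls.bed", "BED")
            summary["call"] = {"events": len(calls),
                               "reads_processed": stats.get("aligned", 0),
                               "split_reads": stats.get("split", 0),
                               "ambiguous_excluded": stats.get("ambiguous", 0)}
            sim_stats: dict = {}
            sim_calls = call_fusions(sim_reads, ref, sample="simulant",
                                     stage="Deep", stats=sim_stats,
                                     **cfg.caller)
            io.write_calls(sim_calls, out / "simulant_calls.tsv", "TSV")
            summary["call"]["simulant_events"] = len(sim_calls)

    if "enrich" in cfg.stages:
        if calls is None:
            raise FileNotFoundError("enrich stage requires calls "
                                    "(run simulate+call or provide calls.tsv)")
        chrom = enrich.chrom_enrichment(calls, ref.chrom_sizes)
        genes = ref.annotation["genes"]
        gene_co = enrich.feature_coincidence(calls, genes,
                                             genes.genome_fraction)
        ltr = enrich.ltr_depletion(calls, sim_calls, ref.subtel_ltr_track(),
                                   scope="subtelomere")
        gstats = enrich.fused_gene_stats(calls, genes,
                                         simulant_calls=sim_calls)
        summary["enrich"] = {
            "chrom_expected_sum": sum(r.expected for r in chrom),
            "chrom_observed_total": sum(r.observed for r in chrom),
            "gene_coincidence_fold": gene_co.fold,
            "gene_coincidence_p": gene_co.p_value,
            "subtel_ltr_direction": ltr.direction,
            "subtel_ltr_fold": ltr.fold,
            "fused_gene_mean_kb": round(gstats["mean"] / 1000, 2)
            if gstats["genes"] else None,
        }
        import pandas as pd
        pd.DataFrame([dataclasses.asdict(r) for r in chrom]).to_csv(
            out / "chrom_enrichment.tsv", sep="\t", index=False)

    if "cna" in cfg.stages:
        if ref is None:
            raise FileNotFoundError("cna stage requires the simulate stage")
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(40,)))
        bins = refsim.make_bins(ref, cfg.cna.get("n_bins", 960))
        width = int(bins.iloc[0]["end"] - bins.iloc[0]["start"])
        truth_segs = []
        for ni in (3, 11):
            chrom = bins.iloc[0]["chrom"]
            start = 40 * width
            truth_segs.append(CnaSegment(f"n{ni:02d}", chrom, start,
                                         start + 20 * width, 0.32,
                                         "gain" if ni == 3 else "loss"))
        profile = refsim.simulate_nuclei_bins(
            ref, truth_segs, n_nuclei=cfg.cna.get("n_nuclei", 23),
            depth=cfg.cna.get("depth", 500), n_bins=cfg.cna.get("n_bins", 960),
            rng=rng)
        segs = cnacall.call_nuclei(profile)
        io.write_bin_counts(profile, out / "cna")
        inter = cnacall.intersect_cna_fusions(segs, calls or [], sim_calls or [])
        summary["cna"] = {"segments": len(segs),
                          "fusion_overlap": inter["overlap"],
                          "fisher_p": inter["p_value"],
                          "gains": sum(s.call == "gain" for s in segs),
                          "losses": sum(s.call == "loss" for s in segs)}

    if "expr" in cfg.stages:
        if ref is None or calls is None:
            raise FileNotFoundError("expr stage requires simulate+call")
        fused_genes = exprlink.genes_hit_by_calls(
            calls, _gene_intervals(ref))
        effects = {g: {"Deep": 2.0} for g in fused_genes}
        matrix = refsim.simulate_counts(ref, effects,
                                        reps=cfg.expr.get("reps", 3),
                                        seed=cfg.seed)
        io.write_counts_matrix(matrix, out / "expr")
        link = exprlink.fused_expression_link(calls, matrix, "Deep")
        fc, top = exprlink.stage_fold_changes(matrix, "Early", "Late")
        summary["expr"] = {"n_fused_genes": link["n_fused_genes"],
                           "frac_expressed": link["frac_expressed"],
                           "fused_fold": link["fold"],
                           "top_gene": top[0] if top else None}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary


def _gene_intervals(ref):
    import pandas as pd
    track = ref.annotation["genes"]
    return pd.DataFrame(
        [{"gene": n, "chrom": c, "start": s, "end": e}
         for (c, s, e), n in zip(track.intervals, track.names)]
    ).set_index("gene")
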