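# telocrisis

Analysis of telomere-fusion amplicon sequencing through a telomere-driven
crisis: split-read fusion calling with junction microhomology, insertion and
deletion metrics; a simulated-fusion ("simulant") null model; genomic
enrichment statistics; single-nucleus copy-number calling; and linkage of
fused loci to gene expression.  A first-class synthetic-data module
generates all three data layers with recorded ground truth, so every step of
the pipeline is testable against known answers.

## Who this is for

Cells that bypass replicative senescence enter *crisis*: eroded,
deprotected telomeres are recognized as double-strand breaks and fuse — to
their sister chromatid (intra-chromosomal), to another chromosome end
(inter-chromosomal), or to internal genomic loci (genomic fusions) —
driving breakage–fusion–bridge instability.  Fusion PCR with subtelomere
primers (chr17p, chrXpYp, the chr21q family) followed by paired-end
sequencing reads out these events at base resolution.  This package is for
researchers who need to turn such amplicon reads into classified junction
calls and to ask the downstream questions: which repair pathway signatures
(microhomology vs insertions) do junctions carry, how asymmetric is
sister-chromatid processing, which chromosomes and features are enriched in
fusions relative to a methodology-matched null, do fusions coincide with
single-nucleus copy-number alterations, and are fused genes transcribed?

## The model in brief

For a junction-spanning sequence *s* joining references *A* and *B*, a
split placement at position *p* is valid when `s[:p]` matches *A* and
`s[p:]` matches *B* exactly.  The microhomology is

    MH = max(valid p) − min(valid p),

the breakpoint is reported at the leftmost valid placement, and when no
perfect placement exists, the maximal middle segment matching neither flank
is the insertion (INS), classified *templated* if it occurs within ±100 bp
of either breakpoint.  Subtelomeric deletion of a fused end is
`telomere_boundary − breakpoint`, and sister-chromatid asymmetry is
`Δ = |d₁ − d₂|`.  Enrichment uses per-chromosome χ² against length-
proportional expectations, 2×2 χ²-or-Fisher tests against genome fractions
or simulant nulls, and comparison-of-means z-tests.  Single-nucleus
(4N) bin counts are normalized to a pooled bulk, `r_i =
log₂((c_i/C)/(b_i/B))`, smoothed with a rolling median and thresholded at
±0.25 (log₂(5/4) = +0.32 for a one-copy gain on 4N).  Expression matrices
are normalized by median-of-ratios size factors and fused genes are
compared with unaffected genes at the matched crisis stage.  Details and
parameter rationale: [docs/methods.md](docs/methods.md).

## Worked example

Run the bundled end-to-end demo (simulate → call → enrich → CNA →
expression) on a 480 kb minigenome with 100 programmed fusions:

```bash
telocrisis run --out demo --seed 11
```

This prints the machine-readable summary (also written to
`demo/summary.json`):

```json
{
  "seed": 11,
  "simulate": { "n_fusions": 100, "n_read_pairs": 15495 },
  "call": { "events": 106, "reads_processed": 18964, "split_reads": 915,
            "ambiguous_excluded": 0, "simulant_events": 244 },
  "enrich": { "chrom_expected_sum": 35.0, "chrom_observed_total": 35,
              "gene_coincidence_fold": 1.291, "gene_coincidence_p": 0.430,
              "subtel_ltr_direction": "depleted", "subtel_ltr_fold": 0.256,
              "fused_gene_mean_kb": 9.9 },
  "cna": { "segments": 2, "fusion_overlap": 1, "fisher_p": 1.0,
           "gains": 1, "losses": 1 },
  "expr": { "n_fused_genes": 11, "frac_expressed": 1.0,
            "fused_fold": 1.348, "top_gene": "g0011" }
}
```

Reading it: 100 simulated fusions produced 15,495 read pairs; the caller
resolved 915 junction-spanning fragments into 106 unique events (a handful
of single-support homology artifacts ride along with the 100 true events).
The 35 genomic junctions match their length-proportional chromosome
expectation exactly by construction of the test (`chrom_expected_sum`),
gene coincidence is mildly elevated but not significant at this scale, and
subtelomeric LTR intervals are depleted of biological junctions relative to
the 244 simulant events (fold 0.26) — the programmed avoidance signal.  The
CNA stage recovers the two injected segments (one gain, one loss) in 23
simulated nuclei, and all 11 fused genes are expressed at the Deep-crisis
stage with a 1.35× mean expression fold over unaffected genes.

The demo also writes `calls.tsv` (one row per unique event with breakpoints,
category, MH bp, INS sequence and templating, per-end deletions and Δ),
`calls.bed` (width-1 junction points for karyotype display), the reference
FASTA/BED files, FASTQ read pairs, and truth tables.

The same steps are available as library calls (`telocrisis.simulate_fusions`,
`telocrisis.call_fusions`, `telocrisis.chrom_enrichment`, ...) and as the
subcommands `simulate`, `call`, `enrich`, `cna`, `expr`.

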