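# Methods

`telocrisis` models and analyses the three data layers of a telomere-driven
crisis experiment in human fibroblasts: fusion amplicon sequencing
(Fusion-seq), single-nucleus whole-genome bin counts, and stage-labelled
RNA-seq count matrices.  This note records the models, the parameter
choices, the numerical decisions, and what the synthetic experiments do and
do not establish about real data.

## The fusion assay model

Telomere fusion PCR amplifies junction fragments with unidirectional
primers landing in three subtelomeres: chr17p, chrXpYp, and the chr21q
family of homologous ends.  The package models each end as a
`SubtelomereRef` with a primer position, a telomere-repeat boundary, and
one or more LTR-like repeat intervals.  A fusion joins a subtelomeric
breakpoint (somewhere between the primer and the boundary) to a partner:

* **genomic** — an internal genomic locus on either strand,
* **intra** — the sister chromatid of the same chromosome end
  (head-to-head, so the partner segment reads in reverse complement),
* **inter** — a different chromosome end.

The subtelomeric deletion of a fused end is `telomere_boundary -
breakpoint`; for an intra event the asymmetry of processing of the two
sister chromatids is `Δ = |d1 - d2|`.

### Junction fine structure

A junction carries either **microhomology (MH)** — `k` bases identical in
both partners, so the exact breakpoint is ambiguous over `k + 1` placements
— or an **insertion (INS)** matching neither flank, never both (exact-match
model; a junction with an unexplained insertion has no perfect placement to
be ambiguous about).  An insertion is **templated** when it (or its reverse
complement — strand-agnostic synthesis is assumed, configurable) occurs
within ±100 bp of either breakpoint in its reference, otherwise
**untemplated**.

The simulator draws MH lengths from a geometric law on {0, 1, 2, ...} with
configurable mean (default 2 bp), insertions with probability 0.3 and
length 1–12 bp.  MH is *injected* by overwriting the `k` junction-proximal
bases of the partner reference with the subtelomere-side continuation, so
the shared bases genuinely exist in both references and enumeration
recovers exactly `k`.  Every event's junction-critical bases (the shared
bases plus the single stop base on each side, and any templated-insertion
source) are protected from later edits; partner positions are redrawn on
conflict.  Because protected windows may legitimately overlap each other,
capacity is limited only by edit density; the generator raises a clear
error when the requested event count exceeds what the subtelomere zones can
host.  Templating truth is recomputed against the final (post-edit)
reference so the recorded flag is always a true statement about the
sequences the caller sees.

Insertions whose first bases happen to continue one of the flanks would be
indistinguishable from a flank plus a sequencing error; the generator
rejects such draws (see *Junction resolution* below for the symmetric
caller-side rule).

### Simulants

The null model ("simulants") draws breakpoints uniformly along each
subtelomere between primer and telomere boundary and partner coordinates
uniformly over the genome, with MH 0 and no insertions, and pushes them
through the *identical* amplicon and read generation used for biological
events, so any detection bias applies to both sets.  Biological events, by
contrast, avoid subtelomeric LTR intervals with probability 0.9 (the
programmed depletion signal); simulants never do.

### Amplicons and reads

An amplicon is `subtelomere[primer:breakpoint] + INS + partner segment`.
Partner segments are 500–3000 bp (uniform); how a single-primer genomic
amplicon terminates is not observable in the assay, so this is a declared
simulation convention.  Reads are paired-end 250 bp from Normal(450, 40)
fragments placed uniformly on the amplicon, mate 2 reverse-complemented,
with independent substitution errors (default 0.001/base; recovery
experiments use 0).  `coverage` is the mean per-base fragment depth: an
amplicon of length L yields Poisson(coverage x L / 450) pairs.  At coverage
10 the expected number of junction-covering fragments is ~8 independent of
amplicon length, which is what makes near-complete event recovery possible
at modest depth.

## Fusion calling

Overlapping mates are merged into full fragments (two 12-mer seeds, full
overlap verification, ≤ 2 mismatches); unmergeable mates are aligned
singly.  The built-in split aligner uses exact 21-mer seeds over both
strands of all references, with ungapped mismatch-tolerant extension (≤ 2
substitutions per segment) used *only* to locate and rank the two anchor
segments.  The A segment must sit on the forward strand of a subtelomere
(primer orientation); reads contained in a single reference yield no call;
equal-score partner placements on unrelated references are flagged
unclassifiable and excluded with a logged count.

**Junction resolution** is a statement about perfect matches: from each
read end the resolver chases exact-match runs, stepping over an isolated
substitution only when the following run is at least 10 bases
(`MISMATCH_RUN_GUARD`) — a mid-flank sequencing error — and never at the
junction, where continuation matches only by chance (P ≈ 4^-10 per event).
If the two exact flanks overlap, the overlap width is the MH and the
breakpoints are reported at the leftmost valid placement; if they leave a
gap, the gap is the insertion.  For error-free reads this provably equals
full split-placement enumeration, which the validation suite checks
junction-by-junction against a brute-force oracle.

**Classification.**  Partner in the same end's subtelomere → intra; another
subtelomere → inter; anywhere else → genomic.  Within the 21q family,
intra status is assigned only where the partner matches the archetype and
the archetype locally diverges from every sibling by at least the family
margin (default 2% identity over a ±50 bp window); otherwise the
conservative inter label is used.  Siblings are simulated at 15% divergence
from the archetype, typical of subtelomeric paralog variation and enough to
make 100 bp windows essentially always discriminable.

**Dedupe.**  Calls agreeing in sample, category, end, partner reference/
strand and both breakpoints within 5 bp merge; support sums; metrics come
from the highest-support member.  Mate-pair-only evidence would yield
interval-resolution calls, which are excluded from MH/INS summaries; the
default pipeline emits base-resolution calls only.

**Fusion frequency** per diploid genome is `amplicons / (input_ng x 1000 /
6.6 pg)`.

## Enrichment statistics

Junctions are points (leftmost breakpoints); feature membership is point
containment; nested genes each count, a gene counts once per call set.
Per-chromosome expected counts are the total count times the chromosome's
length share; each chromosome gets a two-cell goodness-of-fit χ² (df 1).
Feature coincidence and LTR depletion build 2x2 tables against either a
genome-fraction expectation or a matched simulant set, use χ² without
continuity correction when all expected cells are ≥ 5, else a Fisher's
exact test.  `fisher_exact_2x2` computes the two-sided p as the summed
hypergeometric probability of all tables (fixed margins) no more probable
than the observed one, with probability comparisons in exact integer
arithmetic; zero margins give p = 1.  Per-unit tests are reported without
multiplicity correction by default (Benjamini–Hochberg optional), mirroring
per-unit χ² reporting practice.  Comparison of means uses the two-sample
z-statistic from summary statistics with normal tails.

## Single-nucleus CNA calling

Each 4N nucleus's bin counts are normalized to a pooled-nuclei bulk from
the same sample: `r_i = log2((c_i/C)/(b_i/B))`, with zero-bulk bins masked.
On a 4N background a single-copy gain is 5/4 (log2 = +0.32) and a
single-copy loss 3/4 (-0.415), motivating call thresholds of ±0.25.
Segmentation is a deterministic rolling median (window 5 bins, centered),
thresholding, merging of same-sign runs separated by ≤ 2 bins, and a
minimum run length of 5 bins.  Segment edges are then refined on the raw
ratios: the edge walks outward while bins stay beyond *half* the call
threshold, skipping an isolated low bin only when the landing bin clears
the full threshold.  Detection still requires the full threshold on the
smoothed core, so neutral-genome specificity is unaffected, while gain
edges (whose per-bin signal at depth 500 sits only ~1.2 SD above the
threshold) are recovered to within one bin.  Default grids are 2000 bins
over the minigenome at mean depth 500 per bin, the scaled-down analogue of
~500 kb bins on a human genome.  GC correction is omitted — the synthetic
data is GC-neutral — and would be required for real WGA data.

Fusion–CNA intersection counts junction points inside gain/loss segments
and tests the 2x2 (observed vs simulant control, in/out) with the same
Fisher routine bit-for-bit.  Per-chromosome intersection rates are reported
raw, per Mb, and divided by the chromosome's fusion count.

## Expression linkage

Size factors are median-of-ratios: the reference is the per-gene geometric
mean over samples (genes with any zero excluded); each sample's factor is
the median count/reference ratio.  On a proportional two-sample matrix
(B = 2A) this gives exactly (1/√2, √2) and identical normalized columns.
Expression status per stage uses mean normalized counts: ≥ 5 expressed,
< 1 not expressed, in between ambiguous (declared thresholds).  Fused genes
at a stage are genes containing a genomic junction from that stage's calls;
their mean normalized expression is compared against *unaffected* genes
(fold, plus a comparison-of-means z-test).  Stage fold changes are
`(mean_B + 1)/(mean_A + 1)` on normalized counts after a min-mean-10
filter, ranked by |log2 FC| (variance ranking optional) for top-k lists;
full dispersion-modelled differential testing is deliberately out of scope.
Top-list overlap across lines partitions the union by how many lists share
each gene.

The count generator is gamma-Poisson with variance μ + αμ²; α defaults to
0.002 (tight technical-replicate-like noise, under which triplicate null
log2 fold changes at mean 100 stay within about ±0.5), per-gene baselines
are log-normal (σ = 0.5 by default, σ = 0 for mean-level contract checks),
and library sizes vary uniformly over [0.5, 2] to exercise normalization.

## Problem sizes and determinism

Validation experiments run at: 2000 fusion events (class mix 0.4/0.4/0.2)
for recovery; 1000 junctions for oracle agreement; intra-only cohorts of
1000 with deletion ranges (0, 4000) vs (0, 8000) (programmed Δ-ratio 2) for
asymmetry; 10,000 simulants and 200 replicates for null calibration; all
2x2 tables with margins ≤ 30 for Fisher exactness; 23 nuclei x 2000 bins at
depth 500 for CNA; 200 fused genes at 2x programmed expression (622-gene
dense reference) for linkage.  The minigenome is 4 x 120 kb with 11 kb
subtelomeres — large enough that breakpoint collisions within the 5 bp
dedupe tolerance are rare at these event counts.  All randomness flows from
one integer seed through named, stable sub-streams; every generator is a
pure function of (config, seed).

## What the synthetic experiments do not show

The generator has uniform base composition, no segmental duplications or
satellite repeats beyond the telomere tail and the 21q family, substitution
errors only (no indels, no quality profile), no PCR chimeras or slippage,
no GC or mappability bias in WGA coverage, and independent genes with no
covariance structure in expression.  Passing the recovery and calibration
experiments therefore demonstrates the correctness of the algorithms under
their stated models, not their robustness to every artifact of real
libraries; on real data the declared options (mismatch budgets, external
SAM split alignments, GC correction, variance ranking) are the knobs that
matter first.

## Known limitations

* The split aligner is ungapped; indel-bearing junct reads resolve only
  via their error-free mates or not at all.
* Junction MH above ~30 bp would exceed the anchor margin used when
  deciding junction-spanning coverage and recovery degrades.
* Family discrimination assumes position-comparable family members
  (substitution-level divergence); structurally divergent paralogs would
  need alignment-based windows.
* The CNA caller targets gross segmental events (≥ 5 bins); focal changes
  below the smoothing window are invisible by design.
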