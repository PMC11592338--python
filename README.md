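# regulohub

Integrative analysis of 3D genome architecture and chromatin accessibility:
from binned Hi-C contact counts and ATAC-seq peaks/cut-counts to significant
and differential chromatin loops, hierarchical TADs, A/B compartments,
clusters of cis-regulatory elements (COREs), CORE–promoter loops, and
differential transcription-factor footprint statistics at loop anchors.

The package targets the kind of two-condition perturbation study done in
primary cell systems — here modeled after a Schwann-cell experiment in which
an antisense RNA ("AS" condition) is overexpressed against a GFP control,
with two biological replicates per condition of Hi-C and ATAC-seq. Because
such datasets are large and access-restricted, `regulohub` ships a
first-class synthetic-genome generator that plants a known architecture
(compartments, nested TADs, condition-specific loops, COREs, motif
footprints) and simulates realistic counts, so the entire pipeline is
testable end-to-end against ground truth.

## The models at the core

**Loop calling.** For cis bin pairs at genomic distance *d* (10 Kb bins,
50 Kb ≤ *d* ≤ 2 Mb), counts are modeled as negative binomial with

  log μ(d) = β₀ + β₁·log d,  Var(Y) = μ + μ²/θ,

fitted per condition on replicate-summed counts (θ by method of moments on
Poisson-GLM residuals, refined by maximum likelihood). A pair is a
significant loop when its right-tail probability P(Y ≥ y_obs) passes
Benjamini–Hochberg control at q ≤ 0.05. Significant loops are compared
between conditions with a two-group NB Wald test (log library-size offsets)
and partitioned into **static**, **gained** (log₂FC > 1, p < 0.05) and
**lost** (log₂FC < −1, p < 0.05).

**Domains and compartments.** TAD boundaries are insulation minima pooled
over multiple window sizes; candidate domains between boundaries are scored
by confidence = mean observed/expected contact inside the domain − 1, and
only positive-confidence domains are retained, greedily assembled into a
nested (laminar) hierarchy. A/B compartments come from the leading
eigenvector of the Pearson correlation of the O/E matrix at 100 Kb, with the
arbitrary eigenvector sign oriented so that A bins are the ones with higher
ATAC peak coverage.

**COREs and footprints.** COREs are chains of ≥ 2 ATAC peaks with
consecutive gaps < 20 Kb spanning ≥ 1 Kb. TF footprints are scored, after
removing multiplicative Tn5 insertion bias by local-mean scaling, as mean
flank signal minus mean center signal at JASPAR-motif occurrences inside
loop anchors; AS-vs-GFP binding differences per anchor (and per TF class)
use a Wilcoxon rank-sum test with exact small-sample enumeration.

## Worked example

Run the full pipeline on the default synthetic genome (one 20 Mb chromosome,
10 Kb bins, 2 conditions × 2 replicates, 50 planted loops: 20 static /
10 gained / 20 lost):

```sh
regulohub run-all --seed 1 --out run/
```

Selected lines of the printed report (`run/report.txt`):

```
loops.significant.union=51
loops.static=18
loops.gained=13
loops.lost=20
tads.outermost.GFP=21
cores.count.GFP=8
core_promoter_loops.count=5
diffbind.anchors_tested=5
diffbind.anchors_p05=1
diffacc.significant=30
recovery.loop_recall=0.98
recovery.loop_fdr=0.0392157
recovery.tad_boundary_recall.GFP=0.95122
recovery.compartment_agreement.GFP=1
recovery.core_exact.GFP=1
```

Reading: 51 loops pass q ≤ 0.05 in at least one condition, recovering 49 of
the 50 planted loops with 2 non-planted calls; differential classification
labels 13 gained and 20 lost (all 10 planted gains and 19/20 planted losses
recovered, no gained↔lost swaps). All 8 planted COREs are found exactly, 5
CORE–promoter loops link planted promoters to planted COREs, and the one
anchor with a planted condition-specific binding gain is the one anchor
flagged by the per-anchor Wilcoxon test. The three regulatory-hub anchors
are ranked nearest/mid/farthest from the closest TAD boundary, mirroring the
contact-point geometry analysis of a regulatory hub.

The library API mirrors these stages (`regulohub.loops.call_loops`,
`regulohub.domains.call_tads`, `regulohub.cores.detect_cores`,
`regulohub.footprints.differential_binding`, …); `regulohub simulate` writes
the synthetic fixtures (HiC-Pro triplet matrices, narrowPeak, bedGraph cut
tracks, JASPAR PFMs, truth manifest) as plain text for use with the
per-stage subcommands.

## Layout

- `src/regulohub/synthetic.py` — planted architecture + Hi-C/ATAC simulators
- `src/regulohub/intervals.py` — interval algebra, promoters, BED-family I/O
- `src/regulohub/hic.py` — contact matrices, ICE, merging, O/E, Pearson
- `src/regulohub/loops.py` — NB background, significance, differential calls
- `src/regulohub/domains.py` — TADs, compartments, localization, ranking
- `src/regulohub/cores.py` — CORE detection and CORE–promoter loops
- `src/regulohub/footprints.py` — bias correction, motif scan, Wilcoxon
- `src/regulohub/accessibility.py` — differential accessibility stand-in
- `src/regulohub/pipeline.py`, `cli.py` — orchestration and `regulohub` CLI

See `docs/methods.md` for the full model description, parameter defaults,
and known limitations.
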