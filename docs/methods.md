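# Methods

This note documents the models, parameter defaults, and design choices in
`regulohub`, and states what the synthetic testbed does and does not show
about real data.

## Synthetic genome and simulators

The generator plants, on a single 20 Mb chromosome (10 Kb analysis bins,
100 Kb compartment bins):

- **Compartments**: an A/B checkerboard of random blocks of 3–10 × 100 Kb,
  mimicking megabase-scale compartmentalization.
- **TADs**: a contiguous chain of up to 20 outer domains of 40–100 bins;
  every other outer domain nests one inner domain (⅓–½ of the parent).
  Domains tile the region back-to-back because real genomes are largely
  covered by domains, and contiguity is what gives insulation boundaries
  their sharp minima.
- **Loops**: 50 bin pairs at 60 Kb–1.95 Mb separation, split 20 static /
  10 gained / 20 lost. Five static loops are designated CORE–promoter
  loops: one anchor bin receives a gene TSS, the other a planted CORE.
- **Genes, peaks, COREs**: 60 TSSs and 120 ATAC peaks. Accessible features
  (peaks, random TSSs) are placed preferentially (90%) in A compartments,
  which is what lets the compartment eigenvector be oriented by peak
  coverage, as in real chromatin. Planted COREs are peak chains with gaps
  below 20 Kb; all other peaks are kept ≥ 25 Kb from any neighbor so the
  planted clusters are exactly the true clusters. CORE-anchor clusters have
  5 peaks because a 5-vs-5 exact rank-sum test can reach p ≈ 0.008, whereas
  3-vs-3 can never pass 0.05.
- **Motif footprints**: one JASPAR-style motif occurrence in about half the
  peaks (three planted motifs with distinct classes/families); sites are
  bound or unbound. One CORE anchor is the *gain* anchor (bound in AS only),
  one the *null* anchor (equally bound in both conditions).

**Hi-C counts.** For bins i < j at distance d bins, the expected count per
replicate is

    μ_ij = s · d^(−α) · tad_boost^(#shared TADs) · comp^[same compartment] · loop^[planted loop]

with α = 1, and realized counts drawn NB(μ, θ) independently per replicate
(variance μ + μ²/θ). The depth scale *s* is anchored to the control
condition's total weight so that condition-specific loop multipliers produce
exact expected AS/GFP ratios. The diagonal uses a separate high rate and is
excluded from testing by the 50 Kb lower distance bound. The boost exponent
counts *all* planted domains containing the pair, so nested sub-domains are
more enriched than their parents — without this, inner boundaries would be
invisible to any insulation-based caller.

Defaults: depth 5×10⁶ expected cis contacts per replicate (a 20 Mb slice of
a deeply sequenced experiment), θ = 10, tad_boost = 1.35,
compartment factor = 1.3, loop strength = 10. This regime was chosen by an
explicit power analysis: a planted loop must clear Benjamini–Hochberg
control over the ~372,000 tested pairs (needs tail p ≲ 10⁻⁵), while sub-TAD
structure (1.35² × 1.3 ≈ 2.4-fold enrichment) must stay below it. Weaker
loops or higher depth break one side or the other; the point of the testbed
is that the planted truth is recoverable by design, with all *detection*
thresholds held at their conventional values (q ≤ 0.05, |log₂FC| > 1,
p < 0.05, 50 Kb–2 Mb).

**ATAC cut counts.** Per-base Poisson: background 0.05/bp, peaks 2/bp
(strong-peak territory), with bound motif centers thinned by factor
(1 − footprint_depth), footprint_depth = 0.6. A known periodic
multiplicative bias, exp(0.3·sin(2πx/7)), multiplies every rate so the bias
correction has an exact cancellation oracle. Peak-level read counts for the
accessibility stage are NB with planted 3× / ⅓× effects on 25 non-CORE
peaks (CORE peaks are excluded so accessibility changes never confound the
footprint comparison).

**What the simulator does not emulate**: sequence-dependent (hexamer) Tn5
bias, restriction-fragment geometry, mappability/GC covariates, read-level
noise, trans contacts, and correlated replicate structure (replicates are
independent NB draws; the variance model of real biological replicates is
not derivable from the study design). Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated generative
model, not performance on real libraries.

## Contact-matrix stage

ICE balancing follows the standard iterative correction: biases updated by
relative row sums until max|s_i/s̄ − 1| < 10⁻⁶ (≤ 200 iterations), zero-
marginal bins masked (an optional low-marginal percentile mask is exposed,
default off), and the balanced total rescaled to the raw total. Replicates
are merged by entrywise summation *before* ICE for condition-level
matrices. The expected profile is the per-distance arithmetic mean over
non-masked pairs, without smoothing; O/E divides by it. Compartment input
is the Pearson correlation of O/E rows at 100 Kb. Matrices are plain-text
HiC-Pro-style triplet + bin-BED files; binary `.hic`/`.cool` containers are
out of scope.

## Loop statistics

The background is a log-linear NB regression of replicate-summed counts on
log distance per condition — a deliberate reduction of spline-plus-
covariate distance backgrounds, adequate here because the synthetic genome
has no sequence covariates (the fit accepts extra covariate columns).
Dispersion is estimated from the data, so enrichment that is *not* a loop
(domain and compartment structure) widens the fitted NB and is largely
absorbed rather than called. The Poisson seed fit → moment estimate of θ →
NB GLM refit → ML refinement of θ is deterministic and requires no tuning.

Significance is the exact NB right tail P(Y ≥ y) with BH control applied
once over the filtered pair set (50 Kb ≤ d ≤ 2 Mb, fixed *before* testing).
The default calling mode computes q per condition on condition-merged
counts and takes the union of conditions (both modes, per-condition and
pooled, are supported). The differential test is a closed-form two-group NB
Wald test on replicate counts with relative library-size offsets and a
pooled moment dispersion across loops; when one group is all zero, a half
count is added to both group totals to keep the estimate finite. Category
thresholds are strict inequalities. Loops with zero counts everywhere are
untestable and reported static.

## TADs, compartments, localization

Insulation score(b, w) is the mean contact in the w×w square spanning
(b−w…b−1)×(b…b+w−1), for w ∈ {5, 10, 20} bins. Boundary bins are local
minima that are either below (profile mean − 0.5 sd) or have local
prominence ≥ 0.6 sd; the prominence clause exists because a nested domain's
boundary dip rides on its parent's elevated baseline and can sit above any
global threshold. Minima within ±1 bin across windows are pooled.

Candidate domains are boundary pairs of 5–200 bins; confidence is the mean
off-diagonal O/E inside the candidate minus 1, and only positive-confidence
candidates survive — positive confidence is the operative definition of a
"true TAD". Candidates are accepted greedily from strongest confidence
down under a laminarity constraint (any two retained TADs disjoint or
nested), which makes the outermost layer non-overlapping by construction.
Levels count nesting depth from the innermost (level 1). The caller
over-generates weak meta-domains relative to the planted chain (they are
hierarchical parents with small positive confidence); boundary positions,
not domain counts, are the validated output.

Compartment labels are the sign of the leading eigenvector of the Pearson
matrix, oriented so the eigenvector correlates positively with per-bin ATAC
peak coverage; masked bins stay unlabelled. Loop localization is intra
(both anchors overlap the same outermost TAD), inter (different outermost
TADs; adjacent iff consecutive), or unassigned. Boundary-distance ranking
uses boundaries of retained TADs only, anchor midpoints, and coordinate-
ascending tie-breaks; exactly three anchors get the nearest/mid/farthest
labels used for regulatory-hub contact points.

## COREs and CORE–promoter loops

Chain-link clustering with the fixed operative thresholds: consecutive-peak
gap < 20 Kb (measured end-to-start, half-open), span ≥ 1000 bp, ≥ 2 peaks.
This replaces order-statistic adaptive gap selection with the fixed gap the
analysis actually reports; equivalence to all-pairs gap-graph connected
components is tested against an independent oracle. CORE–promoter loops
need one anchor overlapping (≥ 1 bp) a 2200 bp promoter and the other a
CORE; the 2200 bp window is realized as [TSS−1650, TSS+550) — the 2000 bp
accessibility promoter (−1500/+500) widened ~10% per side, since only the
width is fixed by convention; the offset is configurable. The
complete-overlap flag marks an entire promoter or CORE inside a 10 Kb
anchor, or an anchor inside a CORE wider than the bin.

## Footprints and differential binding

Bias correction: corrected(x) = cuts(x) − localmean(cuts)(x) ·
bias(x)/localmean(bias)(x) over a 200 bp sliding window; cuts exactly
proportional to the bias cancel to zero, and protected centers go negative.
The binding score is mean corrected flank (60 bp each side) minus mean
corrected center; flank size and window are configurable knobs, not claims
about any external tool's internals. Motif occurrences come from log-odds
scanning (pseudocount 1, uniform background) of both strands at ≥ 0.8 of
the maximal score, with overlapping same-motif hits merged to the best.
Sites are restricted to loop-anchor bins (≥ 1 bp overlap; a site spanning
two anchors counts in both).

The Wilcoxon rank-sum test is self-contained so that small-sample results
are oracle-checkable: exact enumeration of all C(n+m, n) rank assignments
(midranks for ties) when both groups ≤ 8, otherwise the normal
approximation with tie and continuity correction; groups under 3 sites are
reported untested. Tests run per anchor on the full site list and grouped
by TF class.

## Accessibility stand-in

Differential accessibility reuses the two-group NB Wald machinery (it is an
explicit stand-in for consensus-peak DESeq2/limma-class testing, not a
reimplementation of either): significant iff linear |FC| > 1.5 and
p < 0.05; linear_fc ≡ 2^|log₂FC| exactly. Peaks map to genes through the
±3000 bp TSS window (many-to-many).

## Numerical and degenerate-input conventions

All coordinates are 0-based half-open; adjacency is non-overlap. θ is
clamped to [10⁻³, 10⁶] (10⁶ ≈ Poisson). All-zero matrices, degenerate
correlation matrices, single-replicate designs, and empty boundary sets
raise errors naming the condition; empty peak sets and zero-TAD
configurations return empty results. Every randomized component takes an
explicit seed, and the pipeline report is byte-reproducible for a fixed
configuration.

## Problem sizes

The standard genome (2000 × 2000 bins, ~372k tested pairs, 4 replicate
matrices) runs the full pipeline in well under a minute; the test suite and
the acceptance script each complete in a few minutes on one CPU. These
sizes were chosen so the whole analysis is exercised end-to-end at
desk scale while every statistical stage still operates in its intended
regime (hundreds of thousands of multiple-testing units, low-count NB
tails).
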