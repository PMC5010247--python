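# Methods

## Overview

`mutseg` integrates three cohort tables — somatic mutations (MAF or a
minimal TSV dialect), a normalized expression matrix (genes × samples),
and disease-free-survival records — around one driver gene. Two
analyses are built on this: a transcriptome-wide *response-gene* scan
(changepoint detection on expression ordered by mutation position) and a
mutation-consequence *group* analysis (differential expression,
signatures and survival for +1-frame extension mutants vs. all other
mutants).

## Cohort preparation

Mutations marked silent are removed; for METABRIC-style cohorts the
noncoding "RNA" class is removed as well. Unknown variant
classifications are retained as `other` rather than dropped, so that
class removal is always an explicit filter. For each driver gene,
patients with more than one retained mutation in that gene are excluded
entirely; the analyses operate on the single-mutation patients.

Sample harmonization intersects mutation and clinical sample ids with
the expression matrix after an optional prefix truncation (default: the
first 15 characters, the TCGA sample-level barcode). The matching rule
is configuration, not inference: cohorts with other id schemes can set
`barcode_length=None`. Zero overlap is a hard error.

All coordinates are 1-based inclusive (MAF convention). Variant cDNA
positions use the coding convention: position 1 is the A of the start
codon; pure insertions insert *after* the stated position.

## Segmentation engine

The changepoint engine is a from-scratch implementation of circular
binary segmentation: for a series *y* of length *n*, every arc (*i*, *j*]
is scored by the normalized arc-vs-complement mean difference

Z(i,j) = (ȳ_arc − ȳ_comp) / (s·√(1/k + 1/(n−k))), k = j − i,

with *s* the overall sample SD (ddof 1). Z is invariant under affine
maps of *y*, and the whole procedure is invariant under strictly
monotone transforms of the raw expression because it only ever sees
midranks. Admissible arcs are those whose induced linear pieces (three
for an interior arc, two for a boundary-touching arc) each contain at
least `min_width` observations. The maximal |Z| is compared with the
same maximum over `nperm` random permutations of the series; the
add-one estimator p = (1 + #{T(π) ≥ T_obs}) / (nperm + 1) never returns
zero. If p ≤ `alpha` the series is split at the arc's interior
boundaries and the procedure recurses on each piece; pieces narrower
than 2·`min_width` are never tested. No pre-smoothing and no post-hoc
pruning/undo are applied; whether an established implementation's extra
pruning options would change individual calls is deliberately out of
scope — correctness here is established against an exhaustive
arc-search oracle, null calibration and planted-step recovery rather
than bit-parity with any other implementation.

Numerical details: ties in |Z| (an arc and its complement tie
structurally) are broken to the lexicographically smallest (i, j);
zero-variance series score T = 0 and are never split; permutation maxima
are computed vectorised in blocks over all admissible arcs. Every
stochastic stage derives its seed from the user seed and a stage name
via CRC mixing, so per-gene results do not depend on scan order and
whole runs are bit-reproducible.

Defaults are the strict cohort-scale settings `alpha = 0.005`,
`nperm = 20000`, `min_width = 5`. The parameter validator requires
alpha·(nperm+1) ≥ 1 so the permutation resolution can ever reject.
Tests and the acceptance script run `nperm = 2000` at n = 60 — the
add-one p-value floor (1/2001) is still well below alpha, and a scan of
~100 genes completes in seconds on one CPU.

## Response genes

For driver gene *D* and gene *g*, the ordered series takes the
single-mutation patients of *D* sorted by mutation genomic position
(ties broken by sample id, stable) and assigns the midrank of *g*'s
expression over exactly these patients. A gene qualifies as *expressed*
when at least 20% of these patients have nonzero values (configurable;
the criterion is not derivable from first principles, so it is surfaced
as configuration). Genes with at least one accepted breakpoint are
response genes.

Breakpoint indices map to genomic coordinates at the midpoint of the
flanking mutation positions (tied positions map to the shared value) —
a deliberate, documented choice, since densities are plotted "along the
gene" and any within-gap position is equally defensible. Densities use
Gaussian kernels with Silverman's rule bandwidth floored at 1% of the
gene span, renormalised to unit mass over the evaluation grid, computed
separately for single-breakpoint and multi-breakpoint genes and for the
mutation positions themselves.

No multiple-testing correction is applied across the transcriptome: the
strict split alpha is the only control, matching the analysis the scan
reproduces; a Benjamini–Hochberg layer can be applied downstream on the
reported top split p-values by users who want one.

## Consequence prediction

A transcript model is the spliced cDNA (5'UTR + CDS + 3'UTR) with CDS
bounds and exon end positions. Variants are applied to the cDNA, and the
mutant message is translated from the start codon *through the 3'UTR*;
classification compares the mutant ORF length L with the wild-type
length W: frameshifts with L < W are truncations, L > W extensions
(novel tail = L − W; altered original residues = W − first altered + 1),
L = W same-length frameshifts. If no stop is reached before the end of
the provided cDNA the call is `no_stop` rather than a guess — extensions
are only computable when the 3'UTR is present. Net frame is
(inserted − deleted) mod 3, with 1 → +1 and 2 → −1.

Two residue anchors are reported. `first_altered_residue` is the first
codon whose *translation* differs from wild type (synonymous shifted
codons are skipped). `protein_change` ("p.X###fs") anchors at the first
codon *touched* by the shifted frame — for a pure insertion after coding
position p that is codon p//3 + 1 — matching common annotation practice
even when the first touched codon happens to translate synonymously.

The bundled driver transcript is a **synthetic** GATA3-like model (the
real reference cDNA is not redistributed): a 444-residue protein whose
engineered codons reproduce the documented arithmetic exactly — an
insertion after coding position 1006 truncates (p.G336fs); insertions in
the codon-395..444 hotspot region extend the protein by 63 novel
residues (p.P409fs at the hotspot), altering at most 49 of the original
C-terminal residues; −1-frame deletions in the hotspot region truncate.
Everything outside the engineered sites is filler sequence, so the model
supports coding arithmetic, not sequence-homology work. An
annotation-trusting classification mode (frame from allele lengths,
anchor parsed from `p.X###fs`) is provided for cohorts without usable
cDNA positions; re-translation is the primary mode.

## Group analysis

Single-mutation patients are labelled ext_plus1 / ext_minus1 /
trunc_plus1 / trunc_minus1 / other_mutant from their consequence; the
comparison is ext_plus1 (the dominant class) against the union of the
rest. Per-gene statistics are the median fold change
(median_case / median_control, optional pseudocount, default 0) and a
two-sided Wilcoxon rank-sum p-value — exact enumeration when the
combined sample size is ≤ 12 with no ties, otherwise the normal
approximation with tie and continuity corrections (the switch point is
configurable). Signatures are the top-k genes by ascending p, ties by
|log2 FC| descending then gene id (the ranking rule is a documented
package choice; signatures from other sources can be supplied as plain
gene lists). Cross-cohort concordance counts shared genes whose fold
changes point the same way; "flat" matches only "flat". Default
signature size k = 50.

Survival uses right-censored disease-free survival in months:
Kaplan–Meier curves per group and the two-group log-rank (Mantel–Cox)
chi-square with 1 df (delegated to lifelines; verified in tests against
a hand-computed hypergeometric O/E/V oracle). No Cox regression or
covariate adjustment is provided.

## Synthetic cohorts

The generator draws one driver mutation per patient: position from a
mixture of Gaussian hotspots (defaults: an extension hotspot at coding
position 1224 with weight 0.45, a truncation hotspot at 1006 with
weight 0.2, the remainder uniform over the CDS; hotspot SD 15 bp) and
frame from (+1, −1, 0) probabilities (0.6, 0.15, 0.25). Each (position,
frame) pair is realised as an actual insG / 1-bp deletion /
substitution on the synthetic transcript, and the ground-truth class is
computed by an independent naive mutate-translate-diff oracle — which
the package classifier must then reproduce.

Expression is Gaussian on the raw scale: baseline 8, noise SD 1.
Response genes add ±effect·SD (default effect 2) to samples whose
mutation-position rank exceeds the planted ordinal boundary (default
30 of 60); optional group genes instead shift ext_plus1 samples;
null genes are pure noise; values are clipped at zero (inactive at the
default settings). Effects are injected *before* rank transformation so
the pipeline's midrank machinery is genuinely exercised. This is
deliberately not a negative-binomial RNA-seq model: the analysis
consumes ranks only, so a location-shift Gaussian exercises exactly the
structure the method uses — passing tests therefore demonstrate
correctness of the rank/segmentation machinery, not robustness to
count-specific artefacts (library size, overdispersion, dropout).

Survival times are exponential (baseline hazard 0.02/month; hazard
ratio, default 3, applied to ext_plus1 patients) with independent
exponential censoring whose hazard is chosen to give the target
censored fraction (default 0.4) in the baseline group — in the elevated-
hazard group the realised censoring fraction is correspondingly lower.

Default test-scale conditions are 60 patients and 100 genes (5 response)
at nperm = 2000; the shipped defaults for real cohort runs remain
nperm = 20000.

## Known limitations

* No VCF input, genome-to-transcript projection, liftover, splice-site
  or NMD modelling; cDNA positions are inputs.
* The bundled driver transcript is synthetic (coding arithmetic only).
* Breakpoint counts per gene are reported without pruning; whether to
  collapse adjacent breakpoints is left to downstream interpretation.
* Survival handles two groups and right censoring only.
* The synthetic generator's Gaussian expression model does not emulate
  count noise, batch structure or correlated genes.
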