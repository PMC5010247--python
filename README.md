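# mutseg

Mutation-position / expression segmentation analysis for tumour cohorts.

Recurrently mutated cancer genes often carry functionally distinct
mutation classes in different regions of the gene body — for example,
*GATA3* in breast cancer harbours both truncating frameshifts and a
hotspot of +1-frame frameshifts near proline 409 that read through the
stop codon and append a novel 63-residue C-terminus ("extension"
mutants). `mutseg` provides a tested, reusable implementation of the
computational analyses needed to find and characterise such classes from
cohort-scale somatic mutation, expression and clinical tables:

1. **Response-gene detection.** For a driver gene, patients carrying
   exactly one (non-silent) mutation are ordered by the ranked position
   of that mutation; each expressed gene's rank-transformed expression
   over those patients forms an ordered series, which is segmented by
   circular binary segmentation (CBS). A gene whose series shows at
   least one breakpoint is a *response gene*; breakpoints map back to
   genomic coordinates and are summarised as kernel densities along the
   driver gene.
2. **Frameshift consequence prediction.** Coding indels are applied to a
   transcript model and re-translated through the 3'UTR, classifying
   each as a frameshift truncation, C-terminal extension (with novel
   tail length), same-length frameshift, or point consequence.
3. **Group analysis.** Patients are partitioned by consequence
   (extensions/truncations × frame); the dominant +1-extension group is
   compared against all other mutants: median fold changes with Wilcoxon
   rank-sum p-values, a top-*k* gene signature, direction concordance
   across cohorts, and Kaplan–Meier / log-rank disease-free survival.
4. **Synthetic cohorts.** A generator plants hotspot mutation mixtures,
   step-shift response genes, case-shifted signature genes and
   group-dependent exponential survival — with full ground truth — so
   every stage is testable end to end.

## The statistic

For a series *y* of length *n*, CBS scans all arcs (*i*, *j*] whose
induced pieces each have at least `min_width` observations and maximises

    Z(i,j) = (ȳ_arc − ȳ_complement) / ( s · √(1/k + 1/(n−k)) ),   k = j − i,

where *s* is the overall sample SD. The maximal |Z| is referred to a
permutation distribution (`nperm` random permutations, add-one p-value);
a split is accepted when p ≤ `alpha` and the procedure recurses on the
resulting pieces. Defaults are the strict cohort-scale settings
`alpha = 0.005`, `nperm = 20000`, `min_width = 5`.

## Worked example

```python
from mutseg import (SegmentationParams, TranscriptomeScan, GroupComparison,
                    synthetic_gata3_transcript)
from mutseg.simulate import SimulationConfig, simulate_cohort

cohort, truth = simulate_cohort(SimulationConfig(seed=42, n_group_genes=5))
params = SegmentationParams(alpha=0.005, nperm=2000, seed=42)

scan = TranscriptomeScan(cohort, "GATA3", params).fit()
print(scan.summary())
```

```
Response-gene scan: driver GATA3
  mutation-bearing samples: 60
  genes scanned:  105 (0 filtered, 105 segmented)
  response genes: 7
```

All five planted response genes are recovered, each with one breakpoint
at (or within one sample of) the true ordinal boundary after sample 30,
with split p-values at the permutation floor:

```
   gene  n_breakpoints breakpoint_indices  breakpoint_coords  top_split_p
RESP001              1                 30        8.09787e+06     0.000500
RESP002              1                 30        8.09787e+06     0.000500
RESP003              1                 31        8.09788e+06     0.000500
RESP004              1                 28        8.09787e+06     0.000500
RESP005              1                 30        8.09787e+06     0.000500
```

The group comparison classifies every patient's mutation on the
transcript model, compares +1-frame extensions against all other
mutants, and finds the five planted case-shifted genes at the top of the
differential table along with the planted survival disadvantage:

```python
g = GroupComparison(cohort, synthetic_gata3_transcript(), "GATA3",
                    signature_size=10).fit()
print(g.summary())
```

```
Group comparison (ext_plus1 vs. other mutants)
  groups: ext_plus1=18, ext_minus1=1, trunc_plus1=14, trunc_minus1=9, other_mutant=18
  top differential genes:
        GRP001  FC= 0.739 (down)  p=4.99e-09
        GRP005  FC= 1.286 (up  )  p=1.16e-07
        GRP003  FC= 1.251 (up  )  p=1.59e-06
        GRP004  FC= 1.210 (up  )  p=3.81e-06
        GRP002  FC= 1.186 (up  )  p=6.52e-06
  DFS log-rank: chi2=9.068, p=0.0026 (events: {'ext_plus1': 13, 'other': 22})
```

Here the simulated extension group progresses markedly faster (hazard
ratio 3), and the log-rank test detects it at p ≈ 0.003.

## Command line

```bash
mutseg simulate --n-patients 60 --seed 13 --out sim/
mutseg scan     --mutations sim/mutations.maf.tsv --expression sim/expression.tsv \
                --driver GATA3 --alpha 0.005 --nperm 20000 --min-width 5 --out scan/
mutseg classify --mutations sim/mutations.maf.tsv --driver GATA3 --out cls/
mutseg groups   --mutations sim/mutations.maf.tsv --expression sim/expression.tsv \
                --clinical sim/clinical.tsv --driver GATA3 --out grp/
```

Real cohorts are supplied as TCGA-style MAF (`--dialect tcga` removes
silent calls; `--dialect metabric` additionally removes noncoding "RNA"
calls), an expression TSV (genes × samples) and a clinical TSV
(`sample_id`, `dfs_months`, `dfs_event`). Every run writes a
`run_summary.json` with version, seed, parameters and input hashes.

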