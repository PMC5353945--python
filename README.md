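# neuromark

Pathology-seeded co-expression module discovery and prognostic biomarker
evaluation for ALS transcriptomics.

## The problem

Amyotrophic lateral sclerosis (ALS) lacks a prognostic biomarker that works
across its heterogeneous genetic backgrounds. One near-universal feature is
the accumulation of p62/TDP-43-positive cytoplasmic inclusions in motor
neurons, and the burden of these inclusions tracks disease severity.
`neuromark` implements, as a tested and reusable pipeline, a data-driven
workflow that turns this observation into candidate biomarkers:

1. **Discovery.** Screen a motor-neuron expression matrix for transcripts
   whose expression follows the per-sample inclusion count (Spearman's ρ,
   p < 0.01 unadjusted). Use each hit as a seed and collect its top 1% of
   co-expression partners (Pearson r); build a weighted gene co-expression
   network over the union, with adjacency $a_{ij} = |\mathrm{cor}(x_i,x_j)|^\beta$
   at a soft-threshold power β chosen for approximate scale-free topology.
   Convert to topological overlap
   $\mathrm{TOM}_{ij} = \frac{\sum_u a_{iu}a_{uj} + a_{ij}}{\min(k_i,k_j)+1-a_{ij}}$,
   cluster $1-\mathrm{TOM}$ by average linkage, read modules off the
   dendrogram, and discard modules with no pathology-correlated seed.
2. **Prioritisation.** Score every seeded module against three independent
   assessment gene sets — duration-correlated motor-neuron genes,
   rapid-vs-slow lymphoblastoid genes (Mann–Whitney U), and genome-wide
   significant GWAS genes — with one-sided Fisher exact tests on the
   measured-gene universe. Modules enriched with all three ("triple
   enriched") are the biomarker candidates; a motor-neuron-identity gene set
   serves as a negative control.
3. **Biomarker assessment.** Expand the top module with interaction partners
   from a weighted edge table, then evaluate it in blood (Cox proportional
   hazards of survival on the module's top 15 expression PCs; per-gene
   logistic screens; leave-one-out cross-validated gene panels) and in CSF
   (soluble TREM2: rank-based group comparison, quartile staging of the
   disease course, stage-stratified Spearman association with duration).

Every stage is validated on synthetic studies with planted ground truth
(module membership, pathology coupling, progression shifts), and the CSF
stage ships with a transcribed clinical table of 46 sporadic ALS patients and
20 controls so its statistics are reproduced exactly.

## Worked example

```bash
python examples/04_csf_strem2.py
```

prints

```
ALS mean sTREM2 17.7 ng/ml (n=46) vs control 7.2 ng/ml (n=20)
rank test, ALS elevated: p = 0.033 (two-sided 0.067) - sTREM2 is higher in ALS CSF
      early: n=11  mean  36.4 ng/ml
     middle: n=23  mean  11.5 ng/ml
       late: n=11  mean  12.7 ng/ml
   unstaged: n= 1  mean   8.3 ng/ml
sTREM2 is highest early in the disease course and falls later.
early stage sTREM2 ~ duration: rho = -0.86, one-sided p = 0.9997
late stage sTREM2 ~ duration: rho = +0.73, one-sided p = 0.0057
```

ALS CSF carries about 18 ng/ml of soluble TREM2 against 7 ng/ml in controls;
concentrations are highest (36 ng/ml) in patients sampled in the first
quartile of their disease course and lower (13 ng/ml) in the last quartile,
where higher sTREM2 associates with longer survival (ρ = 0.73) — the pattern
that motivates sTREM2 as a prognostic marker. The other examples
(`examples/01–03`) run the discovery chain, module expansion and the blood
evaluation on synthetic studies and annotate each number they print.

A thin CLI wraps the same library calls: `neuromark csf-eval`,
`neuromark simulate`, `neuromark discover`, `neuromark blood-eval`,
`neuromark run-all` (YAML-configured; see `neuromark --help`).

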