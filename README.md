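# antheat

Comparative heat-stress analysis for desert and temperate ants: survival
dose-response statistics, consensus differential expression, cross-species
overlap testing, and orthogroup category enrichment.

Desert ants survive body temperatures that kill most insects.  Comparing
their transcriptomic heat-stress response with temperate relatives asks a
sharp question: is heat hardiness built on *reactive* induction of
protective genes (many expression changes under stress) or on
*constitutive* high expression of the same genes (few changes, chaperones
already up)?  This package implements the full analysis pipeline for a
six-species study — four desert species across three genera plus two
temperate outgroups — and a synthetic-data generator that emulates the
study design end to end, so every statistic is testable without any data
download.

## What it computes

- **Thermal tolerance** (`antheat.thermal`): tube-level survival assays are
  fit with a binomial GLM, `logit P(death) = beta0 + beta1 T`, giving the
  median lethal temperature `LT50 = -beta0/beta1` with a delta-method 95%
  CI (Firth-penalized refit under separation).  Species are compared with
  the LT50 ratio test (`z = log(LT50_A/LT50_B)/se`); the upper thermal
  limit (UTL) is the highest tested temperature whose survival does not
  differ from the best-surviving group (ANOVA + Tukey HSD); the decline
  width measures how many degrees the survival crash spans.
- **Expression response** (`antheat.expression`): TMM normalization
  (matches edgeR's `calcNormFactors` to 1e-6), two built-in differential
  callers (an NB exact-style conditional test and a moderated t on
  log2-CPM), and the consensus filter: FDR <= 1e-3 in both callers,
  concordant sign, mean |log2FC| >= 2.  HSP70/HSP90 panels are pulled by
  annotation search terms; species are classified weak/medium/strong by
  DET percentage and called constitutive / reactive / temperate-like.
- **Cross-species overlap** (`antheat.overlap`): DET lists reduce to
  unique meaningful annotation names ("uncharacterized protein" dropped);
  each pairwise overlap is tested against a Monte-Carlo null that redraws
  the same number of transcripts from each full transcriptome (10,000
  iterations, p < .01), plus the transcriptome-size vs DET-count Pearson
  correlation.
- **Orthology** (`antheat.orthology`): OrthoFinder-style orthogroups are
  classified into categories I (all species) through V (species-specific);
  genes in single-genus or species-specific orthogroups (IV/V) are
  taxonomically restricted, and a two-sided Fisher exact test asks whether
  restricted genes are enriched among each species' DET.
- **Synthetic studies** (`antheat.simulate`): seeded generators for
  survival assays, annotation catalogs with a shared name pool, orthogroup
  tables with a known category mixture, and NB count matrices with
  constitutive vs reactive stress-gene archetypes — all with ground truth
  and a self-audit.

## Worked example

Run the numbered analysis scripts in order (each reads `results/` from the
previous step):

```
python analysis/01_simulate_study.py --seed 1
python analysis/02_thermal_tolerance.py
python analysis/03_differential_expression.py
python analysis/04_cross_species_overlap.py
python analysis/05_orthology.py
python analysis/06_report.py
```

Step 02 prints the per-species heat-tolerance table:

```
          lt50 ci95_half_width fit_method   utl decline_width
species
Cbom      45.0            0.37         ml  43.0           6.0
Chol      46.0            0.41      firth  45.0           2.0
Mbag     50.13            0.36      firth  49.0           2.0
Orob      46.5            0.34         ml  43.0           8.0
Ffus      42.0            0.41      firth  41.0           2.0
Msab      40.0            0.41      firth  39.0           2.0
```

Mbag (true LT50 49.83) is the most heat-tolerant species and Msab (39.91)
the least; the steep-decline species crash from full survival to zero
within two degrees, while the two reactive desert species decline over six
degrees or more.  Step 03 links this to expression:

```
      det_count  up_hs  down_hs  transcriptome_size  det_pct profile  hsp70_de  hsp90_de        strategy
Cbom         13      8        5                2096     0.62  medium      True      True        reactive
Chol          0      0        0                2226     0.00    weak     False     False    constitutive
Mbag          0      0        0                1936     0.00    weak     False     False    constitutive
Orob         35     26        9                2285     1.53  medium      True      True        reactive
Ffus        248    189       59                3121     7.95  strong      True      True  temperate_like
Msab        540    382      158                4239    12.74  strong      True      True  temperate_like

transcriptome size vs DET count: Pearson r=0.99, p=6e-05 over 6 species
```

The two constitutive desert species change almost nothing under heat yet
keep HSP70/HSP90 high in both conditions; the reactive species induce them.
Step 04 then shows which species pairs share more DET names than the
resampling null predicts (6/15 pairs at p < .01 in this run, none of them
involving the constitutive species), and step 05 summarizes orthogroup
categories and restricted-gene enrichment among DET.

The same pipeline is scriptable from a shell via the `antheat` CLI
(`antheat simulate`, `antheat lt50`, `antheat ratio-test`, `antheat de`,
`antheat overlap`, `antheat run-all`, ...), and every stage is importable
from Python.

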