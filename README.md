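# crcpanel

Cohort genomics for targeted cancer-panel sequencing, built around the
analyses a ~400-gene solid-tumor panel supports in colorectal cancer (CRC):

- **tumor-only somatic filtering** — population allele-frequency
  deprioritization (any database AF > 1%), a 10% allelic-fraction calling
  floor, and a two-component allele-fraction model separating germline
  heterozygous from somatic calls;
- **mutation burden and hypermutation** — TMB = non-synonymous somatic SNVs
  per megabase of panel footprint; hypermutated tumors (typically MMR-deficient
  or *POLE*-mutant) called above a largest-gap threshold, and a random-panel
  ROC experiment quantifying how panels of 400/300/200/100/50 genes lose the
  power to discriminate them;
- **96-context mutational signatures** — substitution-type × flanking-base
  classification (pyrimidine reference), de-novo extraction by
  Kullback–Leibler multiplicative-update NMF, and deconvolution against a
  reference catalog by floor-and-refit constrained least squares;
- **donor-similarity clustering** — with c_ij the number of mutated genes two
  donors share (KRAS/NRAS merged to RAS), the similarity 1/(c_ij + 1) is
  clustered hierarchically (eight Lance–Williams linkage dialects, five
  distances) and the (distance, linkage, k) setting is chosen by the
  clustering-stability indices APN, AD, ADM and FOM under delete-one-column
  validation;
- **clinical association** — per-cluster and per-gene two-tailed Fisher exact
  tests on dichotomized clinicopathological variables, simulation-based power,
  and minimum-sample-size prediction on a 20–500 donor grid;
- **Stage-IV outcomes** — the anti-EGFR exclusion chain, Kaplan–Meier
  progression-free survival, log-rank comparison of genomic subgroups, and
  waterfall/best-response tables.

Because real panel cohorts of this kind are not publicly distributable, the
package ships a first-class synthetic cohort generator
(`crcpanel.simulate`) that reproduces the statistical structure these
analyses assume — ~200 donors, ~8% hypermutated at 30 vs 5 mut/Mb,
driver-weighted gene propensities, signature-mixture SNV contexts, planted
co-mutation clusters with clinical and hazard shifts, and germline
contamination for the filter to remove. All stages are exercised end-to-end
on it.

## Worked example

The numbered drivers under `analysis/` run the full study on the synthetic
cohort and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_somatic_filtering.py
python analysis/03_burden_hypermutation.py
# ... through 07_survival_outcomes.py
```

Representative output (seed 0):

```
kept 1965 of 2852 calls as putatively somatic
  removed  385  (population_af)
  removed   16  (af_floor)
  removed  486  (likely_germline)

15 donors called hypermutated (200/200 agreement with simulation truth)
mean AUC by random-panel size (100 replicates):
   400 genes: 1.0000 (sd 0.0000)
   300 genes: 1.0000 (sd 0.0001)
   200 genes: 0.9992 (sd 0.0018)
   100 genes: 0.9795 (sd 0.0191)
    50 genes: 0.9139 (sd 0.0416)

hypermutated: dominant components mmr_deficient=0.50, pole_exo=0.25
non_hypermutated: dominant components clock_cpg=0.53, flat=0.22
```

Reading this: the filter removed the planted germline contamination (high
population AF or heterozygous-like allele fractions at ~50%); burden calling
then separated hypermutated donors perfectly on the full panel; shrinking
random panels degrades the ROC (full-size panels are essentially equivalent
to exome-scale burden for hypermutation detection, 50-gene panels are not);
and group-level deconvolution attributes hypermutated spectra to the
MMR/POLE-like components they were simulated from.

The same stages are available as a CLI (`crcpanel simulate|filter|burden|
panel-roc|signatures|cluster|associate|survival|run-all`) and as one call,
`crcpanel.pipeline.run_pipeline(config)`, which writes a manifest with a
config hash and per-stage row counts; reruns are byte-identical.

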