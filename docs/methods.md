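# Methods

This note documents the models and procedures implemented in `crcpanel`,
the parameter defaults and why they were chosen, the numerical conventions,
and the known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates, formats, missing data

All variant tables are tab-separated with 1-based inclusive positions (MAF
convention). Unknown variant-class strings map to `other` with a warning,
because downstream analyses only distinguish silent vs protein-altering and
truncating (nonsense/frameshift/splice) vs missense. Missing clinical values
are an explicit `NA` sentinel, never imputed; contingency tables exclude
them pairwise.

## Tumor-only somatic filtering

Without a matched normal, three filters compose in a fixed order:

1. **Population frequency** — a call is deprioritized iff *any* populated
   database frequency strictly exceeds `pop_af_max` (default 0.01). Calls
   with no population annotation pass. Treating "any database" as
   disqualifying is the conservative reading when several databases are
   consulted jointly.
2. **Allelic-fraction floor** — calls below `min_allelic_fraction` (default
   0.10) are removed; a call at exactly 10% survives, since the threshold
   defines the calling limit rather than an exclusion band.
3. **Germline/somatic model** — the allele fraction is scored by the log
   density ratio of two Beta components: a germline-heterozygous component
   centered at `het_center` = 0.5 with spread `het_sd` = 0.07 (FFPE panel
   data at ~500× shows het AFs within a few percent of 0.5), and a somatic
   component centered at `purity_prior`/2 (default purity 0.6, so AF ≈ 0.3
   for a clonal heterozygous somatic variant) with a deliberately broad
   `somatic_sd` = 0.15 to absorb subclonality and copy-number distortion.
   Calls are labeled somatic when the log odds exceed
   `decision_threshold` = 0. Beta parameters come from moment matching;
   the spread is capped below the maximal Beta variance so the density is
   always proper. A call without an allelic fraction is passed through as
   `unscored` rather than silently kept or dropped.

The order — population, then AF floor, then model — was an open design
choice; it is fixed, documented, and covered by an idempotence test
(re-filtering a filtered set is the identity). Manual pathologist review
cannot be automated; an override table of variant keys forced to
somatic/germline stands in for it.

Copy-number calls are kept as gains only above 2.5-fold and losses only
below 0.5-fold, both strict.

## Burden and hypermutation

Burden counts **non-synonymous SNVs only** (silent calls and indels
excluded) within panel genes, divided by the panel footprint in megabases.
The default footprint for a ~415-gene panel is 1.6 Mb — roughly 1/2000th of
a 3.2 Gb genome — and is always overridable in the panel file.

Hypermutation is a strict `burden > threshold` call. Cohorts with a
hypermutated subpopulation are bimodal in log burden, so the default
threshold is the back-transformed midpoint of the largest gap between
consecutive sorted values of log10(burden + 0.1), searched in the upper half
of the distribution. The gap must span at least 0.15 decades: a hypermutated
mode sits several-fold above background (≥ 0.5 decades between modes even at
a 6× rate ratio), while within-mode Poisson gaps at cohort scale stay well
below 0.1 decades. Without such a gap (or with fewer than four donors) a
fixed fallback of 15 mut/Mb applies.

The **random-panel experiment** draws, for each panel size (default
400/300/200/100/50, 100 replicates), a uniform gene subset without
replacement, recomputes burden with the footprint scaled proportionally to
subset size (the only scaling available at gene-count granularity), builds a
ROC of burden against hypermutation truth per replicate, and averages
curves vertically on a fixed 101-point false-positive-rate grid. ROC points
group tied scores (all tied donors move together); AUC is trapezoidal.

## 96-context mutational signatures

Channels follow the standard pyrimidine-reference convention: six
substitution types (C>A, C>G, C>T, T>A, T>C, T>G) × sixteen 5′/3′ flanking
pairs, substitution-major, flanks ordered A,C,G,T by 5′ then 3′.
Purine-reference SNVs are folded by reverse complement before lookup; indels
and context-free SNVs are excluded with a reported count. The trinucleotide
context must be present in the input (or retrievable from a local FASTA);
there is no remote fetch.

**Extraction** is multiplicative-update NMF minimizing generalized
Kullback–Leibler divergence (the classic variant of the algorithm behind the
usual signature tools), best of `n_restarts` random initializations,
converged when the relative objective change falls below 1e-8 or at 2000
iterations. The objective is nonincreasing by construction and asserted so
in tests. Signature columns are normalized to sum to one with exposures
rescaled compensatingly. Rank selection is deliberately left to the caller;
`rank_survey` reports the objective and a restart-consistency score over a
k grid but makes no automatic choice. Note that NMF is only identifiable up
to a cone: planted-factor recovery requires some donors near-pure in each
signature, which is also the realistic regime (e.g. POLE ultra-hypermutators).

**Deconvolution** solves min ‖p − Sw‖² with w ≥ 0 and Σw ≤ 1 for the
normalized donor profile p against catalog S (SLSQP with analytic gradient),
then zeroes weights below `weight_floor` = 0.06 and re-fits the survivors to
a fixed point — the floor-and-refit semantics of the standard deconvolution
tools, which suppress spurious trace attributions. `unassigned` = 1 − Σw.

The bundled K=5 catalog is synthetic: five distinct, documented caricatures
(CpG-clock C>T, broad MMR-deficient C>T/T>C, POLE-like C>A at TpCpT,
APOBEC-like TpC, flat). It avoids reproducing any licensed catalog verbatim;
a COSMIC-format TSV (96 rows in canonical order, one column per signature)
can be supplied instead.

## Donor-similarity clustering

For donors i, j and a configured gene set (KRAS and NRAS merged into RAS by
default), c_ij is the number of shared mutated genes and the similarity
matrix entry is 1/(c_ij + 1) ∈ (0, 1] — exactly 1 iff the pair shares
nothing. The diagonal uses c_ii = |genes(i)|. The clustered objects are the
**rows** of this matrix: each donor's similarity profile is its feature
vector, which is the reading consistent with applying a row-distance method
to "the matrix". Whether the diagonal should enter the distance computation
is unknowable from the source description; including it is the natural
row-vector reading and is fixed here.

Agglomeration implements the Lance–Williams recurrences for eight linkage
dialects: ward.D applies the Ward coefficients to the dissimilarities as
given, ward.D2 to their squares (reporting square-root heights); single,
complete, average (UPGMA), mcquitty (WPGMA), median and centroid use their
standard coefficient sets applied to the input dissimilarities. The merged
cluster always lands on the lower row index, making a cluster's
representative its smallest original member; ties in the minimum merge
distance break on the lowest (left, right) representative pair. Dendrograms
are therefore deterministic and reproducible, but *not* bit-identical to
other implementations' internal orderings — cut-level label agreement on
separated data is the contract, and an independent naive agglomeration
oracle plus a scipy cross-check enforce it in tests.

### Stability indices and model selection

Stability uses the delete-one-column protocol: each feature column is
removed in turn, the data reclustered, and the partition compared with the
full-data clustering.

- **APN** — average proportion of an observation's full-data cluster it no
  longer co-occupies after deletion (0 = perfectly stable);
- **AD** — average distance (in the chosen metric, on full data) between the
  observation's full-data cluster and its deleted-column cluster;
- **ADM** — average Euclidean distance between those clusters' full-data
  centroids;
- **FOM** — root mean intra-cluster variance of the removed column under the
  deleted-column clustering, with the √(n/(n−k)) adjustment.

Lower is more stable throughout. `model_select` scores every
(distance, linkage, k) combination, extracts the argmin setting of each of
the four indices (ties resolved toward more clusters with > 5 donors, then
smaller k), and chooses among those candidates by rank-sum of the four
indices, with the same tie-breaks. The two-stage design is deliberate: AD
and FOM decrease almost monotonically in k, so a single rank-sum over the
whole grid drifts to the largest k on any data; extracting per-index optima
first lets the non-overlap indices veto unstable over-splits, and replaces
the inherently manual "the primary mutated genes should be clear" judgment
with a deterministic rule.

The planted-cluster validation fixture
(`simulate.planted_cluster_profiles`) deserves a note: blocks share
disjoint always-mutated signature genes, and noise is laid along a seeded
cycle alternating blocks so that every donor carries exactly two noise
genes, each shared with one donor of *another* block. This guarantees the
blocks have no internal substructure and no outliers — important because a
stability criterion will, correctly, prefer an over-split that reflects
genuine substructure, and naive random-noise fixtures create such
substructure by accident.

Minkowski distance defaults to exponent p = 2 (duplicating Euclidean, as in
the common dialect); Canberra treats 0/0 terms as zero contributions.

### Therapy annotation

A pure, user-editable lookup from cluster driver tags to recommendations:
all-wild-type → anti-EGFR antibodies (no contraindicating RAS-pathway
mutation), RAS → chemotherapy + Bevacizumab, driver-defined clusters →
matched targeted combinations, hypermutated → immune checkpoint blockade.
Unmapped clusters yield `unclassified` with a warning.

## Clinical association and power

The two-tailed Fisher exact p value follows probability-mass ordering: with
margins fixed, it sums the hypergeometric probability of every table at most
as probable as the observed one, with a relative tolerance of 1e-7 on the
probability comparison (two-tailed conventions differ across software; this
is the common statistical-package one, and it is verified against exhaustive
integer-arithmetic enumeration for every table with total ≤ 30). The odds
ratio is the sample value ad/bc (±∞ on zero cells); a zero margin returns
p = 1 with an undefined odds ratio.

Seven ordinal variables are dichotomized into less/more aggressive levels:
lymphatic and vascular invasion (absence | presence), grade (G1/G2 | G3),
T (T1/T2 | T3/T4), N (N0 | N1/N2), M (M0 | M1), stage (I/II | III/IV);
sex, site and side are tested as given. Each cluster is compared against the
donors of all other clusters (so the hypermutated group is tested against
all non-hypermutated donors and vice versa).

**Power** is simulated conditional on fixed group sizes: the two row totals
are scaled to the target n, outcomes drawn binomially at each group's
observed cell probability, and power is the fraction of simulated tables
with p < α; the Monte-Carlo standard error is reported. This conditioning is
the scheme that keeps "the same cell percentages" as the observed table.
**Minimum sample size** scans n = 20…500 in steps of 10 with 1000
simulations per step and returns the first n reaching the 0.8 target (or
"not reached"). Fisher's test is conservative, so simulated null power sits
at or below α — the calibration test bounds it within Monte-Carlo error of α
from below.

Gene-level association crosses mutated/wild-type with each dichotomized
variable; genes significant anywhere (raw p < 0.05) enter a natural-log
odds-ratio matrix in which ±∞ — and only ±∞ — is replaced by the
pseudonumbers ±4; the matrix is clustered with Euclidean distance and
ward.D. **No multiple-testing correction is applied by default**, matching
the reference analysis style; `benjamini_hochberg` exists but is opt-in and
changes the analysis.

Pathway summaries count each donor once per pathway regardless of how many
member genes are altered (alteration = non-silent variant or CNV call beyond
the gain/loss thresholds); cohorts are compared per pathway by 2×2 Fisher.

## Survival

PFS runs from diagnosis of metastatic disease to progression, right-censored
at last follow-up (censoring handling is a documented assumption — the
standard one — as the source description stops at the endpoint definition).
The Stage-IV chain is: donors on anti-EGFR therapy → drop surgical
resections (PFS set) → drop donors progressing before the first response
assessment (waterfall set); the Kaplan–Meier set starts from the PFS set and
drops donors who are the only member of their cluster. A donor failing
several criteria is excluded once, under the first matching reason, and
every step lands in the trace.

Kaplan–Meier estimation and the log-rank test delegate to lifelines
(product-limit estimator; asymptotic chi-square with groups − 1 degrees of
freedom). A label-permutation log-rank variant exists for very small groups.
Waterfall data is a pure sort (descending best response, ties stable by
donor id); RECIST measurement itself is out of scope — response percentages
are inputs.

## Synthetic cohort generator

Defaults are the study conditions: 200 donors, 8% hypermutated, background
5 mut/Mb vs hypermutated 30 mut/Mb on a 1.6 Mb footprint. Per-donor SNV
counts are Poisson(rate × footprint); each SNV's channel is drawn from the
donor group's signature mixture (normal donors lean on the clock/flat
components, hypermutated on MMR/POLE-like), reported on a random strand to
exercise pyrimidine folding; genes are drawn ∝ driver-weighted propensities
(30 named CRC drivers over 400 background genes); ~8% of calls are indels.
Somatic allele fractions follow a Beta centered near 0.3 (purity ~0.6);
germline contamination (Poisson, default 2 calls/donor) carries het-like
AFs near 0.5 and population frequencies above 1%, giving the filter real
work. Planted cluster profiles deterministically add their genes to member
donors and shift clinical odds and PFS hazards; clinical covariates are
generated with TNM/stage consistency (stage derived from M, then N, then T);
survival is exponential with hazard = ln 2/300 days × the cluster
multiplier, censored uniformly on 200–1200 days.

Determinism: every donor draws from substreams keyed by (seed, donor index,
stream tag), so enlarging a cohort never perturbs earlier donors and fixed
seeds reproduce byte-identical output.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: linkage between signatures and specific driver
genes, subclonal architecture and copy-number-driven allele-fraction
distortion, sequencing artifacts, panel capture nonuniformity, correlated
missingness in clinical records, and informative censoring. Tests against
this cohort validate the machinery and its statistical calibration, not
biological conclusions.

## Problem sizes

The test suite and acceptance script run everything at the sizes the study
design calls for where that is cheap (200-donor cohorts, 100 ROC replicates,
1000-simulation power and null-calibration runs, the full ≤ 30 Fisher
enumeration) and at reduced but structure-preserving sizes where the
computation is cubic (planted clustering fixtures of 24 donors; the demo
pipeline's stability grid restricted to Euclidean × {ward.D, average},
k ≤ 6). These sizes are part of the package's validation design and are
stated in the relevant drivers.

## Known limitations

- The germline/somatic allele-fraction model is intentionally minimal (two
  Beta components, no copy-number awareness); its claimed real-world
  discrimination cannot be validated without matched-normal truth data.
- The exact numeric hypermutation cutoff, the NMF rank, and the original
  cohort's gene lists are not recoverable from the source description; all
  are configurable rather than hard-coded.
- ward.D on raw dissimilarities and median/centroid linkage can produce
  height inversions (inherent to those dialects); heights are monotone for
  ward.D2, single, complete and average.
- Fisher power at small n inherits the test's conservatism; predicted
  minimum sample sizes are anchored to a normal-approximation oracle only
  within one grid step.
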