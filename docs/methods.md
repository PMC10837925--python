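# Methods

## Scope and model

`oligoburden` tests an oligogenic-inheritance hypothesis on a curated
disease-gene panel in a case-control design. The unit of observation is the
*carrier*: a sample holding at least one qualifying heterozygous variant in
a gene, gene pair, or gene set. Four analyses share this primitive:

1. **Per-gene burden** — one 2×2 carrier table per panel gene, exact-tested;
   genes ranked by ascending P, quantile = rank / panel size.
2. **Multi-variant carrier enrichment** — cases vs controls carrying ≥ 2
   qualifying variants anywhere in the panel.
3. **Digenic combinations** — every unordered gene pair co-carried by at
   least one case, tested as co-carrier vs non-co-carrier.
4. **Gene-set burden** — samples carrying ≥ 2 qualifying variants within
   one biological-function category of the panel.

Phenotype association (variant count vs onset age and FSH) is analysed
separately with rank statistics.

## Qualifying-variant filters

A variant qualifies when all of the following hold, each comparison strict
(a boundary value fails):

| filter | threshold | applies to |
|---|---|---|
| read depth | > 20 reads | every variant (mandatory field) |
| allele frequency | < 0.05 in each reference population where observed | every variant |
| REVEL | > 0.5 | missense only |
| splice-site or scSNV score | > 0.6 | splice-class variants |

Design choices where the filter definition was genuinely open:

* **Missing frequencies pass.** A variant absent from all three reference
  populations is treated as rare — novel variants cannot be discarded for
  lack of a frequency.
* **Missing required scores fail.** A missense variant without a REVEL
  score is dropped: deleteriousness cannot be established.
* **Score scope.** REVEL is defined for missense substitutions only, so it
  gates that class alone; splice scores gate splice-class variants;
  non-splice loss-of-function (frameshift, stop gain/loss, start loss)
  qualifies on consequence alone, the standard qualifying-variant design.
* **Splice-score disjunction.** Either splice score above 0.6 suffices by
  default (`splice_scores_conjunctive=True` requires both); with two partly
  redundant predictors the disjunctive reading loses fewer true splice
  variants.
* Consequence strings are matched case-insensitively over a synonym table
  covering Sequence Ontology and ANNOVAR spellings; unrecognised strings
  classify as "other", which never qualifies.
* Carrier status is heterozygous-only by default; homozygous-alternate
  calls can be included with a flag and are logged either way.
* Multi-allelic VCF records are rejected rather than silently decomposed —
  carrier logic on unsplit records is ambiguous.

## Exact statistics

The two-sided Fisher exact P uses the **PMF-ordering** convention: over all
tables with the observed margins, sum the hypergeometric probabilities not
exceeding the observed table's probability, with a relative tie slack of
1e-7 against floating-point misordering (the convention scipy implements,
and the one that reproduces the zero-cell closed forms
C(93,k)/C(558,k) exactly). A doubling-the-smaller-tail variant is available
for comparison. All PMF arithmetic is in log-gamma space; the final P is
clipped to ≤ 1; degenerate margins return P = 1.

The odds ratio is the sample value ad/bc; confidence intervals are Woolf
logit intervals with z = 1.959964. Zero-cell contract: bc = 0 < ad gives
OR = +Inf; ad = 0 = bc gives OR = NaN; any zero cell gives CI = (NaN, +Inf).
Conditional-MLE intervals are out of scope. Burden-table ties are broken
deterministically (descending OR, then gene symbol) so ranks and quantiles
are reproducible; genes with no carriers anywhere are kept at P = 1 with
undefined OR so quantiles cover the full panel. Benjamini–Hochberg
adjustment is offered but off by default — the primary analyses report raw
per-gene P values.

Multi-variant counting is at the **variant level**: two qualifying variants
in one gene make a multi-variant carrier (one carried gene). A gene-level
alternative sits behind `count_genes=True`. The same convention applies
within gene-set categories. Digenic enumeration is case-driven: pairs seen
only in controls are skipped unless requested.

## Phenotype association

Defaults are nonparametric because FSH is right-skewed and variant counts
are small tied integers: Spearman correlation (average ranks; t
approximation for P, exhaustive permutation null when n ≤ 9) and the
two-sided Wilcoxon rank-sum test (exact null when combined n ≤ 20 and
tie-free, otherwise normal approximation with tie and continuity
corrections). Pearson and Welch-t variants are available by flag. Constant
input yields an undefined estimate with P = 1 rather than an error. The
group split is fixed at "one or no variants" vs "two or more".

## Synthetic cohorts

The generator simulates at the **carrier level**, not the allele level: the
analyses only ever see carrier status and counts, so genes are drawn as
Bernoulli carrier indicators. Per gene, the control probability q is
configured and the case probability solves the configured odds ratio on the
odds scale, p = OR·q / (1 − q + OR·q); OR ≠ 1 at q ∈ {0, 1} is rejected as
unsatisfiable. Planted digenic pairs are imposed exactly (accidental
co-carriage is first broken, then the configured number of co-carriers
set). Every carried gene receives ≥ 1 filter-passing variant record;
decoy variants constructed to fail exactly one filter family (shallow
depth, common frequency, benign missense, or non-qualifying class) are
added at a configurable rate and must vanish at qualification. Case
phenotypes follow FSH = 45 + 8·count + N(0, 15²) IU/L (floored just above
the 25 IU/L diagnostic threshold) and onset = 33 − 1.5·count + N(0, 4²)
years (clipped to 16–39.9); controls carry no phenotype values since the
severity analyses concern affected individuals. All randomness flows from
one integer seed; emitted files are byte-identical per seed.

Default generative conditions are the study-scale ones: 93 cases, 465
controls, a 191-gene panel in four categories, per-gene control carrier
probabilities of order 0.2–3%, elevated odds ratios (≈ 4.5–21) for a core
of fifteen genes, one planted digenic pair (RAD52+MSH6, 2 cases vs 0
controls), one decoy per sample on average.

**What the generator does not emulate:** linkage disequilibrium and
haplotype structure, population stratification, relatedness/pedigrees,
realistic allele-frequency spectra, annotation noise, or genes with
correlated carrier status. Passing tests therefore validate the statistical
machinery and its calibration under the assumed sampling model, not
robustness to those real-data complications.

### The reference fixture

`reference_fixture()` is *constructed, not sampled*: explicit per-sample
gene assignments (tables in the source) simultaneously realise the
reference per-gene carrier counts (e.g. RAD52 9/93 vs 8/465, MSH6 11/93 vs
13/465), 33 vs 38 multi-variant carriers, the case variant-count histogram
(15×2, 10×3, 7×4, 1×5), the category multicarrier counts (21/15, 0/0, 5/3,
5/2), and exactly two case co-carriers of RAD52+MSH6 with none in controls.
Filler genes carried by a single sample absorb the remaining variant load
without entering the significant set (a 1/93-vs-0 table has P ≈ 0.17).
The packaged 191-gene panel is a synthetic stand-in: fifteen real gene
symbols with field-standard category assignments plus synthetic filler
symbols. Every fixture variant passes all filters, so gene- and
variant-level counts coincide by construction.

## Numerical and validation choices

* The exact test is cross-checked in the suite against an independent
  exhaustive-enumeration oracle in exact rational arithmetic and against
  `scipy.stats.fisher_exact`; the implementation itself never calls either.
* Simulator calibration, as verified by the suite: under an all-null
  configuration, per-gene type-I error at α = 0.05 stays below 0.06 (the
  exact test is conservative at these carrier frequencies, empirically
  ≈ 0.02); a planted OR of 6 at control carrier probability 0.017 is
  recovered over 1,000 replicates with the **geometric mean** of finite
  per-replicate sample ORs within 10% — the arithmetic mean of an odds
  ratio is upward-biased and becomes infinite whenever a replicate draws a
  zero cell — and Woolf 95% intervals cover the true value in 93–97% of
  replicates (zero-cell replicates count as non-covering).
* Heavy simulations in the suite use in-memory cohorts with decoys and
  second variants disabled and, for single-gene recovery, a one-gene panel;
  these sizes (15 null cohorts of 558 × 191; 1,000 single-gene replicates)
  were chosen as the smallest that make the calibration bounds sharp.
* Float INFO fields read back from VCF are renormalised to 6 significant
  digits (htslib stores them as float32); HGVS strings are percent-encoded
  in INFO because they contain spaces.

## Known limitations

* Only pairwise (order-2) combinations are enumerated; higher orders are
  reserved in the interface.
* No covariate adjustment, kernel/weighted association tests (SKAT-style),
  or genome-wide multiple-testing control — the design tests a fixed
  candidate panel with raw exact P values.
* Variant-combination pathogenicity scoring (VarCoPP/ORVAL-style
  classifiers) is out of scope; the package enumerates and tests
  combinations but does not score them.
* The phenotype model is linear with Gaussian noise; threshold or
  interaction effects are not simulated.
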