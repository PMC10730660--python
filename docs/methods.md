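# Methods

This note records the models, conventions and design choices behind
`pcdkit`, what the synthetic-data generator does and does not emulate, and
the package's known limitations.

## Prevalence model

The disorder is modelled as fully penetrant autosomal recessive under
random mating (Hardy–Weinberg). Three estimators of the affected-birth rate
are provided; they use different reductions of the same data and serve as
mutual cross-checks.

**Method 1 (Hardy–Weinberg).** Affected or suspected individuals are
excluded upstream, so every remaining carrier holds exactly one pathogenic
allele, and `q̂ = carriers / (2 n)`; the rate is `q̂²`. Excluding
genotype-identified patients makes `q̂` estimate the allele frequency
*conditional on not being affected*, `E[q̂] ≈ q·e^{−2q}` — a relative bias
of order `2q` (≈ −1.5% on `q`, −3% on the rate at a 1:66 carrier
frequency). This is inherent to the design, shared by all three methods,
far below the reporting precision of a prevalence ratio, and surfaced
honestly by the recovery harness (below).

**Method 2 (permutation–combination).** The sex-stratified product
`(C_m/n_m)(C_f/n_f)/4`. It is algebraically invariant to swapping the two
strata (property-tested), which also makes the estimate robust to the
ambiguous sex orientation of the source counts: published text and table
disagree about which stratum holds 7,333 individuals; the table orientation
(female 7,333 with 125 carriers, male 10,531 with 144) is adopted, and the
estimate is identical either way.

**Method 3 (Bayesian).** Beta–binomial conjugacy on `q`. Defaults:

* **Prior** — Jeffreys Beta(½, ½). The choice was frozen after verifying by
  closed form that `((AC + ½)/(AN + 1))⁻²` with AC = 269, AN = 35,728
  rounds to the published denominator 17,576; α and β remain configurable.
* **Point estimate** — the *square of the posterior mean* of `q`, not the
  posterior mean of `q²`; only the former reproduces the published value.
* **Interval** — Beta quantiles of `q` squared (a monotone transform needs
  no resampling). A seeded Monte-Carlo alternative (posterior draws,
  square, empirical quantiles) is available via `ci_method="montecarlo"`.
  The exact interval recipe behind the published bounds is not specified;
  the quantile construction lands within 0.4% of them (1:22,463–1:13,953
  vs 1:22,551–1:14,001), and the acceptance tolerance for this quantity is
  1% relative, not exactness.

**Averaging and rendering.** The combined estimate is the arithmetic mean
of the three rates. `1:N` denominators round half-up; the exact mean of the
three reference rates is 1:17,456.6, so 17,457 (nearest integer) and the
published truncated 17,456 are both accepted within ±1. All user-facing
rounding in the package (percentages, ratios) is conventional half-up, via
exact rational arithmetic where counts allow.

## Variant catalog and spectrum summaries

HGVS c. names are opaque identifiers after syntactic normalization
(whitespace stripped, spaces around intronic `+`/`−` offsets removed); no
grammar validation is attempted since names function purely as keys.
Spectrum percentages are `100·count/total` half-up to two decimals. The
shipped 128-variant example catalog reproduces the published category
totals, not real rows (those are restricted); one published count/percent
pair is internally inconsistent (74/128 printed as 58.59%, which is
75/128), and the catalog follows the percent (75 non-transmembrane / 53
transmembrane), treating the count as the typo. Similarly "91.40%" for
117/128 is truncation; half-up gives 91.41. Variants lacking a domain
annotation are reported under their own `unassigned` category.

## Allele-frequency comparison and association testing

2×2 tables use a chi-squared test with Yates continuity correction when
every expected cell is ≥ 5 and Fisher's exact test otherwise — the standard
reading of "chi-squared by default, Fisher when conditions are not met".
Zero-count cells (population-restricted founder variants) therefore route
to Fisher rather than being dropped. Screens are Benjamini–Hochberg
adjusted as a whole, and a direction (higher/lower) is assigned only below
the q-value threshold (default 0.05). Reference populations are pooled
(AC and AN summed) by default; per-reference testing is a flag.

Odds ratios are the conditional maximum-likelihood estimate from the exact
test (scipy's noncentral-hypergeometric root), not the sample cross-product
ratio, and no Haldane continuity correction is applied: a zero cell yields
exactly 0 or +∞, matching how such associations are conventionally
reported. The test suite verifies both the Fisher p and the conditional-MLE
OR against hand-written brute-force oracles (full hypergeometric
enumeration; likelihood-grid scan) over *all* 2×2 tables with total ≤ 40.

Group C0 comparisons use the two-sided Wilcoxon rank-sum test, exact for
small tie-free samples, normal approximation otherwise; groups smaller than
2 report means with an undefined p.

The default phenotype vocabulary is a ten-term config list
(cardiomyopathy, cardiac failure, hypoglycemia, hyperammonemia,
hepatomegaly, elevated ALT, fatigue, asymptomatic, growth retardation,
metabolic decompensation) and is user-extensible. Patients treated before
symptom onset can be excluded from association tables via a flag;
the default includes them, matching published denominators. Phenotype
frequencies report exact arithmetic (71/194 = 36.6% at one decimal) rather
than reproducing rounding quirks of source tables.

## Panel design and the two-tier screening algorithm

The panel is the top-k variants by cohort AF (ties lexicographic; top-k is
provably coverage-optimal and exhaustively verified for small catalogs).
"Covers ~90% of patients" is ambiguous, so three metrics are always
reported for panel mass fraction `c`: allele coverage `c`, ≥1-allele
patient coverage `1−(1−c)²`, and 2-allele coverage `c²`, under
independence of a patient's two alleles. The packaged default panel is the
ten published high-frequency sites.

First-tier decisions: normal C0 (≥ cutoff, default 10 µmol/L — a value
exactly at the cutoff follows the normal branch, since "below cutoff" is
the stated abnormal condition) with 2/1/0 panel alleles → suspected
patient / suspected carrier / negative; abnormal C0 with ≥2 panel alleles →
diagnosed patient (a newborn carries at most two alleles of one gene, so
"more than two" is read as "two or more"), otherwise retest. Second tier:
suspected carriers and retests with a below-cutoff second C0 escalate to
full gene analysis and resolve by their true allele count — the rescue path
for maternally masked patients; with a normal second C0 they resolve by
panel genotype; without a second measurement they are unresolved.

The 17-patient screening fixture is a synthetic reconstruction of the
reference cohort's narrative: 15 patients with abnormal initial C0 and two
panel alleles, 2 masked patients with normal initial C0, one panel allele
and an abnormal second-tier C0. Whether the masked patients carried one or
two panel-detectable alleles is unpublished; one is assigned (consistent
with their "suspected carrier" first-tier label), putting the rescue at
second tier.

## Synthetic cohort generator

**Genotypes.** Two alleles per variant per newborn, independent
Bernoulli(AF), independent across variants; status = patient (≥2 alleles),
carrier (1), negative (0). Default AFs: the three hotspot variants at their
published cohort frequencies (1/239, 1/1,275, 1/1,322), the remaining
seven panel sites sharing the rest so that Σ2·AF = 1/66 (the published
carrier frequency); the model-implied carrier probability is within 1.6%
of 1/66 (the difference is the `e^{−2q}` multiplicity correction).
AFs are validated to (0, 0.05) — the disease-allele regime; the
Hardy–Weinberg conformance tests therefore run at AF 0.04–0.045, where the
χ² goodness-of-fit approximation is also sound.

**C0 model.** Lognormal per class (C0 is positive, right-skewed), class
medians at the published subgroup means — patients 5.27, low-C0 carriers
6.47 µmol/L — and log-sd 0.25. The negative-class center (25 µmol/L) is
not published; it was chosen once, well above the cutoff, to make false
positives from noise negligible. Most carriers draw from the negative
distribution; a 10/72 fraction draws from the low-carrier one. Maternal
masking is a mixture: with probability 2/17 a patient's *initial* C0 is
drawn from the negative distribution (an additive maternal-carnitine term
would add parameters without changing the observable consequence — a
normal first screen). Second-tier C0 applies class drifts toward the
published second-tier means (patients ×4.28/5.27, low carriers ×9.01/6.47);
masked patients revert to the patient distribution, reflecting clearance of
the maternal supply. Post-treatment draws center on 20.21 (patients) and
18.61 (carriers) µmol/L.

These published anchors are means over small selected subgroups (n = 9–17),
so the generator reproduces qualitative structure and expectations, not
population distributions: passing tests demonstrate internal consistency of
the pipeline, not fidelity to unpublished real-world C0 variation,
covariate structure (gestational age, feeding), secondary carnitine
deficiency, or maternal-PCD false positives.

**Determinism.** Every draw flows from one `numpy` Generator; the pipeline
splits a single top-level seed per stage via `SeedSequence.spawn`. Fixed
seeds reproduce cohorts bit-identically (tested on output TSV bytes).

## Recovery harness and known limitations

`end_to_end_recovery` simulates replicate cohorts, excludes
genotype-identified patients (as the study design does), runs all three
estimators and reports per-method means, Monte-Carlo standard errors,
relative bias against the nominal `(Σ AF)²`, and empirical credible-interval
coverage. At n = 10⁵ and carrier frequency 1/66 over 500 replicates the
interval coverage is 0.952, but all three methods carry the systematic
≈ −2.1% patient-exclusion bias described above — roughly ten 3-SE-of-the-
mean bands at that replicate count. The corresponding acceptance test
asserts the strict within-3-SE band and is expected to fail on that
sub-check; the harness reports the decomposition rather than redefining the
target, because the bias is a property of the estimation procedure itself,
not of the implementation.

Test and simulation problem sizes (500 recovery replicates at n = 10⁵,
oracle sweeps to table total 40, 120–150 generator seeds for uniformity
checks) were chosen to keep the full suite in a few minutes on one CPU
while leaving Monte-Carlo error well below the asserted bands.

Out of scope by design: penetrance and consanguinity corrections, X-linked
or dominant inheritance, ACMG evidence assignment, transcript/protein
mapping of variants, acylcarnitine analytes beyond C0, longitudinal
outcomes, and cost-effectiveness modelling.
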