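# Methods

## Problem setting

Glucose-6-phosphate dehydrogenase (G6PD) deficiency is an X-linked
enzymopathy. In Chinese newborn screening (NBS), screen-positive infants
are recalled for confirmatory testing with two approved assays:

* **Enzymatic testing** — the G6PD/6PGD activity ratio; a ratio strictly
  below a cutoff (1.0 for the approved kit) is called deficient.
* **Targeted genotyping** — a 12-variant panel of common Chinese *G6PD*
  variants; variants outside the panel are invisible to it.

Because heterozygous females with normal measured activity are still at
risk of oxidative hemolysis, the diagnostic goal is to identify *every*
infant carrying a pathogenic variant, not only the enzymatically
deficient ones. Sanger sequencing of the *G6PD* coding exons serves as
the gold standard for panel-negative infants; the panel is treated as
fully concordant with sequencing on its 12 targets, so panel-positive
infants are carriers without further sequencing. Carrier truth is
therefore: panel-positive OR sequencing-positive; it is undefined (and
the package fails fast) for panel-negative infants who were never
sequenced.

## Reference cohort

The packaged 555-record reference cohort (437 males, 118 females) is a
deterministic expansion of published stratum counts; the nine
panel-negative, sequencing-positive infants carry their individually
reported activity ratios, variants and ages. Strata without per-record
ratios get representative values (0.30 deficient, 1.30 normal); only
the side of the cutoff, never the value itself, enters any downstream
computation, so the choice is inert. The 94 panel-positive females are
stored as heterozygous: the heterozygous/homozygous split is not
published, and zygosity does not affect any performance or cost figure.
Record ids are `{sex letter}{stratum}-{index}` so repeated expansion is
byte-identical.

## Diagnostic performance

Confusion matrices are tallied per sex and assay against resolved
carrier truth; sensitivity, specificity, PPV and NPV are kept as exact
integer fractions and rounded **half-up to one decimal** only at
presentation (this reproduces published roundings such as 16/23 →
69.6 and 22/58 → 37.9; banker's rounding would not). Metrics with a
zero denominator are flagged not-available rather than raised.

## Strategy engine

A strategy is an ordered list of stages; each stage administers one
test to the sub-population matching a filter over sex and
earlier-stage results. The diagnosis rule is "any administered test
positive, and the infant is a true carrier"; the sensitivity
denominator is all carriers in the cohort regardless of which branch
reached them. Strategies are validated structurally: a filter may only
constrain results of tests administered by an earlier stage, and no
infant may receive the same test twice. Custom strategies can be
supplied as YAML; the five built-ins are the isolated and reflex
combinations in routine use (activity only; panel only; activity then
panel for activity-normal females; panel then activity for
panel-negative infants; both for everyone).

## Cost model

Costs are per administered test and strategy-independent: the defaults
are the median self-pay charges of USD 3 (activity) and USD 50
(genotyping); total cost is the priced sum of test counts and cost per
diagnosed case divides by diagnosed carriers (half-up to 2 decimals at
presentation; CNY conversion at 6.8 is display-only). One published
cell is internally inconsistent: for the reflex-to-genotyping strategy
the source tabulation prints a total of 4,623 USD and 8.60 USD per
case, but the stated prices and test counts give 555·3 + 58·50 =
4,565 USD and 4,565/516 = 8.85 USD per case (and 4,623/516 ≈ 8.96, so
the printed pair is also inconsistent with itself). This package
reports the arithmetic-consistent values and the acceptance script
logs the discrepancy.

## Synthetic cohort model

The generator draws an NBS-positive cohort record by record:

1. Sex — Bernoulli(female_fraction), default 118/555.
2. Carrier status — a single contamination parameter (default 38/555)
   models screening false positives; the first-tier spot test is not
   simulated explicitly because its operating characteristics are
   unknown.
3. Genotype class — male carriers are hemizygous; female carriers are
   homozygous vs heterozygous with odds q : 2(1 − q), q defaulting to
   0.0139 (a reported city-level prevalence).
4. Variant — out-of-panel with probability 9/517, otherwise one of the
   12 panel variants by weight (uniform default). Variant severity is
   collapsed to two classes: a default deficient class (log-normal,
   median 0.35, σ = 0.55 — broad, reflecting the wide spread of
   deficient ratios) and a mild class (c.1024C>T; log-normal, median
   0.90, σ = 0.15) emulating the near-cutoff cluster of that variant.
   Per-variant distributions beyond these two classes are not
   published, so the class parameters are invented defaults.
5. Activity — hemizygotes/homozygotes draw from their variant's
   deficient-class distribution; non-carriers from the normal class
   (log-normal, median 1.35, σ = 0.25); heterozygotes draw
   m·A_def + (1 − m)·A_norm with the X-inactivation (Lyonization)
   fraction m ~ Beta(a, a), the standard symmetric-mosaicism
   abstraction for a trait described only qualitatively as "highly
   variable".

Two ascertainment constraints mirror how such cohorts arise and make
the structural invariants exact rather than approximate:

* Non-carriers (screening false positives) have confirmatory ratios at
  or above the cutoff — the confirmatory assays have no false-positive
  mechanism, so specificity and PPV are exactly 100% on generated
  cohorts.
* Out-of-panel carriers are activity-deficient (their variants are only
  ever discovered via a deficient ratio followed by sequencing), drawn
  by right-truncation or rejection sampling below the cutoff. Every
  carrier is then detectable by at least one assay, so the
  panel-then-activity reflex and dual-testing strategies reach 100%
  sensitivity on every generated cohort, and the activity-first reflex
  strategy misses exactly the activity-normal male carriers.

The Beta shape default a = 1.938 is fixed by solving the analytic
heterozygote deficiency probability (below) equal to 0.625, the
heterozygote detection fraction of enzymatic testing in the reference
cohort.

### Analytic oracles

`het_deficiency_prob` computes P(m·A_def + (1 − m)·A_norm < cutoff) by
probability-integral transforms of both the Beta and the deficient
log-normal onto the unit square, followed by 240-point Gauss–Legendre
quadrature in each dimension; `m` is clipped to [1e−13, 1 − 1e−13] to
avoid division by zero at the Beta endpoints. A non-positive cutoff
returns 0 exactly. The integral is cross-checked against large-n Monte
Carlo in the test suite.

`class_probabilities` gives the exact joint distribution of
(sex, carrier, panel-positive, deficient) cells under the model, using
the class log-normal CDFs and the heterozygote integral.
`expected_strategy_outcome` pushes these cells symbolically through a
strategy's stages, yielding Monte-Carlo-free expected test counts and
diagnoses; the cost sensitivity analysis uses these expectations, so
reported costs are smooth (and provably monotone where expected) in
female fraction and prices.

`recover_parameters` returns method-of-moments estimates of the
contamination and out-of-panel fractions. The allele frequency q is
not identifiable from an NBS-positive cohort alone — screening
conditions away the unaffected majority — and is reported as None.

### What the generator does and does not emulate

It reproduces the *structure* the analysis relies on (X-linked genotype
classes, mosaic heterozygote activity, a mild near-cutoff variant
class, panel-invisible variants, screening false positives) but not
measured per-variant activity distributions, allele counts,
assay measurement error, or repeat-testing variability within an
infant. Passing generator-based tests therefore validates the
pipeline's logic and the model's internal consistency, not the
real-world accuracy of the invented activity distributions.

## Problem sizes and numerical conventions

Monte-Carlo versus analytic comparisons run at n = 50,000 with fixed
seeds and 3-binomial-SE tolerances; property tests on the strategy
engine use exhaustively enumerable cohorts of at most 20 records.
All percentage rounding is half-up (one decimal for rates, two for
per-case costs); metric and cost computations are exact until
presentation.

## Known limitations

* Activity-class parameters are plausible inventions, not estimates.
* Two severity classes cannot express variant-specific spreads.
* The cutoff is configurable but no alternative value is endorsed.
* Recall timing, second-sample logistics and assay chemistry are out of
  scope; the cost model prices testing only (no discounting or QALYs).
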