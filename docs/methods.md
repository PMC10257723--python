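# Methods

## Model and procedure

The scan targets rare recessive-lethal alleles through their demographic
footprint: homozygous carriers are lost before they can be sampled, so a
variant's observed homozygote count O falls below the Hardy-Weinberg
expectation computed from its (mostly heterozygous) carriers.

Per population *i*, the alternate-allele frequency is estimated from phased
haplotypes, p̂ᵢ = (carrier haplotypes) / (2nᵢ); because the scan targets
rare alleles this estimate is driven by non-carriers and heterozygotes and
is nearly unaffected by the missing homozygotes themselves. The combined
expectation is λ = Σᵢ nᵢ p̂ᵢ², summing over populations so that
between-population frequency differences do not masquerade as deficits.
A variant is *tested* when λ > 0.5 and has a *strong deficit* when
O ≤ 0.1·λ. For rare variants O is approximately Poisson(λ), giving the
one-sided deviation p-value P(X ≤ O) and Bonferroni thresholds
(0.05 / number of tested units per class).

Assumptions worth stating: random mating within each population (violations
inflate homozygosity, i.e. bias *against* deficit calls — conservative for
detection, but the reason the FDR is calibrated empirically rather than
taken from the Poisson model); phased, hard genotype calls; autosomal
biallelic units; linkage equilibrium between tested units (cross-class
linkage is handled by the r² filter below).

### Empirical FDR

Intergenic variants carry the lowest predicted functional impact, so their
strong-deficit fraction within a λ bin estimates the chance (plus artifact)
rate. Bins are fixed half-open intervals
[0.5,1), [1,2), [2,3), [3,5), [5,8), [8,13), [13,250), [250,∞);
FDR = f_intergenic / f_pav per bin and PPV = 1 − FDR. An FDR above 1 is
reported uncapped in machine output (a capped value is provided for
display) so that PPV remains its exact complement. Empty class-bins are
flagged unavailable, never treated as zero.

The FDR confidence interval treats the two deficit counts as independent
Poisson rates. The published description cites an ad-hoc approximate
interval whose formula is not reproduced; this package instead conditions
on the total count (given x₁+x₂, x₁ is binomial) and maps an exact
Clopper-Pearson interval for the binomial proportion through
θ/(1−θ)·(n₂/n₁) — the same estimand, with exactly testable coverage. The
method name is recorded in the output metadata (`ci_method`).

### Class hygiene

Linked selection can drag neutral variants into a deficit. Variants are
therefore pruned across the impact hierarchy pLOF > moderate > low >
intergenic: a variant is removed from its class when its pooled-haplotype
r² with any variant of a strictly higher class exceeds 0.8; pLOF variants
are never removed. r² is computed on haplotypes pooled across populations —
the filter is hygiene, not inference, and stratifying it would only thin
the evidence for linkage. Intergenic calibration sets are additionally
definable by minimum distance to annotated genes (5, 50, 100, 250,
500 kb; 5 kb is the default used for calibration).

### geneLOF collapsing

Qualifying pLOFs (high-confidence calls, MAF < 2%, not on the curated
exclusion list) are collapsed per gene into a 0/1/2 genotype counting the
individual's haplotypes that carry at least one qualifying variant; 2 is a
knockout, including compound heterozygotes. The MAF filter is applied per
population at collapsing time — the 2% bound exists because founder
populations carry pathogenic alleles at elevated frequencies, which is a
per-population phenomenon (`per_population=False` switches to pooled
frequencies). Missing genotypes count as unaffected haplotypes, which is
conservative for deficit detection. The collapsed unit then enters the
same λ/O machinery with the carrier-haplotype frequency in the role of p̂.

### Downstream inference

Gene-set over-representation among deficit genes uses 2×2 tables (strong
deficit × set membership) within λ strata [1,5) and [5,∞), tested with the
two-sided Fisher exact test; the two-sided p sums conditional table
probabilities no larger than the observed one, and the effect size is the
conditional-MLE odds ratio (the ψ solving E_ψ[a | margins] = a) with its
exact tail-inversion CI. scipy supplies both; the test suite checks them
against full enumeration of the hypergeometric support on every table with
margins ≤ 12.

Carrier couples (both partners heterozygous geneLOF carriers of the same
gene) have a 1/4 chance per pregnancy of a homozygous conception, so
in-utero lethality predicts excess miscarriage in exactly this group and
not among single-carrier couples. Cases are compared against non-carrier
couples matched 1:100 by nearest neighbour on (maternal birth year, number
of pregnancies), both standardized by the pool standard deviation —
the matching metric is not pinned down by the published description, so it
is documented here and configurable. Matching is with replacement and
deterministic (ties break on couple id). Both an ever-miscarriage test and
a pooled per-pregnancy test are provided; per-gene significance is
Bonferroni-corrected for the number of genes tested.

## Synthetic cohorts: what they emulate, and what not

The generator reproduces the statistical structure the scan consumes:

* **Per-population frequencies** — each variant has its own frequency per
  population (0 allowed: absent).
* **Inbreeding** — with probability fᵢ an individual's second haplotype is
  a whole-genome copy of the first, which yields the marginal law
  P(hom) = p² + fᵢ·p(1−p) exactly while keeping a phased representation.
  Across individuals fᵢ ~ Beta with configured mean m and variance
  ρ·m(1−m) (dispersion ρ = 0 gives a point mass; the distribution across
  individuals is a modelling choice, not an estimate — nothing in the scan
  depends on its shape, only on the marginal homozygosity law).
* **Recessive selection** — each homozygote of a variant with survival
  fraction s survives independently with probability s; removed
  individuals are replaced by a genotype redrawn conditional on not being
  homozygous, keeping population sizes fixed and carrier-haplotype
  frequencies approximately preserved (the perturbation is second order
  for rare variants).
* **Gene structure** — non-intergenic variants map deterministically to
  genes for collapsing; coordinates are laid out on a synthetic genome
  (genes as disjoint intervals on chr1, intergenic variants on a gene-free
  chr2) so VCF/BED round trips and distance classification are exercised.
* **Couple histories** — couples are disjoint pairs from one population;
  a double-carrier pregnancy miscarries with probability
  m₀ + (1−m₀)·(1/4)·π (π = probability a homozygous conception is lost),
  all others with the background rate m₀. Defaults: pregnancies ~
  Poisson(3), background rate m₀ = 0.1, maternal birth years uniform
  1935–1975, background infant (< 2 y) death rate 1% — the scale of a
  founder-population pregnancy-history questionnaire cohort.

Not modelled, deliberately: segmental IBD (the scan only uses marginal
frequencies), recombination and demographic history, imputation
uncertainty (hard calls only; a dosage column is accepted but not
required), sequence context. Passing tests therefore validate the
statistical machinery, not robustness to imputation artifacts or cryptic
relatedness in real cohorts — in real data those are exactly what the
empirical FDR calibration is for.

By default variants are simulated in linkage equilibrium; correlated pairs
for exercising the r² exclusion are constructed explicitly in the tests.

## Numerical choices

* Strong deficit is inclusive (O ≤ 0.1λ): the headline "10% or less"
  definition governs; the strict form differs only on measure-zero
  boundaries.
* Variants with pooled alternate frequency above 0.5 are excluded from
  deficit testing with a warning — the scan targets rare alternate
  alleles, and "MAF" here means the alternate-allele frequency when ≤ 0.5.
* r² is defined 0 for monomorphic variants.
* Bin and stratum intervals are half-open [lo, hi) exactly as printed.
* The two-proportion power analysis uses the classical pooled-variance
  normal approximation (identical to R's `power.prop.test`); sample-size
  inversion is by monotone bracketing (`brentq`). In the extreme
  rare-variant regime (expected counts of order 1) the approximation
  understates the simulated rejection rate by a few percent; the tests
  document it as a conservative lower bound there.
* The per-individual inbreeding estimator is method-of-moments,
  f̂ᵢ = 1 − (observed hets)/(Σ 2p̂q̂), against the individual's own
  population frequencies; it needs on the order of 100+ polymorphic
  variants to be stable and errors out with none.
* All randomness flows from a single seed through `numpy` `SeedSequence`
  spawning; identical configuration and seed give byte-identical output.

## Validation scenarios and problem sizes

The calibration suite (tests and `scripts/acceptance.py`) runs on fixed
scenarios from `homdeficit.scenarios`:

* **HWE null** — 2 populations × 100,000 individuals, 2000 neutral
  variants (intergenic and pLOF on an identical λ grid: 700 per class with
  λ ∈ [0.6, 5), 300 per class with λ ∈ [20, 100]). Checks: mean O/λ within
  [0.97, 1.03] for λ ≥ 20; FDR estimate within [0.7, 1.3].
* **Planted lethals** — 200,000 individuals; 50 pLOFs with s = 0 at
  λ ∈ [5, 12.5] among 150 neutral pLOFs and 800 intergenic variants on the
  same grid. Checks: sensitivity ≥ 0.95; empirical FDR at λ ≥ 5 below 0.2.
* **Inbreeding recovery** — 50,000 individuals, 300 variants with
  frequencies 0.05–0.3; configured f ∈ {0, 0.0625} recovered within ±0.01.
* **Rate-ratio coverage** — 2000 Poisson replicates at true ratio 0.5
  (means 20 and 40); empirical 95% coverage within [0.92, 0.99].
* **Carrier couples** — 30,000 individuals paired into 15,000 couples with
  a 6% lethal carrier allele, yielding ≈140–190 double-carrier couples per
  replicate; 140 cases are tested against 1:100 matched controls. Checks:
  power ≥ 0.8 over 20 replicates at π = 1, m₀ = 0.1; single-carrier
  couples show no excess; π = 0 retains the null in ≥ 90% of replicates.

These sizes put each check in the statistical regime it is about (λ bins
populated, ≈140 case couples, 3+ standard errors of headroom on each
asserted band) while staying workstation-friendly: the full suite runs in
about a minute.

## Known limitations

* The empirical FDR needs well-populated intergenic bins; with few
  intergenic variants the CI is wide and the estimate unstable (flagged
  unavailable when empty, but small-count bins deserve skepticism).
* Selection replacement redraws genotypes conditional on non-homozygosity
  with f = 0; for strongly inbred simulated populations the replacement
  genotype distribution is therefore slightly too heterozygous. The effect
  is second order in p and does not touch the scan itself.
* The couples generator draws pregnancy counts independently of carrier
  status; real reproductive compensation (more pregnancies after a loss)
  is not modelled and would bias per-pregnancy comparisons in real data.
* `read_panel` holds one population's parsed VCF in memory at a time;
  cohorts of hundreds of thousands of samples are expected to arrive
  through the simulator API rather than as text VCFs.
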