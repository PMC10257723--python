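"""Standard validation scenarios.

Each function builds a :class:`~homdeficit.simulate.SimulationConfig` (or a
full simulated dataset) for one of the package's calibration checks. The
problem sizes are the package's validation conditions, chosen to mirror the
statistical regime the scan targets — cohorts of 10^5 individuals, rare
alleles with expected homozygote counts spanning the calibration bins — at
a scale a single workstation handles:

* HWE null: 2 populations x 100,000 individuals, 2000 neutral variants
  (half intergenic, half pLOF on an identical expected-count grid).
* Planted lethals: one population of 200,000 with 50 fully recessive-lethal
  pLOFs at expected counts >= 5 among neutral pLOF and intergenic variants.
* Inbreeding recovery: 50,000 individuals, 300 common variants.
* Carrier couples: 30,000 individuals / 15,000 couples with a 6% carrier
  allele, yielding on the order of 140 double-carrier couples.
"""

from __future__ import annotations

import math

import numpy as np

from .simulate import (CoupleHistoryConfig, PopulationSpec, PregnancyModel,
                       SimulationConfig, TrueVariantSpec)


def _freq_for_lambda(lam: float, pop_sizes: list[int]) -> float:
    """Shared per-population frequency p with sum_i n_i p**2 = lam."""
    return math.sqrt(lam / sum(pop_sizes))


def hwe_null_config(seed: int,
                    n_per_pop: int = 100_000,
                    n_low_per_class: int = 700,
                    n_high_per_class: int = 300) -> SimulationConfig:
    """Neutral two-population cohort under exact HWE (f = 0, s = 1).

    Intergenic and pLOF variants share an identical expected-count grid:
    ``n_low_per_class`` variants per class with lambda log-spaced in
    [0.6, 5) (where chance strong deficits live) and ``n_high_per_class``
    with lambda in [20, 100] (for the observed/expected calibration).
    """
    pops = [PopulationSpec("POP1", n_per_pop), PopulationSpec("POP2", n_per_pop)]
    sizes = [p.n_individuals for p in pops]
    lams = np.concatenate([
        np.geomspace(0.6, 4.99, n_low_per_class),
        np.geomspace(20.0, 100.0, n_high_per_class),
    ])
    variants = []
    for cls in ("intergenic", "plof"):
        for k, lam in enumerate(lams):
            p = _freq_for_lambda(float(lam), sizes)
            variants.append(TrueVariantSpec(
                variant_id=f"{cls}_{k:05d}",
                per_population_freq={"POP1": p, "POP2": p},
                impact_class=cls,
                gene=None if cls == "intergenic" else f"G{cls.upper()}{k:05d}",
                plof_confidence="high" if cls == "plof" else "not_applicable",
            ))
    return SimulationConfig(populations=pops, variants=variants,
                            gene_count=max(n_low_per_class + n_high_per_class, 1),
                            seed=seed)


def planted_lethal_config(seed: int,
                          n_individuals: int = 200_000,
                          n_lethal: int = 50,
                          n_neutral_plof: int = 150,
                          n_intergenic: int = 800) -> SimulationConfig:
    """One population with fully recessive-lethal pLOFs planted at lambda >= 5.

    The lethal variants (survival fraction 0) and the neutral pLOFs share
    the lambda range [5, 12.5]; intergenic variants cover the same range to
    calibrate the FDR in the bins at and above five expected homozygotes.
    """
    pops = [PopulationSpec("POP1", n_individuals)]
    sizes = [n_individuals]
    variants = []
    for k, lam in enumerate(np.geomspace(5.0, 12.5, n_lethal)):
        variants.append(TrueVariantSpec(
            variant_id=f"lethal_{k:04d}",
            per_population_freq={"POP1": _freq_for_lambda(float(lam), sizes)},
            impact_class="plof", gene=f"GLETH{k:04d}",
            plof_confidence="high", survival_fraction=0.0))
    for k, lam in enumerate(np.geomspace(5.0, 12.5, n_neutral_plof)):
        variants.append(TrueVariantSpec(
            variant_id=f"plofneu_{k:04d}",
            per_population_freq={"POP1": _freq_for_lambda(float(lam), sizes)},
            impact_class="plof", gene=f"GNEU{k:04d}", plof_confidence="high"))
    for k, lam in enumerate(np.geomspace(5.0, 12.5, n_intergenic)):
        variants.append(TrueVariantSpec(
            variant_id=f"inter_{k:04d}",
            per_population_freq={"POP1": _freq_for_lambda(float(lam), sizes)},
            impact_class="intergenic"))
    return SimulationConfig(populations=pops, variants=variants,
                            gene_count=n_lethal + n_neutral_plof, seed=seed)


def inbreeding_config(seed: int, f: float,
                      n_individuals: int = 50_000,
                      n_variants: int = 300) -> SimulationConfig:
    """Single population with constant inbreeding f and common neutral variants."""
    pops = [PopulationSpec("POP1", n_individuals, inbreeding_mean=f)]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF0)))
    freqs = rng.uniform(0.05, 0.3, size=n_variants)
    variants = [TrueVariantSpec(variant_id=f"common_{k:04d}",
                                per_population_freq={"POP1": float(p)},
                                impact_class="intergenic")
                for k, p in enumerate(freqs)]
    return SimulationConfig(populations=pops, variants=variants, seed=seed)


def couples_config(seed: int,
                   lethal_miscarriage_prob: float = 1.0,
                   background_rate: float = 0.1,
                   n_individuals: int = 30_000,
                   carrier_freq: float = 0.06) -> SimulationConfig:
    """Cohort for the carrier-couple miscarriage analysis.

    One gene carries a single recessive-lethal pLOF at ``carrier_freq``;
    pairing the population into couples yields about
    (2pq)^2 * n/2 ~ 140 double-carrier couples — the scale of a carrier-
    couple follow-up in a founder population. Pregnancy counts are
    Poisson(3), maternal birth years uniform over 1935-1975 and background
    per-pregnancy miscarriage risk 10%.
    """
    pops = [PopulationSpec("POP1", n_individuals)]
    variants = [TrueVariantSpec(
        variant_id="lethal_0001",
        per_population_freq={"POP1": carrier_freq},
        impact_class="plof", gene="GENE0001", plof_confidence="high",
        survival_fraction=0.0)]
    couples = CoupleHistoryConfig(
        n_couples=n_individuals // 2,
        pregnancies=PregnancyModel(mean=3.0, minimum=0),
        background_miscarriage_rate=background_rate,
        lethal_miscarriage_prob=lethal_miscarriage_prob)
    return SimulationConfig(populations=pops, variants=variants,
                            gene_count=1, seed=seed, couples=couples)
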