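"""Synthetic multi-population cohort generator.

Emulates the statistical structure the homozygosity-deficit scan assumes:
per-population allele frequencies, per-individual inbreeding (excess
homozygosity), impact-class structure, recessive-lethal variants with a
configurable survival fraction, gene structure for collapsing, and couple
reproductive histories — with ground-truth labels so every downstream stage
is testable without external data.

Inbreeding is modelled as a whole-genome haplotype copy: with probability
f_i, individual i's second haplotype is a copy of the first (identical by
descent), which reproduces the marginal law

    P(hom-alt) = f_i * p + (1 - f_i) * p**2 = p**2 + f_i * p * (1 - p)

exactly while preserving a phased representation. Segmental IBD is not
modelled: the scan only consumes marginal genotype/haplotype frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from .panel import CohortPanel, PopulationPanel

IMPACT_CLASSES = ("intergenic", "low", "moderate", "plof")
PLOF_CONFIDENCE = ("high", "low", "not_applicable")


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population.

    ``inbreeding_mean`` is the mean inbreeding coefficient f (probability
    that an individual's two alleles are identical by descent); across
    individuals f is drawn from a Beta distribution with that mean and
    variance ``inbreeding_dispersion * m * (1 - m)`` (dispersion 0 means
    every individual has f equal to the mean).
    """

    name: str
    n_individuals: int
    inbreeding_mean: float = 0.0
    inbreeding_dispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError(f"population {self.name!r}: n_individuals must be >= 1")
        if not 0.0 <= self.inbreeding_mean <= 1.0:
            raise ValueError("inbreeding_mean must lie in [0, 1]")
        if not 0.0 <= self.inbreeding_dispersion < 1.0:
            raise ValueError("inbreeding_dispersion must lie in [0, 1)")


@dataclass(frozen=True)
class TrueVariantSpec:
    """Ground truth for one simulated variant.

    ``survival_fraction`` s is the probability that a homozygous-alternate
    individual survives to be sampled: 1 is neutral, 0 a fully recessive
    lethal. Frequencies are per population and may be 0 (variant absent).
    """

    variant_id: str
    per_population_freq: dict = field(default_factory=dict)
    impact_class: str = "intergenic"
    gene: str | None = None
    plof_confidence: str = "not_applicable"
    survival_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.impact_class not in IMPACT_CLASSES:
            raise ValueError(f"unknown impact class {self.impact_class!r}")
        if self.plof_confidence not in PLOF_CONFIDENCE:
            raise ValueError(f"unknown plof confidence {self.plof_confidence!r}")
        if self.impact_class == "intergenic" and self.gene is not None:
            raise ValueError(
                f"intergenic variant {self.variant_id!r} must not have a gene"
            )
        if not 0.0 <= self.survival_fraction <= 1.0:
            raise ValueError("survival_fraction must lie in [0, 1]")
        for pop, p in self.per_population_freq.items():
            if not 0.0 <= p <= 0.5:
                raise ValueError(
                    f"variant {self.variant_id!r}: frequency {p} in population "
                    f"{pop!r} outside [0, 0.5]"
                )


@dataclass(frozen=True)
class PregnancyModel:
    """Distribution of pregnancy counts per couple: max(minimum, Poisson(mean))."""

    mean: float = 3.0
    minimum: int = 0

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        counts = rng.poisson(self.mean, size=size)
        return np.maximum(counts, self.minimum)


@dataclass(frozen=True)
class CoupleHistoryConfig:
    """Reproductive-history generator settings.

    For a pregnancy of a double-carrier couple (both parents heterozygous
    geneLOF carriers of a lethal gene) the conception is homozygous with
    probability 1/4 and, if homozygous, miscarries with probability
    ``lethal_miscarriage_prob``; so the per-pregnancy miscarriage rate is
    m0 + (1 - m0) * (1/4) * pi for double carriers and m0 otherwise.
    """

    n_couples: int
    pregnancies: PregnancyModel = PregnancyModel()
    background_miscarriage_rate: float = 0.1
    lethal_miscarriage_prob: float = 1.0
    infant_death_rate: float = 0.01
    birth_year_range: tuple[int, int] = (1935, 1975)

    def __post_init__(self) -> None:
        for name in ("background_miscarriage_rate", "lethal_miscarriage_prob",
                     "infant_death_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_couples < 1:
            raise ValueError("n_couples must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    populations: list[PopulationSpec] = field(default_factory=list)
    variants: list[TrueVariantSpec] = field(default_factory=list)
    gene_count: int = 1
    seed: int = 0
    couples: CoupleHistoryConfig | None = None

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("at least one population required")
        if self.gene_count < 1:
            raise ValueError("gene_count must be >= 1")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        vids = [v.variant_id for v in self.variants]
        if len(set(vids)) != len(vids):
            raise ValueError("duplicate variant ids")


def _draw_inbreeding(rng: np.random.Generator, spec: PopulationSpec) -> np.ndarray:
    m, d, n = spec.inbreeding_mean, spec.inbreeding_dispersion, spec.n_individuals
    if d == 0.0 or m in (0.0, 1.0):
        return np.full(n, m)
    conc = (1.0 - d) / d
    return rng.beta(m * conc, (1.0 - m) * conc, size=n)


def _sample_carriers(rng: np.random.Generator, candidates: np.ndarray,
                     p: float) -> np.ndarray:
    """Bernoulli(p) subset of ``candidates`` (binomial count + uniform subset)."""
    if p <= 0.0 or candidates.size == 0:
        return np.empty(0, dtype=np.intp)
    k = rng.binomial(candidates.size, p)
    if k == 0:
        return np.empty(0, dtype=np.intp)
    return candidates[rng.choice(candidates.size, size=k, replace=False)]


def simulate_haplotype_panel(config: SimulationConfig) -> CohortPanel:
    """Draw a phased multi-population panel under the configured model.

    Haplotype alleles at each variant are Bernoulli(p) draws; with
    probability f_i the individual's second haplotype is a whole-genome
    copy of the first. Deterministic given ``config.seed``.
    """
    seq = np.random.SeedSequence(config.seed)
    pop_seeds = seq.spawn(len(config.populations))
    variant_ids = np.array([v.variant_id for v in config.variants], dtype=object)
    m = len(variant_ids)

    populations = []
    for spec, child in zip(config.populations, pop_seeds):
        rng = np.random.default_rng(child)
        n = spec.n_individuals
        f = _draw_inbreeding(rng, spec)
        ibd = rng.random(n) < f
        non_ibd = np.flatnonzero(~ibd)
        all_idx = np.arange(n, dtype=np.intp)

        rows_a: list[np.ndarray] = []
        cols_a: list[np.ndarray] = []
        rows_b: list[np.ndarray] = []
        cols_b: list[np.ndarray] = []
        for j, vspec in enumerate(config.variants):
            p = float(vspec.per_population_freq.get(spec.name, 0.0))
            a = _sample_carriers(rng, all_idx, p)
            copied = a[ibd[a]] if a.size else a
            fresh = _sample_carriers(rng, non_ibd, p)
            b = np.concatenate([copied, fresh])
            if a.size:
                rows_a.append(a)
                cols_a.append(np.full(a.size, j, dtype=np.intp))
            if b.size:
                rows_b.append(b)
                cols_b.append(np.full(b.size, j, dtype=np.intp))

        def build(rows: list[np.ndarray], cols: list[np.ndarray]) -> sparse.csc_matrix:
            if rows:
                r = np.concatenate(rows)
                c = np.concatenate(cols)
                data = np.ones(r.size, dtype=np.uint8)
            else:
                r = c = np.empty(0, dtype=np.intp)
                data = np.empty(0, dtype=np.uint8)
            return sparse.csc_matrix((data, (r, c)), shape=(n, m), dtype=np.uint8)

        populations.append(
            PopulationPanel(name=spec.name, hap_a=build(rows_a, cols_a),
                            hap_b=build(rows_b, cols_b))
        )
    return CohortPanel(variant_ids=variant_ids, populations=populations)


def apply_recessive_selection(panel: CohortPanel,
                              specs: list[TrueVariantSpec],
                              seed: int) -> CohortPanel:
    """Remove homozygotes of variants with survival fraction below one.

    Each homozygous-alternate individual is independently retained with
    probability ``survival_fraction`` and otherwise replaced by a freshly
    drawn non-homozygous genotype at that variant (carrier haplotype
    frequencies approximately preserved, population sizes unchanged).
    """
    selected = {s.variant_id: s for s in specs if s.survival_fraction < 1.0}
    if not selected:
        return panel

    seq = np.random.SeedSequence(seed)
    pop_seeds = seq.spawn(len(panel.populations))
    new_pops = []
    for pop, child in zip(panel.populations, pop_seeds):
        rng = np.random.default_rng(child)
        hap_a = pop.hap_a.tolil(copy=True)
        hap_b = pop.hap_b.tolil(copy=True)
        for vid, vspec in selected.items():
            j = panel.variant_index(vid)
            a, b = pop.column_indices(j)
            hom = np.intersect1d(a, b, assume_unique=True)
            if hom.size == 0:
                continue
            s = vspec.survival_fraction
            removed = hom[rng.random(hom.size) >= s]
            if removed.size == 0:
                continue
            p = float(vspec.per_population_freq.get(pop.name, 0.0))
            # replacement genotype conditional on not homozygous-alternate
            norm = 1.0 - p * p
            pr_het = p * (1.0 - p) / norm  # each of the two het phases
            u = rng.random(removed.size)
            alt_on_a = u < pr_het
            alt_on_b = (u >= pr_het) & (u < 2 * pr_het)
            for i, on_a, on_b in zip(removed, alt_on_a, alt_on_b):
                hap_a[i, j] = 1 if on_a else 0
                hap_b[i, j] = 1 if on_b else 0
        new_pops.append(
            PopulationPanel(name=pop.name, hap_a=hap_a.tocsc(),
                            hap_b=hap_b.tocsc(),
                            individual_ids=pop.individual_ids,
                            missing=pop.missing)
        )
    return CohortPanel(variant_ids=panel.variant_ids, populations=new_pops)


def gene_names(gene_count: int) -> list[str]:
    return [f"GENE{i + 1:04d}" for i in range(gene_count)]


def assign_gene_structure(config: SimulationConfig) -> dict[str, str | None]:
    """Map every variant to a gene (intergenic variants map to None).

    Variants with an explicit gene keep it; other non-intergenic variants
    are assigned uniformly at random among ``gene_count`` genes,
    deterministically given the config seed.
    """
    genes = gene_names(config.gene_count)
    known = set(genes)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xE1)))
    mapping: dict[str, str | None] = {}
    for v in config.variants:
        if v.impact_class == "intergenic":
            mapping[v.variant_id] = None
        elif v.gene is not None:
            known.add(v.gene)
            mapping[v.variant_id] = v.gene
        else:
            mapping[v.variant_id] = genes[rng.integers(len(genes))]
    return mapping


def resolve_genes(config: SimulationConfig) -> list[TrueVariantSpec]:
    """Return variant specs with every non-intergenic gene filled in."""
    mapping = assign_gene_structure(config)
    return [replace(v, gene=mapping[v.variant_id]) for v in config.variants]


def simulate_couple_histories(panel: CohortPanel,
                              gene_map: dict[str, str | None],
                              cfg: CoupleHistoryConfig,
                              lethal_genes: list[str],
                              seed: int,
                              population: str | None = None) -> list:
    """Simulate pregnancy histories for couples drawn from one population.

    Couples are formed from distinct individuals of the population. A couple
    is a double carrier of a lethal gene when both partners are heterozygous
    geneLOF carriers (exactly one haplotype affected); each of its
    pregnancies miscarries with probability m0 + (1 - m0) * (1/4) * pi,
    all other couples' pregnancies with probability m0.
    """
    from .couples import CoupleRecord

    pop = panel.population(population) if population else panel.populations[0]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0)))
    n = pop.n_individuals
    n_couples = min(cfg.n_couples, n // 2)
    if n_couples < 1:
        raise ValueError("population too small to form couples")
    order = rng.permutation(n)
    mothers = order[:n_couples]
    fathers = order[n_couples: 2 * n_couples]

    # per-individual haplotypes-affected count for each lethal gene
    affected = {}
    for gene in lethal_genes:
        cols = np.array([panel.variant_index(v)
                         for v, g in gene_map.items() if g == gene], dtype=np.intp)
        affected[gene] = pop.haplotypes_affected(cols)

    m0 = cfg.background_miscarriage_rate
    pi = cfg.lethal_miscarriage_prob
    rate_dc = m0 + (1.0 - m0) * 0.25 * pi

    n_preg = cfg.pregnancies.draw(rng, n_couples)
    birth_years = rng.integers(cfg.birth_year_range[0], cfg.birth_year_range[1] + 1,
                               size=n_couples)

    records = []
    for k in range(n_couples):
        mi, fi = mothers[k], fathers[k]
        status = {}
        double = False
        for gene in lethal_genes:
            am, af = affected[gene][mi], affected[gene][fi]
            if am == 1 and af == 1:
                status[gene] = "both"
                double = True
            elif am >= 1 or af >= 1:
                status[gene] = "one"
            else:
                status[gene] = "neither"
        rate = rate_dc if double else m0
        preg = int(n_preg[k])
        misc = int(rng.binomial(preg, rate)) if preg else 0
        births = preg - misc
        deaths = int(rng.binomial(births, cfg.infant_death_rate)) if births else 0
        records.append(CoupleRecord(
            couple_id=f"{pop.name}_C{k:06d}",
            mother=str(pop.individual_ids[mi]),
            father=str(pop.individual_ids[fi]),
            carrier_status=status,
            n_pregnancies=preg,
            n_miscarriages=misc,
            birth_year=int(birth_years[k]),
            n_children_dead_before_2=deaths,
        ))
    return records
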