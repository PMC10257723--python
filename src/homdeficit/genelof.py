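"""Gene-level pLOF collapsing (geneLOF).

Rare (MAF < 2%) high-confidence predicted loss-of-function variants of a
gene are collapsed into a single biallelic genotype per individual counting
how many of the two haplotypes carry at least one qualifying pLOF. Two
different pLOFs on opposite haplotypes (a compound heterozygote) therefore
count as 2 — a knockout — which is what gives the gene-based test its power:
individually rare variants that would each fall below the testing threshold
jointly reach it.

The collapsed genotypes feed the same deficit machinery as single variants:
the carrier-haplotype frequency per population plays the role of the allele
frequency, lambda = sum_i n_i p_i**2, and O counts individuals with both
haplotypes affected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import CohortPanel
from .scan import MIN_LAMBDA, STRONG_RATIO

GENELOF_MAF_MAX = 0.02


def select_qualifying_plofs(annotations: pd.DataFrame,
                            panel: CohortPanel,
                            maf_max: float = GENELOF_MAF_MAX,
                            exclude_ids: set[str] | None = None,
                            per_population: bool = True
                            ) -> dict[str, dict[str, list[str]]]:
    """Qualifying pLOF variant ids per population and gene.

    A variant qualifies when its impact class is plof, its confidence flag
    is high (low-confidence calls are dropped), it is not on the curated
    exclusion list, and its alternate-allele frequency in the population
    being collapsed is below ``maf_max``. With ``per_population=False`` the
    frequency filter uses the pooled frequency instead, giving every
    population the same qualifying set.
    """
    exclude_ids = exclude_ids or set()
    ann = annotations[(annotations["impact_class"] == "plof")
                      & (annotations["plof_confidence"] == "high")
                      & (~annotations["variant_id"].isin(exclude_ids))
                      & (annotations["gene"].notna())]
    cols = np.array([panel.variant_index(v) for v in ann["variant_id"]],
                    dtype=np.intp)

    freqs: dict[str, np.ndarray] = {}
    if per_population:
        for pop in panel.populations:
            n = pop.genotyped_counts()[cols].astype(float)
            alt = pop.alt_haplotype_counts()[cols]
            with np.errstate(divide="ignore", invalid="ignore"):
                freqs[pop.name] = np.where(n > 0, alt / (2 * n), 0.0)
    else:
        alt_total = np.zeros(cols.size)
        n_total = np.zeros(cols.size)
        for pop in panel.populations:
            alt_total += pop.alt_haplotype_counts()[cols]
            n_total += pop.genotyped_counts()[cols]
        with np.errstate(divide="ignore", invalid="ignore"):
            pooled = np.where(n_total > 0, alt_total / (2 * n_total), 0.0)
        for pop in panel.populations:
            freqs[pop.name] = pooled

    out: dict[str, dict[str, list[str]]] = {}
    vids = ann["variant_id"].to_numpy()
    genes = ann["gene"].to_numpy()
    for pop in panel.populations:
        keep = freqs[pop.name] < maf_max
        per_gene: dict[str, list[str]] = {}
        for vid, gene in zip(vids[keep], genes[keep]):
            per_gene.setdefault(gene, []).append(vid)
        out[pop.name] = per_gene
    return out


def collapse_to_genelof(panel: CohortPanel,
                        qualifying: dict[str, dict[str, list[str]]]
                        ) -> dict[str, pd.DataFrame]:
    """Per-population geneLOF matrix: individuals x genes, values 0/1/2.

    The value is the number of the individual's two haplotypes carrying at
    least one qualifying pLOF of the gene; missing genotypes contribute
    nothing (a haplotype with only missing calls counts as unaffected).
    """
    out = {}
    for pop in panel.populations:
        per_gene = qualifying.get(pop.name, {})
        data = {}
        for gene in sorted(per_gene):
            cols = np.array([panel.variant_index(v) for v in per_gene[gene]],
                            dtype=np.intp)
            data[gene] = pop.haplotypes_affected(cols)
        out[pop.name] = pd.DataFrame(data, index=pop.individual_ids, dtype=np.uint8)
    return out


@dataclass
class KnockoutCatalogue:
    """Summary of complete (both-haplotype) geneLOF genotypes."""

    n_individuals_with_knockout: int
    knockouts_per_individual: pd.Series
    genes_knocked_out: set[str] = field(default_factory=set)
    genes_with_2_or_more_knockouts: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        per_count = self.knockouts_per_individual.value_counts().sort_index()
        return {
            "n_individuals_with_knockout": self.n_individuals_with_knockout,
            "n_genes_knocked_out": len(self.genes_knocked_out),
            "n_genes_with_2_or_more_knockouts": len(self.genes_with_2_or_more_knockouts),
            "individuals_by_knockout_count": {int(k): int(v)
                                              for k, v in per_count.items()},
            "genes_knocked_out": sorted(self.genes_knocked_out),
            "genes_with_2_or_more_knockouts": sorted(
                self.genes_with_2_or_more_knockouts),
        }


def build_knockout_catalogue(genelof: dict[str, pd.DataFrame]) -> KnockoutCatalogue:
    """Catalogue of individuals and genes with geneLOF = 2 across populations."""
    per_individual = []
    gene_ko_counts: dict[str, int] = {}
    for pop_name, frame in genelof.items():
        if frame.empty:
            continue
        ko = frame.to_numpy() == 2
        counts = ko.sum(axis=1)
        per_individual.append(pd.Series(counts, index=frame.index))
        for gene, n_ko in zip(frame.columns, ko.sum(axis=0)):
            gene_ko_counts[gene] = gene_ko_counts.get(gene, 0) + int(n_ko)
    if per_individual:
        counts = pd.concat(per_individual)
    else:
        counts = pd.Series(dtype=np.int64)
    with_ko = counts[counts > 0]
    return KnockoutCatalogue(
        n_individuals_with_knockout=int((counts > 0).sum()),
        knockouts_per_individual=with_ko,
        genes_knocked_out={g for g, c in gene_ko_counts.items() if c >= 1},
        genes_with_2_or_more_knockouts={g for g, c in gene_ko_counts.items()
                                        if c >= 2},
    )


def genelof_deficit_scan(genelof: dict[str, pd.DataFrame],
                         min_lambda: float = MIN_LAMBDA,
                         strong_ratio: float = STRONG_RATIO) -> pd.DataFrame:
    """Deficit scan on collapsed gene units.

    Treats each gene's geneLOF as a biallelic variant: the per-population
    carrier-haplotype frequency is (affected haplotypes) / (2 n), lambda is
    the across-population sum of n p**2 and O the number of individuals with
    both haplotypes affected. Output columns mirror the single-variant scan.
    """
    genes = sorted({g for frame in genelof.values() for g in frame.columns})
    rows = []
    for gene in genes:
        lam = 0.0
        obs = 0
        per_pop = {}
        for pop_name, frame in genelof.items():
            if gene in frame.columns:
                vals = frame[gene].to_numpy()
                n = vals.size
                p = float(vals.sum()) / (2 * n) if n else 0.0
                lam_pop = n * p ** 2
                obs_pop = int((vals == 2).sum())
            else:
                lam_pop, obs_pop = 0.0, 0
            lam += lam_pop
            obs += obs_pop
            per_pop[pop_name] = (lam_pop, obs_pop)
        tested = lam > min_lambda
        strong = bool(tested and obs <= strong_ratio * lam)
        row = {
            "unit_id": gene,
            "lambda": lam,
            "observed": obs,
            "ratio": obs / lam if lam > 0 else np.nan,
            "tested": tested,
            "strong_deficit": strong,
            "p_poisson": float(stats.poisson.cdf(obs, lam)) if tested else np.nan,
        }
        for pop_name, (lam_pop, obs_pop) in per_pop.items():
            row[f"lambda_{pop_name}"] = lam_pop
            row[f"observed_{pop_name}"] = obs_pop
        rows.append(row)
    return pd.DataFrame(rows)
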