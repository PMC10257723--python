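"""Phased cohort containers.

A cohort is a collection of populations; each population stores the two
phased haplotypes of every individual as sparse indicator matrices over a
shared variant set. Because the scan targets rare alleles, haplotype
matrices are kept in compressed sparse column form: a column holds the
indices of the individuals whose haplotype carries the alternate allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse


def _as_csc(mat: sparse.spmatrix, n: int, m: int) -> sparse.csc_matrix:
    out = sparse.csc_matrix(mat, shape=(n, m), dtype=np.uint8)
    out.sum_duplicates()
    return out


@dataclass
class PopulationPanel:
    """Phased haplotypes of one population.

    ``hap_a`` and ``hap_b`` are ``n_individuals x n_variants`` sparse 0/1
    matrices: entry (i, j) is 1 when the first (resp. second) haplotype of
    individual ``i`` carries the alternate allele of variant ``j``.
    ``missing`` marks genotypes that could not be called; a missing genotype
    contributes neither carrier haplotypes nor homozygotes.
    """

    name: str
    hap_a: sparse.csc_matrix
    hap_b: sparse.csc_matrix
    individual_ids: np.ndarray | None = None
    missing: sparse.csc_matrix | None = None

    def __post_init__(self) -> None:
        if self.hap_a.shape != self.hap_b.shape:
            raise ValueError("haplotype matrices must have identical shape")
        n, m = self.hap_a.shape
        self.hap_a = _as_csc(self.hap_a, n, m)
        self.hap_b = _as_csc(self.hap_b, n, m)
        if self.missing is not None:
            self.missing = _as_csc(self.missing, n, m)
        if self.individual_ids is None:
            width = max(6, len(str(max(n - 1, 0))))
            self.individual_ids = np.array(
                [f"{self.name}_{i:0{width}d}" for i in range(n)], dtype=object
            )
        else:
            self.individual_ids = np.asarray(self.individual_ids, dtype=object)
            if len(self.individual_ids) != n:
                raise ValueError("individual_ids length does not match panel")

    @property
    def n_individuals(self) -> int:
        return self.hap_a.shape[0]

    @property
    def n_variants(self) -> int:
        return self.hap_a.shape[1]

    def genotyped_counts(self) -> np.ndarray:
        """Number of genotyped (non-missing) individuals per variant."""
        n = self.n_individuals
        if self.missing is None:
            return np.full(self.n_variants, n, dtype=np.int64)
        miss = np.asarray(self.missing.sum(axis=0)).ravel()
        return n - miss

    def alt_haplotype_counts(self) -> np.ndarray:
        """Alternate-allele haplotype count per variant (missing excluded)."""
        a = np.asarray(self.hap_a.sum(axis=0)).ravel()
        b = np.asarray(self.hap_b.sum(axis=0)).ravel()
        return (a + b).astype(np.int64)

    def hom_alt_counts(self) -> np.ndarray:
        """Homozygous-alternate individual count per variant."""
        hom = self.hap_a.multiply(self.hap_b)
        return np.asarray(hom.sum(axis=0)).ravel().astype(np.int64)

    def column_indices(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Carrier individual indices of haplotype A and B at variant ``j``."""
        a = self.hap_a.indices[self.hap_a.indptr[j]: self.hap_a.indptr[j + 1]]
        b = self.hap_b.indices[self.hap_b.indptr[j]: self.hap_b.indptr[j + 1]]
        return a, b

    def haplotypes_affected(self, cols: np.ndarray) -> np.ndarray:
        """Per-individual count (0/1/2) of haplotypes carrying an alternate
        allele at one or more of the variant columns ``cols``.

        This is the gene-collapsing primitive: a haplotype is "affected" if
        it carries at least one of the listed variants.
        """
        cols = np.asarray(cols, dtype=np.intp)
        if cols.size == 0:
            return np.zeros(self.n_individuals, dtype=np.uint8)
        aff_a = np.asarray(self.hap_a[:, cols].sum(axis=1)).ravel() > 0
        aff_b = np.asarray(self.hap_b[:, cols].sum(axis=1)).ravel() > 0
        return (aff_a.astype(np.uint8) + aff_b.astype(np.uint8))


@dataclass
class CohortPanel:
    """Multi-population phased panel over a shared variant set."""

    variant_ids: np.ndarray
    populations: list[PopulationPanel]
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        m = len(self.variant_ids)
        for pop in self.populations:
            if pop.n_variants != m:
                raise ValueError(
                    f"population {pop.name!r} has {pop.n_variants} variants, "
                    f"panel defines {m}"
                )
        self._index = {v: j for j, v in enumerate(self.variant_ids)}
        if len(self._index) != m:
            raise ValueError("duplicate variant ids in panel")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"unknown variant id: {variant_id!r}") from None

    def population(self, name: str) -> PopulationPanel:
        for pop in self.populations:
            if pop.name == name:
                return pop
        raise KeyError(f"unknown population: {name!r}")

    def pooled_haplotypes(self) -> sparse.csc_matrix:
        """All haplotypes of all populations stacked into one (2N x m) matrix."""
        blocks = []
        for pop in self.populations:
            blocks.append(pop.hap_a)
            blocks.append(pop.hap_b)
        return sparse.vstack(blocks, format="csc")

    def equals(self, other: "CohortPanel") -> bool:
        """Exact equality of variant sets and haplotype calls."""
        if list(self.variant_ids) != list(other.variant_ids):
            return False
        if self.population_names != other.population_names:
            return False
        for a, b in zip(self.populations, other.populations):
            if a.n_individuals != b.n_individuals:
                return False
            if (a.hap_a != b.hap_a).nnz or (a.hap_b != b.hap_b).nnz:
                return False
        return True
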