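"""Gene collapsing: qualifying filters, compound heterozygotes, knockouts."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from homdeficit import genelof
from homdeficit.panel import CohortPanel, PopulationPanel
from homdeficit.simulate import (PopulationSpec, SimulationConfig,
                                 TrueVariantSpec, simulate_haplotype_panel)

from conftest import panel_from_arrays, panel_from_genotypes


def annotation(rows):
    return pd.DataFrame(rows, columns=["variant_id", "impact_class", "gene",
                                       "plof_confidence"])


class TestQualifyingSelection:
    def _panel(self, freqs):
        """One population of 1000 individuals with given het-carrier counts."""
        n = 1000
        a = np.zeros((n, len(freqs)), dtype=np.uint8)
        for j, p in enumerate(freqs):
            a[: int(round(2 * n * p)), j] = 1  # all on haplotype A: MAF = p
        b = np.zeros_like(a)
        return panel_from_arrays({"P": (a, b)},
                                 [f"v{j}" for j in range(len(freqs))])

    def test_frequency_confidence_and_curation_filters(self):
        panel = self._panel([0.01, 0.03, 0.01, 0.01])
        ann = annotation([
            ("v0", "plof", "G1", "high"),      # qualifies
            ("v1", "plof", "G1", "high"),      # MAF 3% >= 2%: out
            ("v2", "plof", "G1", "low"),       # low confidence: out
            ("v3", "plof", "G1", "high"),      # curated exclusion: out
        ])
        sets = genelof.select_qualifying_plofs(ann, panel, exclude_ids={"v3"})
        assert sets["P"] == {"G1": ["v0"]}

    def test_non_plof_classes_never_qualify(self):
        panel = self._panel([0.01])
        ann = annotation([("v0", "moderate", "G1", "not_applicable")])
        assert genelof.select_qualifying_plofs(ann, panel)["P"] == {}

    def test_per_population_frequency_filter(self):
        """A variant common in one population only qualifies in the other."""
        n = 1000
        a_hi = np.zeros((n, 1), dtype=np.uint8)
        a_hi[:60, 0] = 1  # MAF 3% in P1
        a_lo = np.zeros((n, 1), dtype=np.uint8)
        a_lo[:10, 0] = 1  # MAF 0.5% in P2
        panel = panel_from_arrays(
            {"P1": (a_hi, np.zeros_like(a_hi)),
             "P2": (a_lo, np.zeros_like(a_lo))}, ["v0"])
        ann = annotation([("v0", "plof", "G1", "high")])
        sets = genelof.select_qualifying_plofs(ann, panel)
        assert sets["P1"] == {} and sets["P2"] == {"G1": ["v0"]}
        pooled = genelof.select_qualifying_plofs(ann, panel,
                                                 per_population=False)
        assert pooled["P1"] == pooled["P2"] == {"G1": ["v0"]}  # pooled 1.75%


class TestCollapsing:
    def _two_variant_panel(self, genotype_pairs):
        """Individuals described as (gt at v1, gt at v2) phased strings."""
        return panel_from_genotypes(
            {"P": [[g1, g2] for g1, g2 in genotype_pairs]}, ["v1", "v2"])

    def _collapse(self, panel):
        qualifying = {"P": {"G1": ["v1", "v2"]}}
        return genelof.collapse_to_genelof(panel, qualifying)["P"]

    def test_trans_configuration_is_knockout(self):
        frame = self._collapse(self._two_variant_panel([("1|0", "0|1")]))
        assert frame["G1"].iloc[0] == 2  # compound heterozygote

    def test_cis_configuration_is_single_haplotype(self):
        frame = self._collapse(self._two_variant_panel([("1|0", "1|0")]))
        assert frame["G1"].iloc[0] == 1

    def test_no_qualifying_variant_is_zero(self):
        frame = self._collapse(self._two_variant_panel([("0|0", "0|0")]))
        assert frame["G1"].iloc[0] == 0

    def test_order_independence_and_idempotence(self):
        panel = self._two_variant_panel([("1|0", "0|1"), ("0|1", "0|0")])
        fwd = genelof.collapse_to_genelof(panel, {"P": {"G1": ["v1", "v2"]}})["P"]
        rev = genelof.collapse_to_genelof(panel, {"P": {"G1": ["v2", "v1"]}})["P"]
        dup = genelof.collapse_to_genelof(
            panel, {"P": {"G1": ["v1", "v2", "v1"]}})["P"]
        assert (fwd["G1"] == rev["G1"]).all()
        assert (fwd["G1"] == dup["G1"]).all()


class TestCatalogue:
    def test_toy_counts(self):
        frame = pd.DataFrame({"A": [2, 2, 0], "B": [0, 0, 2]},
                             index=["i1", "i2", "i3"], dtype=np.uint8)
        cat = genelof.build_knockout_catalogue({"P": frame})
        assert cat.n_individuals_with_knockout == 3
        assert cat.genes_knocked_out == {"A", "B"}
        assert cat.genes_with_2_or_more_knockouts == {"A"}

    def test_empty_and_multi_knockout(self):
        empty = genelof.build_knockout_catalogue(
            {"P": pd.DataFrame(index=["i1"])})
        assert empty.n_individuals_with_knockout == 0
        assert empty.genes_knocked_out == set()
        multi = genelof.build_knockout_catalogue(
            {"P": pd.DataFrame({"A": [2], "B": [2]}, index=["i1"])})
        assert multi.knockouts_per_individual.loc["i1"] == 2


class TestGeneScan:
    def test_carrier_frequency_bounds(self):
        """Gene carrier-haplotype frequency lies between the max and the sum
        of its variants' frequencies."""
        cfg = SimulationConfig(
            populations=[PopulationSpec("P", 20_000)],
            variants=[TrueVariantSpec(f"v{k}", {"P": 0.004}, "plof", gene="G1",
                                      plof_confidence="high")
                      for k in range(5)],
            seed=41)
        panel = simulate_haplotype_panel(cfg)
        ann = annotation([(f"v{k}", "plof", "G1", "high") for k in range(5)])
        sets = genelof.select_qualifying_plofs(ann, panel)
        frame = genelof.collapse_to_genelof(panel, sets)["P"]
        gene_freq = frame["G1"].sum() / (2 * len(frame))
        single = [panel.populations[0].alt_haplotype_counts()[j] / (2 * 20_000)
                  for j in range(5)]
        assert max(single) <= gene_freq <= sum(single) + 1e-12

    def test_neutral_gene_in_poisson_band(self):
        cfg = SimulationConfig(
            populations=[PopulationSpec("P", 20_000)],
            variants=[TrueVariantSpec(f"v{k}", {"P": 0.008}, "plof", gene="G1",
                                      plof_confidence="high")
                      for k in range(4)],
            seed=43)
        panel = simulate_haplotype_panel(cfg)
        ann = annotation([(f"v{k}", "plof", "G1", "high") for k in range(4)])
        res = genelof.genelof_deficit_scan(
            genelof.collapse_to_genelof(
                panel, genelof.select_qualifying_plofs(ann, panel)))
        row = res.iloc[0]
        assert row["tested"] and row["lambda"] > 5
        lo, hi = stats.poisson.interval(0.99, row["lambda"])
        assert lo <= row["observed"] <= hi
        assert not row["strong_deficit"]

    def test_gene_with_no_qualifying_variants_not_tested(self):
        res = genelof.genelof_deficit_scan(
            {"P": pd.DataFrame(index=["i1", "i2"])})
        assert len(res) == 0

    def test_jointly_lethal_gene_flagged_where_singles_are_not(self):
        """Collapsing detects a gene whose pLOFs are jointly lethal even
        though each variant alone is below the five-expected-homozygote
        range — the motivation for the gene-based test."""
        n = 100_000
        cfg = SimulationConfig(
            populations=[PopulationSpec("P", n)],
            variants=[TrueVariantSpec(f"v{k}", {"P": 0.004}, "plof", gene="G1",
                                      plof_confidence="high")
                      for k in range(4)],
            seed=47)
        panel = simulate_haplotype_panel(cfg)
        # apply lethality at the gene level: individuals with both haplotypes
        # affected lose their second haplotype's variants (not sampled alive)
        pop = panel.populations[0]
        aff = pop.haplotypes_affected(np.arange(4))
        ko = np.flatnonzero(aff == 2)
        dense_b = pop.hap_b.toarray()
        dense_b[ko, :] = 0
        panel = CohortPanel(
            variant_ids=panel.variant_ids,
            populations=[PopulationPanel("P", pop.hap_a,
                                         sparse.csc_matrix(dense_b))])
        ann = annotation([(f"v{k}", "plof", "G1", "high") for k in range(4)])
        single = genelof.genelof_deficit_scan(
            {"P": pd.DataFrame(
                {f"v{k}": panel.populations[0].haplotypes_affected([k])
                 for k in range(4)}, index=pop.individual_ids)})
        gene = genelof.genelof_deficit_scan(
            genelof.collapse_to_genelof(
                panel, genelof.select_qualifying_plofs(ann, panel)))
        assert (single["lambda"] < 5).all()  # each variant alone: weak regime
        assert gene.iloc[0]["lambda"] >= 5
        assert gene.iloc[0]["strong_deficit"]
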