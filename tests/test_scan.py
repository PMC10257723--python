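"""Scan statistics: frequencies, lambda, deficit flags, LD hygiene, power."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homdeficit import scan
from homdeficit.simulate import (PopulationSpec, SimulationConfig,
                                 TrueVariantSpec, simulate_haplotype_panel)

from conftest import panel_from_arrays, panel_from_genotypes
from oracles import enumerate_expected, enumerate_homozygotes


class TestFrequencyAndLambda:
    def test_frequency_from_haplotype_counts(self):
        panel = panel_from_genotypes(
            {"P": [["0|1"], ["0|0"], ["1|1"], ["0|0"]]}, ["v0"])
        (freq,) = scan.estimate_population_frequency(panel, "v0")
        assert freq.p_hat == pytest.approx(3 / 8)
        assert freq.n == 4

    def test_frequency_all_reference_and_het_hom_mix(self):
        rows = [["0|0"]] * 989 + [["0|1"]] * 10 + [["1|1"]]
        panel = panel_from_genotypes({"P": rows}, ["v0"])
        (freq,) = scan.estimate_population_frequency(panel, "v0")
        assert freq.p_hat == pytest.approx(12 / 2000)
        panel0 = panel_from_genotypes({"P": [["0|0"], ["0|0"]]}, ["v0"])
        assert scan.estimate_population_frequency(panel0, "v0")[0].p_hat == 0.0

    def test_unknown_variant_rejected(self, toy_panel):
        with pytest.raises(KeyError):
            scan.estimate_population_frequency(toy_panel, "nope")

    def test_expected_homozygotes_sums_populations(self):
        freqs = [scan.PopulationFrequency("A", 0.1, 1000),
                 scan.PopulationFrequency("B", 0.2, 1000)]
        lam, terms = scan.expected_homozygotes(freqs)
        assert lam == pytest.approx(50.0)
        assert terms == {"A": pytest.approx(10.0), "B": pytest.approx(40.0)}

    def test_expected_homozygotes_cohort_scale(self):
        """MAF 0.18% in 1.52M individuals corresponds to ~5 expected homozygotes."""
        freqs = [scan.PopulationFrequency("all", 0.0018135, 1_520_000)]
        lam, _ = scan.expected_homozygotes(freqs)
        assert lam == pytest.approx(5.0, rel=1e-3)

    def test_observed_homozygotes(self, toy_panel):
        combined, per_pop = scan.observed_homozygotes(toy_panel, "va")
        assert (combined, per_pop) == (1, {"P1": 1, "P2": 0})
        assert scan.observed_homozygotes(toy_panel, "vb")[0] == 1
        trio = panel_from_genotypes({"P": [["0|1"], ["1|1"], ["1|1"]]}, ["v"])
        assert scan.observed_homozygotes(trio, "v")[0] == 2
        none = panel_from_genotypes({"P": [["0|0"], ["0|1"]]}, ["v"])
        assert scan.observed_homozygotes(none, "v")[0] == 0

    def test_matches_enumeration_oracle_on_small_panels(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n, m = rng.integers(2, 50), rng.integers(1, 8)
            a = (rng.random((n, m)) < 0.3).astype(np.uint8)
            b = (rng.random((n, m)) < 0.3).astype(np.uint8)
            panel = panel_from_arrays({"P": (a, b)})
            res = scan.scan_panel(panel)
            assert list(res["observed"]) == enumerate_homozygotes(a, b)
            assert res["lambda"].to_numpy() == pytest.approx(
                enumerate_expected(a, b))

    def test_lambda_additivity_across_populations(self):
        rng = np.random.default_rng(7)
        pops = {name: ((rng.random((30, 4)) < 0.3).astype(np.uint8),
                       (rng.random((30, 4)) < 0.3).astype(np.uint8))
                for name in ("P1", "P2", "P3")}
        res = scan.scan_panel(panel_from_arrays(pops))
        per_pop = res[[f"lambda_{p}" for p in ("P1", "P2", "P3")]].sum(axis=1)
        assert np.allclose(res["lambda"], per_pop)


class TestDeficitClassification:
    @pytest.mark.parametrize("obs,lam,tested,strong", [
        (1, 29.2, True, True),     # ratio 0.034
        (3, 20.0, True, False),    # ratio 0.15
        (0, 0.4, False, False),    # below the testing threshold
        (2, 20.0, True, True),     # boundary: exactly 10% counts as deficit
    ])
    def test_strong_deficit_rule(self, obs, lam, tested, strong):
        assert scan.classify_strong_deficit(obs, lam) == (tested, strong)

    @given(obs=st.integers(0, 50), lam=st.floats(0.6, 1000),
           d_obs=st.integers(0, 5), d_lam=st.floats(0, 100))
    @settings(max_examples=200, deadline=None)
    def test_strong_deficit_monotone(self, obs, lam, d_obs, d_lam):
        """Decreasing O or increasing lambda never unsets a strong deficit."""
        _, strong = scan.classify_strong_deficit(obs, lam)
        if strong:
            assert scan.classify_strong_deficit(max(obs - d_obs, 0),
                                                lam + d_lam)[1]

    def test_poisson_pvalue(self):
        assert scan.poisson_deficit_pvalue(0, 5.0) == pytest.approx(
            math.exp(-5), rel=1e-9)
        assert scan.poisson_deficit_pvalue(1, 29.2) == pytest.approx(
            math.exp(-29.2) * (1 + 29.2), rel=1e-9)
        assert scan.poisson_deficit_pvalue(30, 29.2) >= 0.5
        with pytest.raises(ValueError):
            scan.poisson_deficit_pvalue(0, 0.0)

    def test_bonferroni_threshold(self):
        assert scan.bonferroni_threshold(1736) == pytest.approx(2.88e-5, rel=5e-3)
        assert scan.bonferroni_threshold(1258) == pytest.approx(3.97e-5, rel=5e-3)
        assert scan.bonferroni_threshold(1) == 0.05
        with pytest.raises(ValueError):
            scan.bonferroni_threshold(0)

    def test_maf_for_expected_count(self):
        assert scan.maf_for_expected_count(5, 1.52e6) == pytest.approx(
            0.0018, abs=5e-5)
        assert scan.maf_for_expected_count(8, 1.52e6) == pytest.approx(
            0.0023, abs=5e-5)
        assert scan.maf_for_expected_count(100, 100) == 1.0
        with pytest.raises(ValueError):
            scan.maf_for_expected_count(0, 100)

    def test_null_poisson_calibration_is_conservative(self):
        """Under HWE the deficit p-value is stochastically >= uniform."""
        cfg = SimulationConfig(
            populations=[PopulationSpec("P", 50_000)],
            variants=[TrueVariantSpec(f"v{k}", {"P": math.sqrt(3 / 50_000)},
                                      "intergenic") for k in range(500)],
            seed=21)
        res = scan.scan_panel(simulate_haplotype_panel(cfg))
        for t in (0.05, 0.01):
            frac = (res.loc[res["tested"], "p_poisson"] < t).mean()
            assert frac <= t + 2 * math.sqrt(t * (1 - t) / 500)


class TestLDHygiene:
    def test_identical_haplotypes_r2_one(self):
        rng = np.random.default_rng(1)
        a = (rng.random((500, 1)) < 0.2).astype(np.uint8)
        b = (rng.random((500, 1)) < 0.2).astype(np.uint8)
        panel = panel_from_arrays(
            {"P": (np.hstack([a, a]), np.hstack([b, b]))}, ["x", "y"])
        assert scan.haplotype_r2(panel, "x", "y") == pytest.approx(1.0)

    def test_monomorphic_pair_r2_zero_by_convention(self):
        panel = panel_from_genotypes({"P": [["0|0", "0|1"], ["0|0", "0|0"]]},
                                     ["mono", "poly"])
        assert scan.haplotype_r2(panel, "mono", "poly") == 0.0

    def test_independent_variants_low_r2(self):
        cfg = SimulationConfig(
            populations=[PopulationSpec("P", 50_000)],
            variants=[TrueVariantSpec("a", {"P": 0.2}, "intergenic"),
                      TrueVariantSpec("b", {"P": 0.2}, "intergenic")],
            seed=13)
        panel = simulate_haplotype_panel(cfg)  # 1e5 haplotypes
        assert scan.haplotype_r2(panel, "a", "b") < 0.01

    def _ld_panel(self):
        rng = np.random.default_rng(3)
        plof_a = (rng.random((800, 1)) < 0.15).astype(np.uint8)
        plof_b = (rng.random((800, 1)) < 0.15).astype(np.uint8)
        ind_a = (rng.random((800, 2)) < 0.15).astype(np.uint8)
        ind_b = (rng.random((800, 2)) < 0.15).astype(np.uint8)
        low_a = (rng.random((800, 1)) < 0.15).astype(np.uint8)
        low_b = (rng.random((800, 1)) < 0.15).astype(np.uint8)
        a = np.hstack([plof_a, plof_a, ind_a[:, :1], low_a, low_a])
        b = np.hstack([plof_b, plof_b, ind_b[:, :1], low_b, low_b])
        ids = ["plof1", "mod_linked", "mod_free", "low1", "inter_linked"]
        ann = pd.DataFrame({
            "variant_id": ids,
            "impact_class": ["plof", "moderate", "moderate", "low", "intergenic"],
        })
        return panel_from_arrays({"P": (a, b)}, ids), ann

    def test_crossclass_exclusion_hierarchy(self):
        panel, ann = self._ld_panel()
        retained = scan.crossclass_ld_exclude(panel, ann)
        assert retained["plof"] == ["plof1"]          # never removed
        assert retained["moderate"] == ["mod_free"]   # linked to plof: removed
        assert retained["low"] == ["low1"]            # independent of plof
        assert retained["intergenic"] == []           # in perfect LD with low

    def test_exclusion_keeps_below_threshold(self):
        panel, ann = self._ld_panel()
        retained = scan.crossclass_ld_exclude(panel, ann, r2_threshold=1.01)
        assert retained["moderate"] == ["mod_linked", "mod_free"]


class TestIntergenicDistance:
    def test_distance_set_membership(self):
        variants = pd.DataFrame({
            "variant_id": ["inside", "near", "far", "other_chrom"],
            "chrom": ["chr1", "chr1", "chr1", "chr9"],
            "pos": [100_001, 126_000, 720_001, 5],
        })
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [100_000],
                              "end": [120_000]})
        sets = scan.classify_intergenic_by_distance(variants, genes)
        assert not sets.loc["inside"].drop("distance").any()
        assert sets.loc["near", "gt_5000"] and not sets.loc["near", "gt_50000"]
        assert sets.loc["far"].drop("distance").all()
        assert sets.loc["other_chrom"].drop("distance").all()  # gene-free chrom

    def test_malformed_interval_rejected(self):
        variants = pd.DataFrame({"variant_id": ["v"], "chrom": ["chr1"],
                                 "pos": [10]})
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [40]})
        with pytest.raises(ValueError):
            scan.classify_intergenic_by_distance(variants, genes)


class TestPower:
    def test_null_power_is_alpha_tail(self):
        assert scan.power_two_proportions(0.01, 0.01, 10_000) == pytest.approx(
            0.025, abs=1e-6)

    def test_solve_n_inverse_consistency(self):
        n = scan.solve_n_two_proportions(1e-5, 1e-6, 0.05, 0.8)
        assert scan.power_two_proportions(1e-5, 1e-6, n) == pytest.approx(
            0.8, abs=1e-6)

    def test_power_matches_monte_carlo_rejection_rate(self):
        """Analytic power within +-0.02 of a simulated two-proportion z test.

        Checked where the normal approximation holds (expected counts well
        above 10 per arm); with near-Poisson counts the z approximation is
        known to understate the rejection rate, which the looser sanity
        check below documents.
        """
        from scipy.stats import norm
        rng = np.random.default_rng(17)

        def empirical(p1, p2, n, reps=20_000):
            x1 = rng.binomial(n, p1, size=reps)
            x2 = rng.binomial(n, p2, size=reps)
            pbar = (x1 + x2) / (2 * n)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (x1 - x2) / n / np.sqrt(2 * pbar * (1 - pbar) / n)
            return (np.abs(np.nan_to_num(z)) > norm.ppf(0.975)).mean()

        p1, p2, n = 0.2, 0.1, 199
        assert abs(empirical(p1, p2, n)
                   - scan.power_two_proportions(p1, p2, n)) < 0.02
        # rare-variant regime: analytic power is a conservative lower bound
        p1, p2, n = 1e-5, 1e-6, 1_520_000
        assert scan.power_two_proportions(p1, p2, n) <= empirical(p1, p2, n) + 0.02


class TestInbreeding:
    def test_full_ibd_individual_estimates_one(self):
        rng = np.random.default_rng(5)
        a = (rng.random((200, 500)) < 0.2).astype(np.uint8)
        b = (rng.random((200, 500)) < 0.2).astype(np.uint8)
        b[0] = a[0]  # individual 0 is a whole-genome IBD copy
        est = scan.estimate_inbreeding(panel_from_arrays({"P": (a, b)}))
        assert est.loc[0, "f_hat"] == pytest.approx(1.0, abs=0.05)

    def test_outbred_individuals_estimate_zero(self):
        cfg = SimulationConfig(
            populations=[PopulationSpec("P", 50)],
            variants=[TrueVariantSpec(f"v{k}", {"P": 0.2}, "intergenic")
                      for k in range(10_000)],
            seed=23)
        est = scan.estimate_inbreeding(simulate_haplotype_panel(cfg))
        assert np.abs(est["f_hat"]).max() < 0.05
        assert abs(est["f_hat"].mean()) < 0.01

    def test_monomorphic_only_panel_rejected(self):
        panel = panel_from_genotypes({"P": [["0|0"], ["0|0"]]})
        with pytest.raises(ValueError):
            scan.estimate_inbreeding(panel)


class TestFrequencyOverride:
    def test_dosage_frequency_replaces_hard_call_estimate(self):
        from conftest import panel_from_genotypes
        panel = panel_from_genotypes(
            {"P": [["0|1"], ["0|0"], ["0|0"], ["0|0"]]}, ["v0"])
        base = scan.scan_panel(panel)
        assert base.loc[0, "lambda"] == pytest.approx(4 * (1 / 8) ** 2)
        override = pd.DataFrame({"variant_id": ["v0"], "population": ["P"],
                                 "p_hat": [0.25]})
        dosed = scan.scan_panel(panel, frequency_override=override)
        assert dosed.loc[0, "lambda"] == pytest.approx(4 * 0.25 ** 2)
        assert dosed.loc[0, "observed"] == base.loc[0, "observed"]
        with pytest.raises(ValueError):
            scan.scan_panel(panel, frequency_override=pd.DataFrame(
                {"variant_id": ["v0"], "population": ["P"], "p_hat": [1.5]}))
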