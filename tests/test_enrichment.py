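"""Per-gene enrichment tests, multiple-testing control and tier assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dnvmeta.enrichment import (
    EnrichmentError, WeightScheme, adjust_bh, assign_tiers, fisher_combine,
    fwer_threshold, missense_clustering_test, model_level_significance,
    poisson_upper_tail, run_three_models, weighted_statistic_test,
)
from dnvmeta.mutation_model import GeneModel

from oracles import poisson_tail_oracle


class TestPoissonUpperTail:
    @pytest.mark.parametrize("obs,lam,expected", [
        (0, 5.0, 1.0),
        # 1 - e^{-0.5} (1 + 0.5 + 0.125)
        (3, 0.5, 0.014388),
        # 1 - 3 e^{-2}
        (2, 2.0, 0.593994),
    ])
    def test_frozen_values(self, obs, lam, expected):
        assert poisson_upper_tail(obs, lam) == pytest.approx(expected, abs=5e-7)

    @pytest.mark.parametrize("obs,lam", [(1, 0.3), (4, 2.7), (10, 0.05)])
    def test_matches_series_oracle(self, obs, lam):
        assert poisson_upper_tail(obs, lam) == pytest.approx(
            poisson_tail_oracle(obs, lam), rel=1e-9
        )

    def test_monotone_in_observed(self):
        ps = [poisson_upper_tail(k, 1.5) for k in range(8)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_negative_inputs_rejected(self):
        with pytest.raises(EnrichmentError):
            poisson_upper_tail(-1, 1.0)
        with pytest.raises(EnrichmentError):
            poisson_upper_tail(1, -1.0)


class TestWeightedTest:
    LAM = {"LGD": 0.3, "MIS": 0.8, "MIS30": 0.15, "SYN": 0.4}

    def test_no_observed_dnvs_gives_p_one(self):
        p = weighted_statistic_test([], self.LAM, n_iter=500, seed=1)
        assert p == 1.0

    def test_constant_weights_reduce_to_poisson_tail(self):
        # With equal weights the statistic is a monotone function of the
        # total count, so the Monte-Carlo p must match the Poisson tail.
        w = WeightScheme({c: 1.0 for c in self.LAM})
        lam_tot = sum(self.LAM.values())
        for k in (1, 3, 5):
            p_mc = weighted_statistic_test(
                ["MIS"] * k, self.LAM, weights=w, n_iter=40_000, seed=3
            )
            p_exact = poisson_upper_tail(k, lam_tot)
            se = np.sqrt(p_exact * (1 - p_exact) / 40_000)
            assert abs(p_mc - p_exact) < 4 * se + 2 / 40_000

    def test_seeded_determinism(self):
        args = (["LGD", "MIS"], self.LAM)
        p1 = weighted_statistic_test(*args, n_iter=2000, seed=42)
        p2 = weighted_statistic_test(*args, n_iter=2000, seed=42)
        assert p1 == p2

    def test_severe_observation_is_more_significant(self):
        p_lgd = weighted_statistic_test(["LGD"] * 3, self.LAM, n_iter=20_000,
                                        seed=5)
        p_syn = weighted_statistic_test(["SYN"] * 3, self.LAM, n_iter=20_000,
                                        seed=5)
        assert p_lgd < p_syn

    def test_invalid_n_iter(self):
        with pytest.raises(EnrichmentError):
            weighted_statistic_test([], self.LAM, n_iter=0)


class TestClusteringTest:
    def test_single_missense_is_uninformative(self):
        assert missense_clustering_test([17], 300) == 1.0

    def test_identical_positions_are_clustered(self):
        p = missense_clustering_test([150, 150, 150], 300, n_iter=10_000,
                                     seed=1)
        assert p < 0.01

    def test_null_positions_are_calibrated(self):
        # positions drawn from the null itself give roughly uniform p
        rng = np.random.default_rng(7)
        ps = [
            missense_clustering_test(
                rng.integers(1, 301, size=4), 300, n_iter=400, seed=int(s)
            )
            for s in rng.integers(0, 2**31, size=200)
        ]
        assert 0.25 < np.mean(ps) < 0.75
        assert (np.array(ps) < 0.1).mean() < 0.25

    def test_position_outside_cds_rejected(self):
        with pytest.raises(EnrichmentError):
            missense_clustering_test([10, 400], 300)


class TestAdjustBH:
    def test_hand_stepped_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03], m=3), [0.03, 0.03, 0.03]
        )

    def test_single_p(self):
        assert adjust_bh([0.04], m=1)[0] == pytest.approx(0.04)

    def test_universe_larger_than_tested(self):
        # untested genes (p = 1) only matter through the denominator
        q = adjust_bh([0.001, 0.5], m=100)
        assert q[0] == pytest.approx(0.1)
        assert q[1] == pytest.approx(1.0)  # 0.5 * 100 / 2 capped

    def test_small_universe_rejected(self):
        with pytest.raises(EnrichmentError):
            adjust_bh([0.1, 0.2], m=1)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_dominates_p_and_is_monotone(self, ps):
        q = adjust_bh(ps)
        p = np.array(ps)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestFwerThreshold:
    def test_exome_wide_constant(self):
        assert fwer_threshold(19_618, 7, 0.05) == pytest.approx(3.64e-7,
                                                                rel=5e-3)

    @pytest.mark.parametrize("genes,tests,alpha,expected", [
        (1, 1, 0.05, 0.05),
        (20_000, 1, 0.05, 2.5e-6),
    ])
    def test_arithmetic(self, genes, tests, alpha, expected):
        assert fwer_threshold(genes, tests, alpha) == pytest.approx(expected)


def _toy_results(p_by_gene_model):
    rows = []
    for gene, per_model in p_by_gene_model.items():
        for model, p in per_model.items():
            rows.append(dict(gene=gene, model=model, test="LGD", p=p))
    return pd.DataFrame(rows)


class TestAssignTiers:
    THRESHOLD = 1e-6

    def test_union_vs_intersection(self):
        res = _toy_results({
            "UNION_ONLY": {"CH": 1e-4, "TRI": 0.9, "WPT": 0.9},
            "ALL_MODELS": {"CH": 1e-4, "TRI": 1e-4, "WPT": 1e-4},
            "EXOME_WIDE": {"CH": 1e-9, "TRI": 1e-9, "WPT": 1e-9},
            "NULL": {"CH": 0.9, "TRI": 0.9, "WPT": 0.9},
        })
        counts = {g: 5 for g in res["gene"].unique()}
        tiers = assign_tiers(res, None, counts, threshold=self.THRESHOLD,
                             model_universe=10).set_index("gene")
        assert tiers.at["UNION_ONLY", "tier"] == "LC"
        assert tiers.at["ALL_MODELS", "tier"] == "MC"
        assert tiers.at["EXOME_WIDE", "tier"] == "HC"
        assert tiers.at["NULL", "tier"] == "none"

    def test_dnv_count_requirement_is_strict(self):
        res = _toy_results({"G": {"CH": 1e-9, "TRI": 1e-9, "WPT": 1e-9}})
        for count, tier in ((2, "none"), (3, "HC")):
            tiers = assign_tiers(res, None, {"G": count},
                                 threshold=self.THRESHOLD, model_universe=10)
            assert tiers.loc[0, "tier"] == tier

    def test_sibling_significance_excludes(self):
        res = _toy_results({"G": {"CH": 1e-9, "TRI": 1e-9, "WPT": 1e-9}})
        sib = _toy_results({"G": {"CH": 1e-6, "TRI": 0.8}})
        tiers = assign_tiers(res, sib, {"G": 5}, threshold=self.THRESHOLD,
                             model_universe=10)
        assert tiers.loc[0, "tier"] == "none"
        assert bool(tiers.loc[0, "sibling_excluded"])

    def test_nesting_on_random_inputs(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(200)]
        rows = []
        for gene in genes:
            for model in ("CH", "TRI", "WPT"):
                rows.append(dict(gene=gene, model=model, test="LGD",
                                 p=float(rng.beta(0.2, 3.0))))
        res = pd.DataFrame(rows)
        counts = {g: int(rng.integers(0, 8)) for g in genes}
        tiers = assign_tiers(res, None, counts, threshold=1e-3,
                             model_universe=200)
        sets = {
            t: set(tiers.loc[tiers["tier"].isin(members), "gene"])
            for t, members in
            (("LC", ["LC", "MC", "HC"]), ("MC", ["MC", "HC"]), ("HC", ["HC"]))
        }
        assert sets["HC"] <= sets["MC"] <= sets["LC"]
        assert all(counts[g] >= 3 for g in sets["LC"])

    def test_combine_rules_agree_on_single_test_models(self):
        res = _toy_results({
            "A": {"CH": 0.001, "TRI": 0.004, "WPT": 0.2},
            "B": {"CH": 0.5, "TRI": 0.9, "WPT": 0.7},
        })
        t1 = model_level_significance(res, 10, combine="min_q")
        t2 = model_level_significance(res, 10, combine="min_p_then_fdr")
        pd.testing.assert_frame_equal(t1, t2)


class TestRunThreeModels:
    def _models(self, n=5, lam_scale=1e-6):
        return {
            f"G{i}": GeneModel(f"G{i}", "1", 300, lam_scale, 3 * lam_scale,
                               lam_scale / 2, lam_scale)
            for i in range(n)
        }

    def test_zero_count_gene_has_p_one(self, small_cohort):
        table, models = small_cohort["table"], small_cohort["model_map"]
        res = run_three_models(table, models, "sibling", n_iter=200, seed=0)
        counts = table.counts["sibling"]
        silent = counts.index[counts.sum(axis=1) == 0]
        assert len(silent) > 0
        sub = res[res["gene"].isin(silent)]
        assert (sub["p"] == 1.0).all()

    def test_seven_tests_per_gene(self, small_cohort):
        res = run_three_models(
            small_cohort["table"], small_cohort["model_map"], "NDD",
            records=small_cohort["records"], n_iter=100, seed=0,
        )
        per_gene = res.groupby("gene").size()
        assert (per_gene == 7).all()
        assert set(map(tuple, res[["model", "test"]].drop_duplicates()
                       .itertuples(index=False))) == {
            ("CH", "LGD"), ("CH", "MIS"), ("CH", "MIS30"),
            ("TRI", "LGD"), ("TRI", "MIS"),
            ("WPT", "allDNV"), ("WPT", "MISens"),
        }

    def test_planted_gene_reaches_exome_wide_significance(self, small_cohort):
        # the planted relative risks (10-50x) push CH LGD p far below the
        # exome-wide threshold for most planted genes
        res = run_three_models(
            small_cohort["table"], small_cohort["model_map"], "NDD",
            n_iter=100, seed=0,
        )
        planted = small_cohort["architecture"].risk_genes
        ch_lgd = res[(res["model"] == "CH") & (res["test"] == "LGD")
                     & res["gene"].isin(planted)]
        assert (ch_lgd["p"] < 3.64e-7).mean() > 0.5

    def test_missing_gene_model_rejected(self, small_cohort):
        models = dict(small_cohort["model_map"])
        missing = small_cohort["table"].counts.index[0]
        models.pop(missing)
        with pytest.raises(EnrichmentError, match=missing):
            run_three_models(small_cohort["table"], models, "NDD",
                             n_iter=50, seed=0)

    def test_seeded_reproducibility(self, small_cohort):
        kw = dict(records=small_cohort["records"], n_iter=150, seed=9)
        r1 = run_three_models(small_cohort["table"],
                              small_cohort["model_map"], "NDD", **kw)
        r2 = run_three_models(small_cohort["table"],
                              small_cohort["model_map"], "NDD", **kw)
        pd.testing.assert_frame_equal(r1, r2)


def test_fisher_combination_of_uniform_pvalues():
    # combining two p-values of 1 stays 1; combining small ones gets smaller
    assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)
    assert fisher_combine([0.01, 0.01]) < 0.01
    assert 0.0 < fisher_combine([0.5, 0.5]) < 1.0
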