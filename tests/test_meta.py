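"""Effect-size meta-analysis: hand-derived oracles, invariants, statsmodels cross-check."""

import numpy as np
import pytest

from cohortmeta.meta import (
    HeterogeneityStats, StudyEffect, begg_test, hedges_g, heterogeneity,
    leave_one_out, meta_per_gene, pool,
)
from cohortmeta.preprocess import harmonize_genes
from cohortmeta.simulate import CohortSpec, generate_cohorts, make_truth

from conftest import multi_gene_cohort


def effects_from(gs, vs):
    return [
        StudyEffect(study_label=f"s{i}", g=g, variance=v, n_tumor=10, n_normal=10)
        for i, (g, v) in enumerate(zip(gs, vs))
    ]


class TestHedgesG:
    def test_hand_evaluated_example(self):
        # d = 2/1 = 2, J = 1 - 3/15 = 0.8, g = 1.6,
        # var = J^2 [(6/9) + 4/12] = 0.64 * 1 = 0.64
        e = hedges_g(4, 1, 3, 2, 1, 3)
        assert e.g == pytest.approx(1.6, abs=1e-12)
        assert e.variance == pytest.approx(0.64, abs=1e-12)

    def test_equal_means_zero(self):
        assert hedges_g(5, 1, 10, 5, 2, 10).g == 0.0

    def test_group_swap_antisymmetry(self):
        a = hedges_g(4, 1.2, 8, 2, 0.9, 6)
        b = hedges_g(2, 0.9, 6, 4, 1.2, 8)
        assert a.g == pytest.approx(-b.g, abs=1e-12)
        assert a.variance == pytest.approx(b.variance, abs=1e-12)

    def test_cohens_d_flag(self):
        assert hedges_g(4, 1, 3, 2, 1, 3, correction=False).g == pytest.approx(2.0)

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            hedges_g(4, 1, 1, 2, 1, 3)


class TestHeterogeneity:
    def test_identical_studies(self):
        het = heterogeneity(effects_from([0.5] * 4, [0.1] * 4))
        assert het.Q == pytest.approx(0.0, abs=1e-12)
        assert het.I2 == 0.0 and het.tau2 == 0.0

    def test_hand_evaluated_q(self):
        # w = (10, 5); theta_F = 12.5/15; Q = 10(1/6)^2 + 5(1/3)^2 = 5/6
        het = heterogeneity(effects_from([1.0, 0.5], [0.1, 0.2]))
        assert het.Q == pytest.approx(5 / 6, abs=1e-10)
        assert het.I2 == 0.0  # Q < df
        assert het.tau2 == 0.0

    def test_constructed_i2_60_percent(self):
        # equal variances 1, deviations (2,1,0,-1,-2): Q = 10, df = 4
        het = heterogeneity(effects_from([2.0, 1.0, 0.0, -1.0, -2.0], [1.0] * 5))
        assert het.Q == pytest.approx(10.0, abs=1e-10)
        assert het.I2 == pytest.approx(60.0, abs=1e-10)
        # DL: C = 5 - 5/5 = 4, tau2 = 6/4
        assert het.tau2 == pytest.approx(1.5, abs=1e-10)

    def test_single_study_errors(self):
        with pytest.raises(ValueError):
            heterogeneity(effects_from([1.0], [0.1]))


class TestPool:
    def test_fixed_effect_closed_form(self):
        res = pool(effects_from([1.0, 0.5], [0.1, 0.2]))
        assert res.model == "fixed"
        assert res.pooled == pytest.approx(5 / 6, abs=1e-10)
        assert res.se == pytest.approx(np.sqrt(1 / 15), abs=1e-10)

    @pytest.mark.parametrize(
        "i2,p_q,model",
        [(56.0, 0.02, "random"), (0.0, 0.9, "fixed"), (56.0, 0.2, "fixed"),
         (30.0, 0.01, "fixed")],
    )
    def test_model_selection_rule(self, i2, p_q, model):
        het = HeterogeneityStats(Q=5.0, df=4, p_Q=p_q, I2=i2, tau2=0.1)
        res = pool(effects_from([1.0, 0.8, 0.6], [0.1, 0.1, 0.1]), het)
        assert res.model == model

    def test_random_equals_fixed_when_tau2_zero(self):
        effects = effects_from([1.0, 0.5, 0.8], [0.1, 0.2, 0.15])
        fixed = pool(effects, HeterogeneityStats(Q=1, df=2, p_Q=0.9, I2=0, tau2=0.0))
        forced_random = pool(
            effects, HeterogeneityStats(Q=20, df=2, p_Q=0.01, I2=90, tau2=0.0)
        )
        assert forced_random.model == "random"
        assert forced_random.pooled == pytest.approx(fixed.pooled, abs=1e-12)

    def test_single_study_passthrough(self):
        res = pool(effects_from([1.2], [0.2]))
        assert res.pooled == 1.2 and res.model == "fixed"

    def test_pooled_within_study_range_and_reorder_invariant(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            k = rng.integers(2, 9)
            gs = rng.normal(0.5, 1.0, k)
            vs = rng.uniform(0.05, 0.5, k)
            res = pool(effects_from(gs, vs))
            assert gs.min() - 1e-12 <= res.pooled <= gs.max() + 1e-12
            perm = rng.permutation(k)
            res2 = pool(effects_from(gs[perm], vs[perm]))
            assert res2.pooled == pytest.approx(res.pooled, abs=1e-12)

    def test_weights_normalized_and_significance(self):
        res = pool(effects_from([1.0, 1.2], [0.05, 0.05]))
        assert sum(res.weights) == pytest.approx(1.0)
        assert res.significant  # CI well above zero

    def test_statsmodels_cross_check(self):
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(9)
        gs = rng.normal(0.8, 0.5, 6)
        vs = rng.uniform(0.05, 0.3, 6)
        ours_het = heterogeneity(effects_from(gs, vs))
        ref = combine_effects(gs, vs, method_re="dl")
        assert ours_het.tau2 == pytest.approx(ref.tau2, abs=1e-10)
        fixed = pool(effects_from(gs, vs),
                     HeterogeneityStats(Q=1, df=5, p_Q=0.9, I2=0, tau2=ours_het.tau2))
        assert fixed.pooled == pytest.approx(ref.mean_effect_fe, abs=1e-10)
        forced = pool(effects_from(gs, vs),
                      HeterogeneityStats(Q=99, df=5, p_Q=1e-6, I2=99, tau2=ours_het.tau2))
        assert forced.pooled == pytest.approx(ref.mean_effect_re, abs=1e-10)


class TestLeaveOneOut:
    def test_two_studies_reduce_to_singletons(self):
        effects = effects_from([1.0, 0.4], [0.1, 0.2])
        results, _ = leave_one_out(effects)
        assert len(results) == 2
        assert results[0].pooled == pytest.approx(0.4)
        assert results[1].pooled == pytest.approx(1.0)

    def test_identical_studies_identical_results(self):
        results, stable = leave_one_out(effects_from([0.9] * 5, [0.05] * 5))
        assert len({round(r.pooled, 12) for r in results}) == 1
        assert stable

    def test_strong_effect_regime_is_stable(self):
        rng = np.random.default_rng(21)
        gs = rng.normal(1.0, 0.2, 8)
        vs = rng.uniform(0.05, 0.15, 8)
        results, stable = leave_one_out(effects_from(gs, vs))
        assert len(results) == 8
        assert stable

    def test_single_study_errors(self):
        with pytest.raises(ValueError):
            leave_one_out(effects_from([1.0], [0.1]))


class TestBegg:
    def test_equal_variances_full_ties(self):
        res = begg_test(effects_from([1.0, 0.5, 0.2, 0.9], [0.1] * 4))
        assert res.estimate == 0.0
        assert res.p_value == 1.0

    def test_matches_brute_force_enumeration(self):
        # independent oracle: deviates + O(k^2) concordance counting in-test
        gs = np.array([0.2, 0.9, 0.5, 1.4, 0.1, 1.9, 0.7, 1.1])
        vs = np.array([0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40])
        w = 1 / vs
        theta = np.sum(w * gs) / np.sum(w)
        u = (gs - theta) / np.sqrt(vs - 1 / np.sum(w))
        s = sum(
            np.sign(u[i] - u[j]) * np.sign(vs[i] - vs[j])
            for i in range(8) for j in range(i)
        )
        n0 = 8 * 7 / 2
        tau = s / n0  # no ties in either margin
        res = begg_test(effects_from(gs, vs))
        assert res.estimate == pytest.approx(tau, abs=1e-10)
        assert res.statistic == pytest.approx(s, abs=1e-10)

    def test_monotone_construction_gives_tau_one(self):
        vs = np.linspace(0.2, 2.0, 10)
        # effects rising steeply with variance -> deviates rise with variance
        gs = 10.0 * vs
        res = begg_test(effects_from(gs, vs))
        assert res.estimate == pytest.approx(1.0)

    def test_too_few_studies_errors(self):
        with pytest.raises(ValueError):
            begg_test(effects_from([1.0, 0.5], [0.1, 0.2]))


class TestMetaPerGene:
    def test_constant_gene_flagged_and_skipped(self):
        c1 = multi_gene_cohort(
            {"A": [5, 6, 7, 1, 2, 3], "B": [4.0] * 6}, n_tumor=3, label="m1"
        )
        c2 = multi_gene_cohort(
            {"A": [6, 7, 8, 2, 3, 4], "B": [1, 2, 3, 4, 5, 6]}, n_tumor=3, label="m2"
        )
        hset = harmonize_genes([c1, c2])
        table = meta_per_gene(hset)
        assert "B" not in table.index
        assert "B" in table.attrs["skipped_genes"]
        assert "A" in table.index

    def test_target_recovery_large_groups(self):
        specs = [CohortSpec(50, 50, label=f"r{i}") for i in range(8)]
        truth = make_truth(n_genes=30, n_members=3, delta_target=1.0,
                           delta_members=1.0, tau2=0.05)
        cohorts, _ = generate_cohorts(specs, truth, 77)
        table = meta_per_gene(harmonize_genes(cohorts))
        assert table.loc["TPI1", "pooled"] == pytest.approx(1.0, abs=0.15)

    def test_matches_per_gene_pool(self, small_world):
        from cohortmeta.meta import gene_effects

        hset, truth = small_world
        table = meta_per_gene(hset)
        gene = table.index[5]
        res = pool(gene_effects(hset, gene))
        assert table.loc[gene, "pooled"] == pytest.approx(res.pooled, abs=1e-12)
        assert table.loc[gene, "p"] == pytest.approx(res.p_value, abs=1e-12)
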