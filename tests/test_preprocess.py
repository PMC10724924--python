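"""Reading, filtering, scale detection, batch adjustment, harmonization."""

import numpy as np
import pandas as pd
import pytest

from cohortmeta.io import read_survival, write_cohort
from cohortmeta.preprocess import (
    combat_adjust, filter_datasets, harmonize_genes, maybe_log2,
    merge_by_platform, read_cohort,
)
from cohortmeta.simulate import (
    CohortSpec, generate_cohorts, generate_survival, make_truth,
)

from conftest import multi_gene_cohort, toy_cohort


@pytest.fixture()
def disk_cohort(tmp_path):
    truth = make_truth(n_genes=25, n_members=3)
    cohort = generate_cohorts(
        [CohortSpec(6, 6, paired=True, label="dc", platform_label="p")], truth, 8
    )[0][0]
    expr, pheno = tmp_path / "expr.tsv", tmp_path / "pheno.tsv"
    surv = generate_survival(
        cohort.expression("TPI1")[cohort.group == "tumor"], 2.0, 0.3, seed=5
    )
    write_cohort(cohort, expr, pheno, survival=surv)
    return cohort, expr, pheno, surv


class TestReadCohort:
    def test_round_trip(self, disk_cohort):
        cohort, expr, pheno, _ = disk_cohort
        back = read_cohort(expr, pheno, platform_label="p", label="dc")
        assert back.values.shape == cohort.values.shape
        assert np.allclose(back.values.to_numpy(), cohort.values.to_numpy(),
                           rtol=1e-9)
        assert back.group.equals(cohort.group)
        assert back.pair_id.tolist() == cohort.pair_id.tolist()

    def test_survival_round_trip(self, disk_cohort):
        _, _, pheno, surv = disk_cohort
        back = read_survival(pheno)
        assert np.allclose(back["time"], surv["time"], rtol=1e-9)
        assert (back["event"] == surv["event"]).all()

    def test_missing_sample_named_in_error(self, tmp_path):
        mat = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["G1"])
        mat.index.name = "gene"
        mat.to_csv(tmp_path / "e.tsv", sep="\t")
        pd.DataFrame({
            "sample_id": ["s1", "s2", "sGHOST"],
            "group": ["tumor", "normal", "normal"],
        }).to_csv(tmp_path / "p.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="sGHOST"):
            read_cohort(tmp_path / "e.tsv", tmp_path / "p.tsv")

    def test_duplicate_symbols_collapsed_by_mean(self, tmp_path):
        (tmp_path / "e.tsv").write_text(
            "gene\ts1\ts2\nTPI1\t2\t4\ntpi1\t4\t8\nG2\t1\t1\n"
        )
        (tmp_path / "p.tsv").write_text(
            "sample_id\tgroup\ns1\ttumor\ns2\tnormal\n"
        )
        c = read_cohort(tmp_path / "e.tsv", tmp_path / "p.tsv")
        assert c.values.loc["TPI1"].tolist() == [3.0, 6.0]

    def test_missing_group_errors(self, tmp_path):
        (tmp_path / "e.tsv").write_text("gene\ts1\ts2\nG1\t1\t2\n")
        (tmp_path / "p.tsv").write_text(
            "sample_id\tgroup\ns1\ttumor\ns2\ttumor\n"
        )
        with pytest.raises(ValueError, match="normal"):
            read_cohort(tmp_path / "e.tsv", tmp_path / "p.tsv")


class TestFilterDatasets:
    def test_boundary_inclusive(self):
        small = toy_cohort([1, 2, 3], [4, 5], label="n5")       # total 5
        boundary = toy_cohort([1, 2, 3], [4, 5, 6], label="n6")  # total 6
        kept = filter_datasets([small, boundary])
        assert [c.label for c in kept] == ["n6"]

    def test_empty_input_passes_through(self):
        assert filter_datasets([]) == []

    def test_all_removed_errors(self):
        with pytest.raises(ValueError):
            filter_datasets([toy_cohort([1, 2], [3, 4], label="n4")])

    def test_order_preserved(self):
        cohorts = [toy_cohort(range(5), range(5), label=f"c{i}") for i in range(3)]
        assert [c.label for c in filter_datasets(cohorts)] == ["c0", "c1", "c2"]


class TestMaybeLog2:
    def test_linear_scale_transformed(self):
        c = toy_cohort([10000, 500, 20], [1, 2, 3])
        out = maybe_log2(c)
        assert out.log_scale
        assert out.values.iloc[0, 0] == pytest.approx(np.log2(10001))

    def test_log_scale_untouched(self):
        c = toy_cohort([12, 5, 7], [1, 2, 3])
        assert maybe_log2(c).values.equals(c.values)

    def test_all_zero_untouched(self):
        c = toy_cohort([0, 0], [0, 0.0001])
        assert maybe_log2(c).values.equals(c.values)

    def test_negative_with_linear_max_errors(self):
        c = toy_cohort([100, -1], [2, 3])
        with pytest.raises(ValueError):
            maybe_log2(c)


class TestCombat:
    @staticmethod
    def _design(n_per_batch=50, n_genes=300, shift_sd=0.0, seed=3):
        rng = np.random.default_rng(seed)
        cols = [f"s{i}" for i in range(2 * n_per_batch)]
        mat = pd.DataFrame(rng.normal(7, 1, (n_genes, 2 * n_per_batch)), columns=cols)
        batch = np.array(["A"] * n_per_batch + ["B"] * n_per_batch)
        group = np.array(
            (["tumor"] * (n_per_batch // 2) + ["normal"] * (n_per_batch // 2)) * 2
        )
        shifts = rng.normal(2.0, shift_sd, n_genes)
        mat.iloc[:, n_per_batch:] = mat.iloc[:, n_per_batch:].add(shifts, axis=0)
        return mat, batch, group

    def test_single_batch_errors(self):
        mat, batch, group = self._design()
        with pytest.raises(ValueError):
            combat_adjust(mat, ["A"] * len(batch), group)

    def test_singleton_batch_errors(self):
        mat, batch, group = self._design()
        batch = batch.copy()
        batch[:-1] = "A"
        batch[-1] = "C"
        with pytest.raises(ValueError, match="scale"):
            combat_adjust(mat, batch, group)

    def test_confounded_design_rejected(self):
        mat, batch, _ = self._design(n_per_batch=10)
        group = np.array(["tumor"] * 10 + ["normal"] * 10)  # batch == group
        with pytest.raises(ValueError, match="confounded"):
            combat_adjust(mat, batch, group)

    def test_constant_shift_removed_on_average(self):
        # EB shrinkage leaves ~0.5x estimation noise per gene for a shift
        # that is constant across genes; the cross-gene mean residual is ~0
        mat, batch, group = self._design(shift_sd=0.0)
        adj = combat_adjust(mat, batch, group)
        resid = adj.iloc[:, 50:].mean(axis=1) - adj.iloc[:, :50].mean(axis=1)
        assert abs(resid.mean()) < 0.05

    def test_heterogeneous_shifts_removed_per_gene(self):
        mat, batch, group = self._design(shift_sd=2.0)
        adj = combat_adjust(mat, batch, group)
        resid = adj.iloc[:, 50:].mean(axis=1) - adj.iloc[:, :50].mean(axis=1)
        assert resid.abs().mean() < 0.05
        assert resid.abs().max() < 0.2

    def test_group_signal_preserved(self):
        mat, batch, group = self._design(shift_sd=1.0)
        tumor = group == "tumor"
        mat.loc[:, tumor] = mat.loc[:, tumor] + 1.5
        adj = combat_adjust(mat, batch, group)
        diff = adj.loc[:, tumor].mean(axis=1) - adj.loc[:, ~tumor].mean(axis=1)
        assert diff.mean() == pytest.approx(1.5, abs=0.1)

    def test_readjustment_contracts(self):
        # parametric EB is not exactly idempotent (shrinkage re-targets the
        # residual noise) but re-application must change far less than the
        # first pass and far less than the data scale
        mat, batch, group = self._design(shift_sd=1.0)
        adj1 = combat_adjust(mat, batch, group)
        adj2 = combat_adjust(adj1, batch, group)
        change1 = (adj1 - mat).abs().to_numpy().max()
        change2 = (adj2 - adj1).abs().to_numpy().max()
        assert change2 < 0.25 * change1
        assert change2 < 0.3


class TestHarmonize:
    def test_intersection(self):
        c1 = multi_gene_cohort({"A": [1, 2, 3, 4], "B": [2, 3, 4, 5],
                                "C": [0, 1, 0, 1]}, n_tumor=2, label="h1")
        c2 = multi_gene_cohort({"B": [5, 6, 7, 8], "C": [1, 2, 1, 2],
                                "D": [3, 3, 4, 4]}, n_tumor=2, label="h2")
        hset = harmonize_genes([c1, c2])
        assert hset.common_genes == ["B", "C"]
        for c in hset.cohorts:
            assert c.gene_ids == ["B", "C"]

    def test_identical_sets_values_unchanged(self):
        c1 = multi_gene_cohort({"B": [1, 2, 3, 4], "A": [2, 3, 4, 5]},
                               n_tumor=2, label="i1")
        hset = harmonize_genes([c1])
        assert hset.common_genes == ["A", "B"]
        assert hset.cohorts[0].values.loc["B"].tolist() == [1, 2, 3, 4]

    def test_disjoint_sets_error(self):
        c1 = multi_gene_cohort({"A": [1, 2, 1, 2]}, n_tumor=2, label="d1")
        c2 = multi_gene_cohort({"B": [1, 2, 1, 2]}, n_tumor=2, label="d2")
        with pytest.raises(ValueError, match="intersection"):
            harmonize_genes([c1, c2])

    def test_order_invariance(self, small_world):
        hset, _ = small_world
        reversed_set = harmonize_genes(list(reversed(hset.cohorts)))
        assert reversed_set.common_genes == hset.common_genes
        by_label = {c.label: c for c in reversed_set.cohorts}
        for c in hset.cohorts:
            assert by_label[c.label].values.equals(c.values)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            harmonize_genes([])


class TestMergeByPlatform:
    def test_shared_platform_merged_and_adjusted(self):
        truth = make_truth(n_genes=150, n_members=3)
        specs = [
            CohortSpec(10, 10, platform_label="shared", label="m1"),
            CohortSpec(12, 12, platform_label="shared", label="m2"),
            CohortSpec(8, 8, platform_label="solo", label="m3"),
        ]
        cohorts, _ = generate_cohorts(specs, truth, 31)
        # give m2 a strong artificial location offset against m1
        cohorts[1] = cohorts[1].with_values(cohorts[1].values + 3.0)
        merged = merge_by_platform(cohorts)
        labels = sorted(c.label for c in merged)
        assert labels == ["m1+m2", "m3"]
        big = next(c for c in merged if c.label == "m1+m2")
        assert big.n_samples == 44
        # the +3 offset between sources is mostly gone after adjustment
        m1_cols = [s for s in big.sample_ids if s.startswith("m1")]
        m2_cols = [s for s in big.sample_ids if s.startswith("m2")]
        gap = (
            big.values[m2_cols].mean(axis=1) - big.values[m1_cols].mean(axis=1)
        ).mean()
        assert abs(gap) < 0.3
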