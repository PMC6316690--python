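"""Normalization, BH adjustment and the DE screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import _oracles
from conftest import toy_count_matrix
from ricenet import expression as expr
from ricenet.exceptions import EmptyMatrixError, InputError


class TestFilterNoninformative:
    def test_all_zero_rows_removed_order_preserved(self):
        cm = toy_count_matrix(
            [[0, 0, 0], [5, 0, 1], [0, 0, 0], [1, 1, 1], [0, 1, 0]]
        )
        out = expr.filter_noninformative(cm)
        assert out.gene_ids == ["g1", "g3", "g4"]

    def test_single_count_of_one_is_retained(self):
        cm = toy_count_matrix([[0, 0, 1], [2, 2, 2]])
        out = expr.filter_noninformative(cm)
        assert "g0" in out.gene_ids

    def test_empty_result_raises(self):
        cm = toy_count_matrix(np.zeros((3, 4), dtype=int))
        with pytest.raises(EmptyMatrixError):
            expr.filter_noninformative(cm)


class TestSizeFactors:
    def test_identical_samples_get_equal_factors(self):
        cm = toy_count_matrix([[4, 4], [7, 7], [2, 2]])
        f = expr.size_factors(cm)
        assert f.iloc[0] == pytest.approx(f.iloc[1])

    def test_scale_equivariance(self):
        base = np.array([[10, 20], [40, 80], [5, 10], [100, 200]])
        f = expr.size_factors(toy_count_matrix(base))
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)

    def test_matches_median_of_ratios_oracle(self):
        counts = np.array([[10, 20, 30], [5, 6, 7], [100, 90, 80], [1, 2, 3]])
        f = expr.size_factors(toy_count_matrix(counts, stages=["seedling"] * 3))
        expected = _oracles.size_factors(counts)
        np.testing.assert_allclose(f.to_numpy(), expected, rtol=0, atol=1e-12)

    def test_fallback_when_no_gene_is_all_positive(self):
        counts = np.array([[0, 5, 6], [4, 0, 8], [3, 7, 0], [9, 0, 4]])
        with pytest.warns(UserWarning, match="falling back"):
            f = expr.size_factors(toy_count_matrix(counts, stages=["seedling"] * 3))
        assert (f > 0).all()


class TestNormalize:
    def test_unit_factors_are_identity(self):
        cm = toy_count_matrix([[3, 4], [5, 6]])
        f = pd.Series([1.0, 1.0], index=cm.sample_ids)
        pd.testing.assert_frame_equal(expr.normalize(cm, f), cm.counts / 1.0)

    def test_doubling_a_factor_halves_the_column(self):
        cm = toy_count_matrix([[8, 8], [4, 4]])
        f = pd.Series([1.0, 2.0], index=cm.sample_ids)
        out = expr.normalize(cm, f)
        np.testing.assert_allclose(out.iloc[:, 1], cm.counts.iloc[:, 1] / 2.0)

    def test_round_trip_equalizes_scaled_copies(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 100, size=(6, 1)) * 2
        scales = np.array([1.0, 2.0, 0.5, 4.0])
        counts = (base * scales).astype(int)
        cm = toy_count_matrix(counts, stages=["seedling"] * 4)
        out = expr.normalize(cm, expr.size_factors(cm))
        sums = out.sum(axis=0).to_numpy()
        np.testing.assert_allclose(sums, sums[0], rtol=1e-9)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            expr.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_all_equal_inputs_unchanged(self):
        np.testing.assert_allclose(expr.bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(expr.bh_adjust([0.37]), [0.37])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_matches_oracle_and_permutation_equivariance(self, pvals, rnd):
        adjusted = expr.bh_adjust(pvals)
        np.testing.assert_allclose(adjusted, _oracles.bh_adjust(pvals), atol=1e-12)
        assert ((adjusted >= 0) & (adjusted <= 1)).all()
        assert (adjusted >= np.asarray(pvals) - 1e-15).all()
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        shuffled = expr.bh_adjust([pvals[i] for i in perm])
        np.testing.assert_allclose(shuffled, adjusted[perm], atol=1e-12)


class TestDifferentialExpression:
    def _log_expr(self, values, samples):
        genes = pd.Index([f"g{i}" for i in range(len(values))], name="gene")
        return pd.DataFrame(values, index=genes, columns=samples.index)

    def _samples(self, conditions):
        return pd.DataFrame(
            {
                "condition": conditions,
                "stage": ["seedling"] * len(conditions),
                "replicate": range(1, len(conditions) + 1),
            },
            index=pd.Index([f"s{j}" for j in range(len(conditions))], name="sample"),
        )

    def test_identical_groups_give_p_one(self):
        samples = self._samples(["normal", "normal", "stress", "stress"])
        le = self._log_expr([[1.0, 2.0, 1.0, 2.0]], samples)
        out = expr.differential_expression(le, samples, "seedling")
        assert out.loc[0, "p_raw"] == pytest.approx(1.0)
        assert out.loc[0, "log2fc"] == pytest.approx(0.0)

    def test_label_swap_flips_log2fc_sign(self):
        samples = self._samples(["normal", "normal", "stress", "stress"])
        swapped = self._samples(["stress", "stress", "normal", "normal"])
        le = self._log_expr([[1.0, 2.0, 5.0, 6.5]], samples)
        a = expr.differential_expression(le, samples, "seedling")
        b = expr.differential_expression(le, swapped, "seedling")
        assert a.loc[0, "log2fc"] == pytest.approx(-b.loc[0, "log2fc"])
        assert a.loc[0, "p_raw"] == pytest.approx(b.loc[0, "p_raw"])

    def test_zero_variance_equal_means_convention(self):
        samples = self._samples(["normal", "normal", "stress", "stress"])
        le = self._log_expr([[3.0, 3.0, 3.0, 3.0], [3.0, 3.0, 5.0, 5.0]], samples)
        out = expr.differential_expression(le, samples, "seedling")
        assert out.loc[0, "p_raw"] == 1.0
        assert out.loc[1, "p_raw"] == 0.0

    def test_planted_fold_change_is_called_up(self):
        rng = np.random.default_rng(3)
        samples = self._samples(["normal"] * 3 + ["stress"] * 3)
        null = rng.normal(5.0, 0.005, size=(40, 6))
        null[0, 3:] += 2.0  # planted log2fc = 2 on the first gene
        le = self._log_expr(null, samples)
        part = expr.differential_expression(le, samples, "seedling")
        part["p_adj"] = expr.bh_adjust(part["p_raw"].to_numpy())
        row = part[part["gene"] == "g0"].iloc[0]
        assert row["p_adj"] < 0.01
        assert row["log2fc"] == pytest.approx(2.0, abs=0.2)
        assert row["log2fc"] > 0

    def test_too_few_replicates_rejected(self):
        samples = self._samples(["normal", "stress", "stress"])
        le = self._log_expr([[1.0, 2.0, 3.0]], samples)
        with pytest.raises(InputError):
            expr.differential_expression(le, samples, "seedling")


class TestClassifyDE:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "stage", "log2fc", "p_raw", "p_adj"])

    def test_empty_significant_set(self):
        t = self._table([["a", "seedling", 1.0, 0.5, 0.9], ["a", "booting", 1.0, 0.5, 0.9]])
        sets = expr.classify_de(t, alpha=0.01)
        assert sets.union == []

    def test_disjoint_stage_sets_union(self):
        rows = [[f"s{i}", "seedling", 1.0, 0.0, 0.0] for i in range(2)]
        rows += [[f"b{i}", "booting", -1.0, 0.0, 0.0] for i in range(3)]
        sets = expr.classify_de(self._table(rows), alpha=0.01)
        assert len(sets.union) == 5

    def test_overlapping_sets_inclusion_exclusion(self):
        seed = [[f"g{i}", "seedling", 1.0, 0.0, 0.0] for i in range(4)]
        boot = [[f"g{i}", "booting", 1.0, 0.0, 0.0] for i in range(3, 7)]
        sets = expr.classify_de(self._table(seed + boot), alpha=0.01)
        assert len(sets.union) == 7
        assert sets.both == ["g3"]
        assert (
            len(sets.union)
            == len(sets.seedling_only) + len(sets.booting_only) + len(sets.both)
        )


class TestDERecovery:
    def test_planted_de_recall_and_false_positive_rate(self, default_run):
        """At the standard regime the Welch screen recovers the planted
        DE genes in their stage with recall >= 0.8 and keeps the
        false-positive rate among null genes below 5x alpha."""
        res = default_run
        truth = res.truth
        table = res.de_table
        sig = {
            stage: set(part.loc[part["call"] != "ns", "gene"])
            for stage, part in table.groupby("stage")
        }
        hits = total = 0
        for gene, (stage, _, _) in truth.de_genes.items():
            stages = ["seedling", "booting"] if stage == "both" else [stage]
            for s in stages:
                total += 1
                hits += gene in sig[s]
        assert hits / total >= 0.8
        null_genes = set(res.counts.gene_ids) - set(truth.de_genes)
        false_calls = sum(
            1 for s in sig.values() for g in s if g in null_genes
        )
        assert false_calls / (2 * len(null_genes)) <= 5 * 0.01

    def test_union_decomposition_identity(self, default_run):
        sets = default_run.de_sets
        assert len(sets.union) == (
            len(sets.seedling_only) + len(sets.booting_only) + len(sets.both)
        )


def test_read_de_table_round_trip(tmp_path, default_run):
    path = tmp_path / "de.tsv"
    default_run.de_table.to_csv(path, sep="\t", index=False)
    loaded = expr.read_de_table(path)
    assert list(loaded.columns) == list(default_run.de_table.columns)
    assert (loaded["call"] == default_run.de_table["call"]).all()
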