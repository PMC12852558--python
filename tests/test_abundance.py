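"""TPM normalisation, control-relative activity, fold changes, clustering."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from virome_triage.abundance import (
    ExpressionMatrix,
    GroupContrast,
    detect_presence,
    group_fold_change,
    heatmap_matrix,
    prevalence,
    relative_to_controls,
    tpm_from_counts,
)
from virome_triage.io_formats import read_quant_table


def make_matrix(values, controls=(), **kwargs):
    return ExpressionMatrix(values=pd.DataFrame(values), control_ids=frozenset(controls), **kwargs)


class TestTpmFromCounts:
    def test_equal_counts_and_lengths_split_evenly(self):
        assert tpm_from_counts([10, 10], [100, 100]) == pytest.approx([500_000, 500_000])

    def test_length_normalisation(self):
        tpm = tpm_from_counts([10, 10], [100, 200])
        assert tpm == pytest.approx([666_666.67, 333_333.33], rel=1e-6)

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError, match="undefined"):
            tpm_from_counts([0, 0], [100, 100])

    def test_nonpositive_length_error(self):
        with pytest.raises(ValueError, match="length"):
            tpm_from_counts([1, 1], [100, 0])

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1e6, allow_nan=False),
                st.floats(1, 1e5, allow_nan=False),
            ),
            min_size=2,
            max_size=50,
        ).filter(lambda rows: sum(c for c, _ in rows) > 0)
    )
    def test_conservation_sums_to_one_million(self, rows):
        counts = [c for c, _ in rows]
        lengths = [l for _, l in rows]
        assert tpm_from_counts(counts, lengths).sum() == pytest.approx(1e6, abs=1e-3)


class TestFromQuantTables:
    QUANT = "Name\tLength\tNumReads\nvir1\t1000\t{v}\nACT7\t1500\t300\nbulk\t2000\t5000\n"

    def test_recomputed_columns_sum_to_one_million(self):
        tables = {
            "L1": read_quant_table(io.StringIO(self.QUANT.format(v=10))),
            "L2": read_quant_table(io.StringIO(self.QUANT.format(v=40))),
        }
        m = ExpressionMatrix.from_quant_tables(tables, control_ids=["ACT7"])
        assert m.values.sum(axis=0).to_numpy() == pytest.approx([1e6, 1e6], abs=1e-3)

    def test_mismatched_feature_sets_rejected(self):
        other = "Name\tLength\tNumReads\nonly\t100\t5\n"
        tables = {
            "L1": read_quant_table(io.StringIO(self.QUANT.format(v=10))),
            "L2": read_quant_table(io.StringIO(other)),
        }
        with pytest.raises(ValueError, match="differ"):
            ExpressionMatrix.from_quant_tables(tables)

    def test_unknown_control_id_rejected(self):
        tables = {"L1": read_quant_table(io.StringIO(self.QUANT.format(v=10)))}
        with pytest.raises(ValueError, match="control"):
            ExpressionMatrix.from_quant_tables(tables, control_ids=["nope"])


class TestRelativeToControls:
    def test_ratio_to_mean_of_controls(self):
        m = make_matrix(
            {"L1": {"vir": 40.0, "c1": 10.0, "c2": 30.0, "c3": 20.0}},
            controls=["c1", "c2", "c3"],
        )
        assert relative_to_controls(m, "vir")["L1"] == pytest.approx(2.0)

    def test_zero_control_mean_gives_missing_only_there(self):
        m = make_matrix(
            {
                "L1": {"vir": 40.0, "c1": 20.0},
                "L2": {"vir": 40.0, "c1": 0.0},
            },
            controls=["c1"],
        )
        ratio = relative_to_controls(m, "vir")
        assert ratio["L1"] == pytest.approx(2.0)
        assert np.isnan(ratio["L2"])

    def test_control_feature_is_relative_to_the_mean_not_one(self):
        m = make_matrix(
            {"L1": {"c1": 10.0, "c2": 30.0}}, controls=["c1", "c2"]
        )
        assert relative_to_controls(m, "c1")["L1"] == pytest.approx(0.5)

    def test_absent_feature_is_error(self):
        m = make_matrix({"L1": {"c1": 1.0}}, controls=["c1"])
        with pytest.raises(KeyError):
            relative_to_controls(m, "ghost")


class TestPresence:
    def test_threshold_boundary(self):
        m = make_matrix({"L1": {"a": 0.99, "b": 1.0}})
        calls = detect_presence(m, tpm_threshold=1.0)
        assert not calls.loc["a", "L1"] and calls.loc["b", "L1"]

    def test_threshold_zero_marks_everything_present(self):
        m = make_matrix({"L1": {"a": 0.0}})
        assert detect_presence(m, tpm_threshold=0.0).loc["a", "L1"]

    def test_all_zero_row_has_zero_prevalence(self):
        m = make_matrix({"L1": {"a": 0.0}, "L2": {"a": 0.0}})
        assert prevalence(m).loc["a"] == 0


class TestGroupFoldChange:
    def test_mean_ratio(self):
        m = make_matrix(
            {"A1": {"v": 224.0}, "A2": {"v": 224.0}, "B1": {"v": 2.0}, "B2": {"v": 2.0}}
        )
        contrast = GroupContrast(frozenset({"A1", "A2"}), frozenset({"B1", "B2"}))
        assert group_fold_change(m, contrast)["v"] == pytest.approx(112.0)

    def test_zero_denominator_without_pseudocount_is_missing(self):
        m = make_matrix({"A1": {"v": 5.0}, "B1": {"v": 0.0}})
        contrast = GroupContrast(frozenset({"A1"}), frozenset({"B1"}))
        assert np.isnan(group_fold_change(m, contrast)["v"])

    def test_pseudocount_neutral_element(self):
        m = make_matrix({"A1": {"v": 0.0}, "B1": {"v": 0.0}})
        contrast = GroupContrast(frozenset({"A1"}), frozenset({"B1"}))
        assert group_fold_change(m, contrast, pseudocount=1.0)["v"] == pytest.approx(1.0)

    def test_scale_invariance(self):
        base = {"A1": {"v": 30.0}, "A2": {"v": 50.0}, "B1": {"v": 4.0}, "B2": {"v": 6.0}}
        contrast = GroupContrast(frozenset({"A1", "A2"}), frozenset({"B1", "B2"}))
        f1 = group_fold_change(make_matrix(base), contrast)["v"]
        scaled = {k: {"v": 7.0 * v["v"]} for k, v in base.items()}
        f2 = group_fold_change(make_matrix(scaled), contrast)["v"]
        assert f1 == pytest.approx(f2)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            GroupContrast(frozenset({"A1"}), frozenset({"A1"}))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            GroupContrast(frozenset(), frozenset({"B1"}))


class TestHeatmapMatrix:
    def test_identical_rows_are_adjacent_leaves(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            rng.uniform(0, 100, size=(4, 6)),
            index=["a", "b", "c", "d"],
            columns=[f"L{i}" for i in range(6)],
        )
        data.loc["d"] = data.loc["a"]
        m = ExpressionMatrix(values=data)
        _, _, leaves = heatmap_matrix(m)
        pos = {name: i for i, name in enumerate(leaves)}
        assert abs(pos["a"] - pos["d"]) == 1

    def test_log_transform_with_pseudocount(self):
        m = make_matrix({"L1": {"a": 0.0, "b": 9.0}, "L2": {"a": 99.0, "b": 0.0}})
        heat, _, _ = heatmap_matrix(m, pseudocount=1.0)
        assert heat.loc["a", "L1"] == pytest.approx(0.0)
        assert heat.loc["a", "L2"] == pytest.approx(2.0)
        assert heat.loc["b", "L1"] == pytest.approx(1.0)

    def test_single_row_trivial_order(self):
        m = make_matrix({"L1": {"a": 1.0}, "L2": {"a": 2.0}})
        heat, link, leaves = heatmap_matrix(m)
        assert link is None and leaves == ["a"]

    def test_planted_correlation_blocks_separate(self):
        """Two planted correlation blocks end up in disjoint leaf runs."""
        rng = np.random.default_rng(42)
        base1 = rng.uniform(1, 100, size=12)
        base2 = rng.uniform(1, 100, size=12)
        rows = {}
        for i in range(5):
            rows[f"x{i}"] = base1 * rng.uniform(0.9, 1.1, size=12)
        for i in range(5):
            rows[f"y{i}"] = base2 * rng.uniform(0.9, 1.1, size=12)
        data = pd.DataFrame(rows).T
        data.columns = [f"L{i}" for i in range(12)]
        m = ExpressionMatrix(values=data)

        # oracle: within-block correlation distance is below between-block
        logged = np.log10(data.to_numpy() + 1)
        corr = np.corrcoef(logged)
        within = [corr[i, j] for i in range(5) for j in range(i + 1, 5)]
        between = [corr[i, j] for i in range(5) for j in range(5, 10)]
        assert min(within) > max(between)

        _, _, leaves = heatmap_matrix(m)
        first_block = {name[0] for name in leaves[:5]}
        second_block = {name[0] for name in leaves[5:]}
        assert first_block in ({"x"}, {"y"}) and first_block != second_block

    def test_zero_variance_row_sits_apart(self, caplog):
        rng = np.random.default_rng(7)
        data = pd.DataFrame(
            rng.uniform(1, 50, size=(3, 5)), index=["a", "b", "flat"]
        )
        data.loc["flat"] = 3.0
        with caplog.at_level("INFO", logger="virome_triage.abundance"):
            _, link, leaves = heatmap_matrix(ExpressionMatrix(values=data))
        assert set(leaves) == {"a", "b", "flat"}
        assert any("zero-variance" in rec.message for rec in caplog.records)

    def test_empty_matrix_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            heatmap_matrix(ExpressionMatrix(values=pd.DataFrame()))
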