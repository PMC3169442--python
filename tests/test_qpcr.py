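import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ervprofiler import (
    DataError,
    ParameterError,
    UndefinedStatisticError,
    chip_enrichment,
    delta_delta_ct,
    read_ct_table,
    replicate_summary,
    two_tailed_ttest,
)

from _oracles import permutation_ttest_p


def _expression_table(rows):
    return pd.DataFrame(rows, columns=["sample", "target", "replicate", "ct"])


def _triplicate(sample, target, ct):
    return [(sample, target, i + 1, ct) for i in range(3)]


class TestDeltaDeltaCt:
    def test_three_cycles_lower_is_eightfold(self):
        table = _expression_table(
            _triplicate("wt", "MusD", 25.0) + _triplicate("wt", "Actb", 16.0)
            + _triplicate("ko", "MusD", 22.0) + _triplicate("ko", "Actb", 16.0)
        )
        result = delta_delta_ct(table, "MusD", "Actb", "wt")
        folds = dict(zip(result["sample"], result["fold"]))
        assert folds["wt"] == 1.0
        assert folds["ko"] == pytest.approx(8.0)

    def test_identical_cts_give_unit_fold_everywhere(self):
        table = _expression_table(
            _triplicate("a", "t", 24.0) + _triplicate("a", "ref", 16.0)
            + _triplicate("b", "t", 24.0) + _triplicate("b", "ref", 16.0)
        )
        result = delta_delta_ct(table, "t", "ref", "a")
        assert np.allclose(result["fold"], 1.0)

    def test_machine_offset_cancels(self, rng):
        base = _expression_table(
            [("wt", "t", i, 24 + rng.normal(0, 0.1)) for i in range(3)]
            + [("wt", "ref", i, 16 + rng.normal(0, 0.1)) for i in range(3)]
            + [("ko", "t", i, 21 + rng.normal(0, 0.1)) for i in range(3)]
            + [("ko", "ref", i, 16 + rng.normal(0, 0.1)) for i in range(3)]
        )
        shifted = base.assign(ct=base["ct"] + 5.0)
        a = delta_delta_ct(base, "t", "ref", "wt")
        b = delta_delta_ct(shifted, "t", "ref", "wt")
        assert np.allclose(a["fold"], b["fold"])

    def test_missing_reference_gene_is_a_data_error(self):
        table = _expression_table(_triplicate("wt", "t", 24.0))
        with pytest.raises(DataError):
            delta_delta_ct(table, "t", "ref", "wt")

    def test_single_replicate_reports_fold_but_no_sd(self):
        table = _expression_table(
            [("wt", "t", 1, 24.0), ("wt", "ref", 1, 16.0),
             ("ko", "t", 1, 23.0), ("ko", "ref", 1, 16.0)]
        )
        result = delta_delta_ct(table, "t", "ref", "wt")
        ko = result[result["sample"] == "ko"].iloc[0]
        assert ko["fold"] == pytest.approx(2.0) and np.isnan(ko["sd"])

    def test_table_io_round_trip(self, tmp_path):
        table = _expression_table(
            _triplicate("wt", "t", 24.0) + _triplicate("wt", "ref", 16.0)
        )
        path = tmp_path / "ct.tsv"
        table.to_csv(path, sep="\t", index=False)
        loaded = read_ct_table(path)
        pd.testing.assert_frame_equal(
            loaded, table.astype({"ct": float}), check_dtype=False
        )


def _chip_table(rows):
    return pd.DataFrame(rows, columns=["sample", "assay", "target", "replicate", "ct"])


def _chip_rows(sample, assay, target, ct):
    return [(sample, assay, target, i + 1, ct) for i in range(3)]


class TestChipEnrichment:
    def test_equal_ct_is_one_hundred_percent_of_input(self):
        table = _chip_table(
            _chip_rows("wt", "H3K9me3", "IAP", 25.0)
            + _chip_rows("wt", "input", "IAP", 25.0)
        )
        result = chip_enrichment(table, "H3K9me3")
        assert result["enrichment"].iloc[0] == pytest.approx(100.0)

    def test_three_cycles_later_is_one_eighth_of_input(self):
        table = _chip_table(
            _chip_rows("wt", "H3K9me3", "IAP", 28.0)
            + _chip_rows("wt", "input", "IAP", 25.0)
        )
        result = chip_enrichment(table, "H3K9me3")
        assert result["enrichment"].iloc[0] == pytest.approx(12.5)

    def test_relative_to_h3_halves_when_the_mark_drops_twofold(self):
        def line(sample, mark_ct):
            return (
                _chip_rows(sample, "H4K20me3", "majsat", mark_ct)
                + _chip_rows(sample, "H3", "majsat", 24.0)
                + _chip_rows(sample, "input", "majsat", 22.0)
            )

        table = _chip_table(line("wt", 25.0) + line("cbx5_ko", 26.0))
        result = chip_enrichment(table, "H4K20me3", mode="relative_to_h3")
        values = dict(zip(result["sample"], result["enrichment"]))
        assert values["cbx5_ko"] / values["wt"] == pytest.approx(0.5)

    def test_input_dilution_correction(self):
        table = _chip_table(
            _chip_rows("wt", "H3K9me3", "IAP", 25.0)
            + _chip_rows("wt", "input", "IAP", 25.0)
        )
        result = chip_enrichment(table, "H3K9me3", input_fraction=0.1)
        # input was 10% of chromatin: adjusted input Ct drops by log2(10)
        assert result["enrichment"].iloc[0] == pytest.approx(10.0)

    def test_missing_input_is_a_data_error(self):
        table = _chip_table(_chip_rows("wt", "H3K9me3", "IAP", 25.0))
        with pytest.raises(DataError):
            chip_enrichment(table, "H3K9me3")

    def test_enrichment_is_monotone_decreasing_in_ip_ct(self):
        values = []
        for ip_ct in (24.0, 25.0, 26.5, 28.0):
            table = _chip_table(
                _chip_rows("wt", "mark", "IAP", ip_ct)
                + _chip_rows("wt", "input", "IAP", 23.0)
            )
            values.append(chip_enrichment(table, "mark")["enrichment"].iloc[0])
        assert all(a > b for a, b in zip(values, values[1:]))


class TestReplicateSummary:
    def test_constant_replicates(self):
        assert replicate_summary([2, 2, 2]) == (2.0, 0.0)

    def test_hand_computed_sd(self):
        mean, sd = replicate_summary([1, 2, 3])
        assert (mean, sd) == (2.0, 1.0)

    def test_single_value_has_no_sd(self):
        mean, sd = replicate_summary([5.0])
        assert mean == 5.0 and np.isnan(sd)

    def test_empty_input_is_a_data_error(self):
        with pytest.raises(DataError):
            replicate_summary([])

    def test_matches_numpy_reference(self, rng):
        for _ in range(20):
            values = rng.normal(size=int(rng.integers(2, 12)))
            mean, sd = replicate_summary(values)
            assert mean == pytest.approx(values.mean(), abs=1e-12)
            assert sd == pytest.approx(values.std(ddof=1), abs=1e-12)


class TestTTest:
    def test_identical_groups_are_not_significant(self):
        result = two_tailed_ttest([1, 2, 3], [1, 2, 3])
        assert result.t == 0.0 and result.p == pytest.approx(1.0)
        assert result.flag == "ns"

    def test_large_shift_is_doubly_significant(self):
        result = two_tailed_ttest([1, 2, 3], [101, 102, 103])
        assert result.p < 0.01 and result.flag == "**"

    def test_symmetry_in_group_order(self):
        a, b = [1.0, 2.5, 3.0], [2.0, 4.0, 5.0]
        ab = two_tailed_ttest(a, b)
        ba = two_tailed_ttest(b, a)
        assert ab.p == ba.p and ab.t == -ba.t

    def test_zero_pooled_variance_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            two_tailed_ttest([2, 2, 2], [2, 2, 2])

    def test_matches_reference_implementation_to_1e9(self, rng):
        for _ in range(50):
            a = rng.normal(size=int(rng.integers(2, 10)))
            b = rng.normal(loc=rng.normal(), size=int(rng.integers(2, 10)))
            mine = two_tailed_ttest(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert mine.t == pytest.approx(ref.statistic, abs=1e-9)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-9)
            welch = two_tailed_ttest(a, b, equal_var=False)
            ref_w = stats.ttest_ind(a, b, equal_var=False)
            assert welch.p == pytest.approx(ref_w.pvalue, abs=1e-9)

    def test_agrees_with_permutation_oracle_on_three_vs_three(self, rng):
        """On 3-vs-3 inputs the exact permutation p over all 20 label
        assignments bounds and tracks the t-test p-value."""
        perm_ps, t_ps = [], []
        for _ in range(20):
            a = list(rng.normal(size=3))
            b = list(rng.normal(loc=2.0, size=3))
            perm_ps.append(permutation_ttest_p(a, b))
            t_ps.append(two_tailed_ttest(a, b).p)
        # the permutation null on 20 assignments is granular (minimum 0.1),
        # so require closeness plus rank concordance rather than equality
        assert np.all(np.abs(np.array(perm_ps) - np.array(t_ps)) < 0.25)
        # many pairs tie at the granular minimum 0.1, which caps attainable
        # rank correlation; require clear positive concordance
        assert stats.spearmanr(perm_ps, t_ps).statistic > 0.6

    def test_tiny_groups_are_rejected(self):
        with pytest.raises(ParameterError):
            two_tailed_ttest([1.0], [1.0, 2.0])
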