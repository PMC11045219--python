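"""Splicing index arithmetic, filters, fold changes and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from exonsi.counts_io import CountTable
from exonsi.errors import DataError, ParameterError
from exonsi.splicing import (compute_fano, compute_rpkm,
                             compute_splicing_index, filter_exons, ma_summary,
                             set_overlap_percent, si_log2fc, top_n_by_fc)


def _copy(table: CountTable) -> CountTable:
    return CountTable(features=table.features.copy(),
                      counts=table.counts.copy(),
                      conditions=dict(table.conditions))


class TestRpkm:
    def test_hand_value(self):
        assert compute_rpkm(500, 2000, 1e6) == pytest.approx(250.0)

    def test_zero_counts_give_zero(self):
        assert compute_rpkm(0, 2000, 1e6) == 0.0

    def test_doubling_library_halves_rpkm(self):
        assert compute_rpkm(10, 100, 2e6) == compute_rpkm(10, 100, 1e6) / 2

    def test_zero_library_rejected(self):
        with pytest.raises(ParameterError):
            compute_rpkm(10, 100, 0)


class TestSplicingIndex:
    def test_hand_value(self, toy_tables):
        exon, gene = toy_tables
        table = compute_splicing_index(exon, gene)
        # E1: (10/100) / (100/1000) = 1.0 in control_1
        assert table.si.loc["E1", "control_1"] == pytest.approx(1.0)

    def test_zero_exon_reads_give_zero_si(self, toy_tables):
        exon, gene = toy_tables
        table = compute_splicing_index(exon, gene)
        assert table.si.loc["E4", "knockdown_1"] == 0.0

    def test_library_size_cancels(self, toy_tables):
        """Multiplying every count in one sample by 7 leaves SI unchanged."""
        exon, gene = toy_tables
        before = compute_splicing_index(exon, gene).si
        exon.counts["control_2"] *= 7
        gene.counts["control_2"] *= 7
        after = compute_splicing_index(exon, gene).si
        pd.testing.assert_frame_equal(before, after)

    @settings(derandomize=True, max_examples=25, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(scale=st.integers(min_value=1, max_value=1000),
           sample=st.integers(min_value=0, max_value=5))
    def test_si_invariant_under_any_sample_rescaling(self, toy_tables, scale,
                                                     sample):
        exon, gene = (_copy(t) for t in toy_tables)
        before = compute_splicing_index(exon, gene).si
        col = exon.counts.columns[sample]
        exon.counts[col] *= scale
        gene.counts[col] *= scale
        after = compute_splicing_index(exon, gene).si
        pd.testing.assert_frame_equal(before, after)

    def test_unknown_gene_rejected(self, toy_tables):
        exon, gene = toy_tables
        exon.features.loc["E1", "gene_id"] = "G999"
        with pytest.raises(DataError):
            compute_splicing_index(exon, gene)


class TestFilters:
    def test_min_reads_needs_one_full_condition(self, toy_tables):
        exon, _ = toy_tables
        flags = filter_exons(exon)
        # (6,7,8) in control, (0,0,0) in knockdown: kept
        assert flags.loc["E4", "pass_min_reads"]
        # (5,9,9)/(4,9,9): 5 is not > 5, removed
        assert not flags.loc["E5", "pass_min_reads"]

    def test_single_exon_gene_removed(self, toy_tables):
        exon, _ = toy_tables
        flags = filter_exons(exon)
        assert not flags.loc["E3", "pass_multi_exon"]
        assert flags.loc["E1", "pass_multi_exon"]

    @settings(derandomize=True, max_examples=25, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(extra=st.integers(min_value=0, max_value=100))
    def test_adding_reads_never_removes_an_exon(self, toy_tables, extra):
        exon = _copy(toy_tables[0])
        kept_before = filter_exons(exon)["pass_min_reads"]
        exon.counts.loc["E5"] += extra
        kept_after = filter_exons(exon)["pass_min_reads"]
        assert kept_after["E5"] >= kept_before["E5"]


class TestFano:
    @pytest.mark.parametrize("values,expected", [
        ((0.10, 0.10, 0.10), 0.0),
        ((0.099, 0.100, 0.101), 1e-5),
        ((0.05, 0.10, 0.15), 0.025),
    ])
    def test_hand_values(self, values, expected):
        assert compute_fano(values) == pytest.approx(expected, rel=1e-9)

    def test_zero_mean_is_undefined(self):
        assert np.isnan(compute_fano((0.0, 0.0, 0.0)))


class TestFoldChange:
    def test_equal_means_give_zero(self):
        assert si_log2fc(0.5, 0.5) == pytest.approx(0.0)

    def test_twofold_without_pseudocount(self):
        assert si_log2fc(0.2, 0.1, pseudocount=0) == pytest.approx(1.0)

    def test_zero_control_with_pseudocount(self):
        expected = np.log2(1e-3) - np.log2(0.101)
        assert si_log2fc(0.0, 0.1, pseudocount=1e-3) == pytest.approx(expected)
        assert expected == pytest.approx(-6.66, abs=0.01)

    def test_negative_mean_rejected(self):
        with pytest.raises(DataError):
            si_log2fc(-0.1, 0.5)


class TestSummaries:
    def test_ma_percentages(self):
        above, below = ma_summary([0.6, -0.6, 0.0, 0.2, -1.0], threshold=0.5)
        assert (above, below) == (20.0, 40.0)

    def test_all_zero_fold_changes(self):
        assert ma_summary([0.0, 0.0]) == (0.0, 0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            ma_summary([])

    def test_overlap_percent(self):
        assert set_overlap_percent({"a", "b", "c", "d"}, {"a", "b"}) == 50.0
        assert set_overlap_percent({"a"}, {"a", "b"}) == 100.0
        assert set_overlap_percent({"a"}, {"b"}) == 0.0

    def test_empty_first_set_rejected(self):
        with pytest.raises(ParameterError):
            set_overlap_percent(set(), {"a"})


class TestTopN:
    def test_top_exons_are_planted(self, planted_dataset):
        (exon, gene, truth), config = planted_dataset
        table = compute_splicing_index(exon, gene, fano_max=np.inf)
        top = top_n_by_fc(table, n=20, direction="up")
        truth = truth.set_index("exon_id")
        assert (truth.loc[top, "direction"] == "up").mean() >= 0.9

    def test_n_larger_than_table_rejected(self, toy_tables):
        table = compute_splicing_index(*toy_tables)
        with pytest.raises(ParameterError):
            top_n_by_fc(table, n=10 ** 6)


def test_planted_sign_agreement(planted_dataset):
    """log2FC sign matches the planted direction for large-effect exons."""
    (exon, gene, truth), config = planted_dataset
    table = compute_splicing_index(exon, gene)
    truth = truth.set_index("exon_id")
    planted = truth.index[truth["direction"] != "null"]
    fc = table.summary.loc[planted, "log2fc"]
    expected_sign = np.where(truth.loc[planted, "direction"] == "up", 1, -1)
    assert (np.sign(fc) == expected_sign).mean() >= 0.95
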