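"""Moderated statistic and randomization q-values, with an enumeration oracle."""

import statistics
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from exonsi.diffstats import (call_significant, compute_q, exon_differential,
                              moderated_d, permutation_null)
from exonsi.errors import ParameterError
from exonsi.simulate import make_null_exon_dataset

LABELS = ["A", "A", "A", "B", "B", "B"]


# -- independent oracle: plain-python enumeration of all label assignments --

def oracle_d(g1, g2, s0):
    n1, n2 = len(g1), len(g2)
    ss1 = sum((x - statistics.mean(g1)) ** 2 for x in g1)
    ss2 = sum((x - statistics.mean(g2)) ** 2 for x in g2)
    s = ((1 / n1 + 1 / n2) * (ss1 + ss2) / (n1 + n2 - 2)) ** 0.5
    return (statistics.mean(g1) - statistics.mean(g2)) / (s + s0)


def oracle_q(rows, s0=0.1):
    """q per exon from exhaustive 3-vs-3 label enumeration, by the book."""
    observed = [oracle_d(r[:3], r[3:], s0) for r in rows]
    null_columns = []
    for g1_cols in combinations(range(6), 3):
        g2_cols = [c for c in range(6) if c not in g1_cols]
        null_columns.append([oracle_d([r[c] for c in g1_cols],
                                      [r[c] for c in g2_cols], s0)
                             for r in rows])
    q_raw = []
    for d_i in observed:
        n_obs = sum(abs(d) >= abs(d_i) for d in observed)
        per_perm = [sum(abs(d) >= abs(d_i) for d in col)
                    for col in null_columns]
        q_raw.append(min(max(statistics.median(per_perm) / n_obs, 0.0), 1.0))
    # step-up: smallest estimate over thresholds at or below |d_i|
    q = []
    for i, d_i in enumerate(observed):
        q.append(min(q_raw[j] for j in range(len(rows))
                     if abs(observed[j]) <= abs(d_i)))
    return q


class TestModeratedD:
    def test_identical_groups_give_zero(self):
        assert moderated_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_zero_variance_reduces_to_shift_over_s0(self):
        assert moderated_d([2, 2, 2], [1, 1, 1], s0=0.1) == pytest.approx(10.0)

    def test_hand_value_with_pooled_se(self):
        d = moderated_d([0, 1, 2], [4, 5, 6], s0=0.1)
        assert d == pytest.approx(-4.0 / (np.sqrt(2 / 3) + 0.1), rel=1e-9)
        assert d == pytest.approx(-4.364, abs=5e-4)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 100, 3))
        assert np.allclose(moderated_d(a, b), -moderated_d(b, a))

    def test_small_group_rejected(self):
        with pytest.raises(ParameterError):
            moderated_d([1.0], [1.0, 2.0])

    def test_large_s0_kills_every_statistic(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, 50, 3))
        assert np.abs(moderated_d(a, b, s0=1e9)).max() < 1e-6


class TestPermutationNull:
    def test_three_vs_three_is_exhaustive_with_identity(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(5, 6))
        null = permutation_null(values, LABELS)
        assert null.shape == (5, 20)
        d_obs = moderated_d(values[:, :3], values[:, 3:])
        assert any(np.allclose(null[:, b], d_obs) for b in range(20))

    def test_constant_exon_is_null_everywhere(self):
        values = np.full((1, 6), 3.14)
        for scheme in ("label-permutation", "gaussian"):
            null = permutation_null(values, LABELS, scheme=scheme, seed=0)
            assert np.allclose(null, 0.0)

    def test_gaussian_scheme_is_seed_reproducible(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(10, 6))
        a = permutation_null(values, LABELS, scheme="gaussian", seed=42)
        b = permutation_null(values, LABELS, scheme="gaussian", seed=42)
        assert np.array_equal(a, b)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ParameterError):
            permutation_null(np.zeros((2, 6)), LABELS, scheme="bootstrap")


class TestQValues:
    def test_runaway_exon_gets_q_near_zero(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0, 0.01, size=(50, 6))
        values[0, :3] += 100.0  # one exon far beyond any null
        null = permutation_null(values, LABELS)
        d = moderated_d(values[:, :3], values[:, 3:])
        q = compute_q(d, null)
        assert q[0] < 0.05
        assert q[0] == q.min()

    def test_matches_enumeration_oracle_on_toy_instance(self):
        rng = np.random.default_rng(5)
        rows = rng.normal(0, 1, size=(5, 6))
        rows[0, :3] += 3.0
        expected = oracle_q([list(r) for r in rows])
        d = moderated_d(rows[:, :3], rows[:, 3:])
        q = compute_q(d, permutation_null(rows, LABELS))
        assert np.allclose(q, expected, atol=1e-12)

    def test_q_monotone_in_abs_d(self):
        table = make_null_exon_dataset(500, seed=6)
        result = exon_differential(table, LABELS)
        order = np.argsort(-np.abs(result["d"].to_numpy()))
        q_sorted = result["q"].to_numpy()[order]
        assert (np.diff(q_sorted) >= -1e-12).all()

    def test_antisymmetry_of_condition_swap(self):
        table = make_null_exon_dataset(100, seed=7)
        fwd = exon_differential(table, LABELS)
        swapped_cols = list(table.columns[3:]) + list(table.columns[:3])
        swapped = exon_differential(table[swapped_cols], LABELS)
        assert np.allclose(fwd["d"], -swapped["d"])
        assert np.allclose(fwd["q"], swapped["q"])


class TestCalls:
    def test_no_calls_when_all_q_high(self):
        result = pd.DataFrame({"d": [0.1, -0.2], "q": [0.9, 0.8],
                               "log2fc": [0.1, -0.2]}, index=["E1", "E2"])
        up, down = call_significant(result)
        assert up == set() and down == set()

    def test_partition_of_significant_set(self):
        table = make_null_exon_dataset(300, seed=8)
        values = table.to_numpy()
        values[:30, :3] += 1.0
        values[30:60, 3:] += 1.0
        df = pd.DataFrame(values, index=table.index, columns=table.columns)
        result = exon_differential(df, LABELS)
        result["log2fc"] = result["d"]
        up, down = call_significant(result, q_max=0.05)
        assert up.isdisjoint(down)
        assert up | down == set(result.index[result["q"] < 0.05])


def test_null_fraction_beyond_null_quantile_is_calibrated():
    """About 5% of null exons exceed the null ensemble's 95th percentile of |d|."""
    table = make_null_exon_dataset(8457, seed=9)
    d = moderated_d(table.to_numpy()[:, :3], table.to_numpy()[:, 3:])
    null = permutation_null(table, LABELS)
    cutoff = np.quantile(np.abs(null), 0.95)
    frac = np.mean(np.abs(d) > cutoff)
    se = np.sqrt(0.05 * 0.95 / 8457)
    assert abs(frac - 0.05) < 4 * se
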