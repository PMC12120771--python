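import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tflens import (
    ExpressionMatrix,
    column_stats,
    compute_internal_z,
    group_scores,
    trimmed_mean,
)
from tflens.zscore import trim_counts

from conftest import random_matrix


def trimmean_oracle(values, trim_total):
    """Independent sort-and-drop reference (spreadsheet TRIMMEAN semantics).

    The mean uses the correctly rounded sum so the comparison tests the
    truncation rule, not floating-point accumulation order.
    """
    arr = sorted(values)
    k = int(np.floor(len(arr) * trim_total / 2.0))
    kept = arr[k: len(arr) - k]
    return math.fsum(kept) / len(kept)


class TestColumnStats:
    def test_simple_column(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=list("abc")))
        out = column_stats(m)
        assert out.loc["s", "mean"] == 2.0
        assert out.loc["s", "sd"] == 1.0

    def test_constant_column_flagged(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [7.0, 7.0, 7.0]}, index=list("abc")))
        assert bool(column_stats(m).loc["s", "degenerate"])

    def test_matches_two_pass_oracle(self, rng):
        x = rng.lognormal(size=50)
        m = ExpressionMatrix(pd.DataFrame({"s": x}, index=[f"g{i}" for i in range(50)]))
        out = column_stats(m)
        mean = sum(x) / len(x)
        sd = (sum((v - mean) ** 2 for v in x) / (len(x) - 1)) ** 0.5
        assert abs(out.loc["s", "mean"] - mean) <= 1e-12
        assert abs(out.loc["s", "sd"] - sd) <= 1e-12


class TestInternalZ:
    def test_forced_example(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=list("abc")))
        z = compute_internal_z(m, log2_transform=False)
        np.testing.assert_allclose(z.z["s"], [-1.0, 0.0, 1.0])

    def test_affine_invariance_per_column(self, rng):
        m = random_matrix(rng, n_genes=30, n_samples=4)
        shifted = ExpressionMatrix(m.values * 3.5 + 11.0)
        z0 = compute_internal_z(m, log2_transform=False)
        z1 = compute_internal_z(shifted, log2_transform=False)
        np.testing.assert_allclose(z0.z, z1.z, atol=1e-12)

    def test_normalization_contract(self, rng):
        m = random_matrix(rng, n_genes=200, n_samples=10)
        z = compute_internal_z(m).z.to_numpy()
        assert np.abs(z.mean(axis=0)).max() < 1e-9
        assert np.abs(z.std(axis=0, ddof=1) - 1).max() < 1e-9

    def test_log2_transform_applied_first(self, rng):
        m = random_matrix(rng, n_genes=40, n_samples=3)
        z = compute_internal_z(m, log2_transform=True)
        logged = ExpressionMatrix(np.log2(m.values + 1), log_transformed=True)
        z_manual = compute_internal_z(logged, log2_transform=False)
        np.testing.assert_allclose(z.z, z_manual.z, atol=1e-12)
        assert z.provenance["log2_transform"] is True

    def test_zero_variance_column_errors_then_drops(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]},
                          index=list("abc"))
        m = ExpressionMatrix(df)
        with pytest.raises(ValueError, match="flat"):
            compute_internal_z(m, log2_transform=False)
        z = compute_internal_z(m, log2_transform=False, drop_degenerate=True)
        assert z.sample_ids == ["ok"]
        assert z.provenance["dropped_columns"] == ["flat"]


class TestTrimmedMean:
    @pytest.mark.parametrize(
        "values, trim, expected",
        [
            ([5, 5, 5, 5, 5], 0.2, 5.0),
            ([3.7], 0.5, 3.7),  # single-sample timepoint: k = 0
            ([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], 0.2, 5.5),  # drop 1 and 100
        ],
    )
    def test_examples(self, values, trim, expected):
        assert trimmed_mean(values, trim) == pytest.approx(expected, abs=1e-12)

    def test_zero_trim_is_plain_mean(self, rng):
        x = rng.normal(size=17)
        assert trimmed_mean(x, 0.0) == pytest.approx(x.mean(), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            trimmed_mean([])
        with pytest.raises(ValueError):
            trimmed_mean([1.0, 2.0], trim_total=1.0)

    @settings(derandomize=True, max_examples=300)
    @given(
        values=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50),
        trim=st.floats(0.0, 0.99),
    )
    def test_matches_sort_and_slice_oracle(self, values, trim):
        assert trimmed_mean(values, trim) == trimmean_oracle(values, trim)

    @settings(derandomize=True, max_examples=200)
    @given(values=st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=40))
    def test_matches_scipy_trim_mean(self, values):
        # scipy cuts floor(prop*n) per side: identical truncation rule at 0.2
        expected = stats.trim_mean(values, 0.1)
        assert trimmed_mean(values, 0.2) == pytest.approx(expected, abs=1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(
        values=st.lists(st.floats(-100, 100), min_size=1, max_size=30),
        trim=st.floats(0.0, 0.99),
    )
    def test_bounded_by_min_and_max(self, values, trim):
        tm = trimmed_mean(values, trim)
        assert min(values) - 1e-9 <= tm <= max(values) + 1e-9

    def test_monotone_in_retained_value(self, rng):
        x = rng.normal(size=11)
        base = trimmed_mean(x, 0.2)
        x2 = np.sort(x).copy()
        x2[5] += 1.0  # bump the median value, always retained
        assert trimmed_mean(x2, 0.2) >= base

    def test_trim_counts_excel_rule(self):
        # total excluded = n*trim rounded down to the nearest even integer
        for n in range(1, 51):
            k, S = trim_counts(n, 0.2)
            assert k == int(np.floor(0.1 * n))
            assert S == n - 2 * k >= 1


class TestGroupScores:
    def test_tiny_example_no_trim_possible(self):
        z = pd.DataFrame(
            [[0.9, 1.1, -1.0, -1.2]],
            index=["TF1"],
            columns=["a1", "a2", "n1", "n2"],
        )
        from tflens.zscore import InternalZMatrix

        labels = {"a1": "ADENO", "a2": "ADENO", "n1": "NEPC", "n2": "NEPC"}
        table = group_scores(InternalZMatrix(z), labels, 0.2)
        assert table.loc["TF1", "Z_ad"] == pytest.approx(1.0)
        assert table.loc["TF1", "Z_NE"] == pytest.approx(-1.1)
        assert table.loc["TF1", "k_ad"] == 0

    def test_sample_order_invariance(self, rng):
        m = random_matrix(rng, n_genes=20, n_samples=10)
        z = compute_internal_z(m)
        labels = {s: ("ADENO" if i < 6 else "NEPC") for i, s in enumerate(m.sample_ids)}
        t1 = group_scores(z, labels)
        from tflens.zscore import InternalZMatrix

        shuffled = InternalZMatrix(z.z[list(reversed(m.sample_ids))])
        t2 = group_scores(shuffled, labels)
        pd.testing.assert_frame_equal(t1, t2)

    def test_matches_per_row_oracle(self, rng):
        m = random_matrix(rng, n_genes=50, n_samples=50)
        z = compute_internal_z(m)
        labels = {s: ("ADENO" if i < 30 else "NEPC") for i, s in enumerate(m.sample_ids)}
        table = group_scores(z, labels, 0.2)
        ad_cols = m.sample_ids[:30]
        for tf in m.gene_ids:
            expected = trimmean_oracle(z.z.loc[tf, ad_cols].tolist(), 0.2)
            assert table.loc[tf, "Z_ad"] == pytest.approx(expected, abs=1e-12)

    def test_excluded_samples_ignored(self, rng):
        m = random_matrix(rng, n_genes=20, n_samples=9)
        z = compute_internal_z(m)
        sids = m.sample_ids
        labels = {s: "ADENO" for s in sids[:4]} | {s: "NEPC" for s in sids[4:8]}
        labels[sids[8]] = "EXCLUDED"
        with_excl = group_scores(z, labels)
        from tflens.zscore import InternalZMatrix

        without = group_scores(InternalZMatrix(z.z[sids[:8]]),
                               {k: v for k, v in labels.items() if k != sids[8]})
        pd.testing.assert_frame_equal(with_excl, without)

    def test_empty_group_raises(self, rng):
        m = random_matrix(rng, n_genes=10, n_samples=4)
        z = compute_internal_z(m)
        with pytest.raises(ValueError, match="NEPC"):
            group_scores(z, {s: "ADENO" for s in m.sample_ids})
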