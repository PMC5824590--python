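"""Expression filtering, divergence calling, Fisher/FDR and bias calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import bhlhfam as bf
from bhlhfam.expression import ExpressionMatrix, bias_table

from helpers import fisher_family_oracle


class TestExpressed:
    def test_all_zero_is_not_expressed(self):
        assert not bf.is_expressed([0.0, 0.0, 0.0])

    def test_single_condition_above_one_suffices(self):
        assert bf.is_expressed([0, 0, 1.5])

    def test_exactly_one_everywhere_is_not_expressed(self):
        assert not bf.is_expressed([1.0, 1.0, 1.0])

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            bf.is_expressed([])


class TestPearson:
    def test_perfect_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert bf.pearson_r(x, x) == pytest.approx(1.0)
        assert bf.pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 6.5/..., var_x = 5, var_y = 8.75 -> r = 6.5/sqrt(43.75)
        assert bf.pearson_r([1, 2, 3, 4], [1, 2, 3, 5]) == pytest.approx(0.9827, abs=5e-5)

    def test_zero_variance_signals_nan(self):
        assert math.isnan(bf.pearson_r([1, 1, 1], [1, 2, 3]))


class TestCriticalR:
    def test_twelve_conditions_reproduces_0576(self):
        assert round(bf.critical_r(12, 0.05), 3) == 0.576

    def test_three_conditions(self):
        assert round(bf.critical_r(3, 0.05), 3) == 0.997

    def test_alpha_to_one_limit(self):
        assert bf.critical_r(12, 0.9999) == pytest.approx(0.0, abs=1e-3)

    def test_monotone_decreasing_in_conditions(self):
        values = [bf.critical_r(n) for n in range(3, 30)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            bf.critical_r(2)


def _matrix(fpkm: dict) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(fpkm).T)


class TestDivergence:
    def test_high_r_is_conserved(self):
        m = _matrix({"a": [1, 5, 9, 2], "b": [2, 6, 10, 2.5]})
        call = bf.call_divergence(("a", "b"), m)
        assert call.call == "conserved"

    def test_low_r_is_diverged_and_negative_flagged(self):
        m = _matrix({"a": [1, 5, 9, 2], "b": [9, 4, 1.5, 8]})
        call = bf.call_divergence(("a", "b"), m)
        assert call.call == "diverged"
        assert call.negative

    def test_threshold_is_inclusive(self):
        m = _matrix({"a": [1, 5, 9, 2], "b": [2, 6, 10, 2.5]})
        r = bf.pearson_r(m.fpkm.loc["a"], m.fpkm.loc["b"])
        call = bf.call_divergence(("a", "b"), m, threshold=r)
        assert call.call == "conserved"

    def test_unexpressed_gene_not_testable(self):
        m = _matrix({"a": [0.2, 0.5, 0.9, 0.1], "b": [2, 6, 10, 2.5]})
        assert bf.call_divergence(("a", "b"), m).call == "not_testable"

    def test_missing_gene_named_in_error(self):
        m = _matrix({"a": [1, 2, 3]})
        with pytest.raises(KeyError, match="zzz"):
            bf.call_divergence(("a", "zzz"), m)


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((5, 5, 5, 5), 1.0),
            ((3, 1, 1, 3), 34 / 70),          # exhaustive enumeration over X in 0..4
            ((0, 10, 10, 0), 2 / 184756),     # 2 / C(20, 10)
        ],
    )
    def test_frozen_enumeration_values(self, table, expected):
        assert bf.fisher_exact_2x2(*table) == pytest.approx(expected, rel=1e-12)

    def test_zero_margin_gives_one(self):
        assert bf.fisher_exact_2x2(0, 0, 3, 5) == 1.0
        assert bf.fisher_exact_2x2(0, 3, 0, 5) == 1.0

    def test_negative_or_fractional_rejected(self):
        with pytest.raises(ValueError):
            bf.fisher_exact_2x2(-1, 2, 3, 4)

    def test_large_table_path_matches_scipy(self):
        p = bf.fisher_exact_2x2(100, 10**6 - 100, 10, 10**6 - 10)
        ref = stats.fisher_exact([[100, 10**6 - 100], [10, 10**6 - 10]])[1]
        assert p == pytest.approx(ref, rel=1e-9)
        assert p < 1e-15

    @given(
        a=st.integers(0, 30), b=st.integers(0, 30),
        c=st.integers(0, 30), d=st.integers(0, 30),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_hypergeometric_enumeration(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            assert bf.fisher_exact_2x2(a, b, c, d) == 1.0
        else:
            oracle = fisher_family_oracle(a + b, c + d, a + c)[a]
            assert bf.fisher_exact_2x2(a, b, c, d) == pytest.approx(oracle, rel=1e-12)

    def test_small_table_path_agrees_with_scipy(self):
        for table in [(3, 1, 1, 3), (2, 7, 8, 2), (10, 2, 3, 15), (1, 1, 1, 1)]:
            ref = stats.fisher_exact([[table[0], table[1]], [table[2], table[3]]])[1]
            assert bf.fisher_exact_2x2(*table) == pytest.approx(ref, rel=1e-7)


class TestFDR:
    def test_single_p_unchanged(self):
        assert bf.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_arithmetic(self):
        qs = bf.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(qs, [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        qs = bf.bh_fdr([0.2, 0.2, 0.2])
        assert np.allclose(qs, 0.2)

    def test_q_at_least_p_and_order_preserving(self):
        rng = np.random.default_rng(0)
        p = rng.random(40)
        q = bf.bh_fdr(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bf.bh_fdr([0.5, 1.5])


def _counts(rows: dict, conditions=None) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    if conditions:
        df.columns = conditions
    return df


class TestBias:
    LIB = pd.Series([10**6] * 3, index=["c1", "c2", "c3"])

    def test_identical_counts_equal(self):
        counts = _counts({"a": [500, 600, 700], "d": [500, 600, 700]},
                         ["c1", "c2", "c3"])
        call = bf.homeolog_bias(("a", "d"), counts, self.LIB)
        assert call.overall == "equal"
        assert set(call.per_condition.values()) == {"equal"}

    def test_tenfold_single_condition_is_ahigh(self):
        counts = _counts({"a": [100], "d": [10]}, ["c1"])
        lib = pd.Series([10**6], index=["c1"])
        call = bf.homeolog_bias(("a", "d"), counts, lib)
        assert call.overall == "Ahigh"
        assert call.p_values["c1"] < 1e-15

    def test_small_fold_is_equal_despite_counts(self):
        counts = _counts({"a": [12], "d": [10]}, ["c1"])
        lib = pd.Series([10**6], index=["c1"])
        call = bf.homeolog_bias(("a", "d"), counts, lib)
        assert call.overall == "equal"

    def test_antisymmetry_swapping_columns(self):
        counts = _counts({"a": [800, 30, 400], "d": [200, 30, 100]},
                         ["c1", "c2", "c3"])
        swapped = counts.rename(index={"a": "d", "d": "a"})
        call = bf.homeolog_bias(("a", "d"), counts, self.LIB)
        rev = bf.homeolog_bias(("a", "d"), swapped, self.LIB)
        assert call.overall == "Ahigh" and rev.overall == "Dhigh"
        for c in call.p_values:
            assert call.p_values[c] == pytest.approx(rev.p_values[c], rel=1e-9)

    def test_mixed_when_both_directions_significant(self):
        counts = _counts({"a": [800, 100, 400], "d": [200, 900, 405]},
                         ["c1", "c2", "c3"])
        call = bf.homeolog_bias(("a", "d"), counts, self.LIB)
        assert call.overall == "mixed"

    def test_every_pair_gets_exactly_one_overall_category(self):
        rng = np.random.default_rng(1)
        genes = {}
        pairs = []
        for i in range(10):
            genes[f"a{i}"] = rng.integers(0, 2000, 3)
            genes[f"d{i}"] = rng.integers(0, 2000, 3)
            pairs.append((f"a{i}", f"d{i}"))
        counts = _counts(genes, ["c1", "c2", "c3"])
        calls = bias_table(pairs, counts, self.LIB)
        assert len(calls) == 10
        for c in calls:
            assert c.overall in ("Ahigh", "equal", "Dhigh", "mixed", "not_tested")

    def test_missing_condition_counts_not_tested(self):
        counts = _counts({"a": [100, np.nan], "d": [10, 5]}, ["c1", "c2"])
        lib = pd.Series([10**6, 10**6], index=["c1", "c2"])
        call = bf.homeolog_bias(("a", "d"), counts, lib)
        assert call.per_condition["c2"] == "not_tested"


class TestGenerateExpressionContract:
    def test_perfect_correlation_noise_off(self):
        counts, fpkm, truth = bf.generate_expression(
            [("a", "d")], (0, 1, 0), [1.0], [10**6] * 12, seed=0,
            dispersion=None,
        )
        r = bf.pearson_r(fpkm.loc["a"], fpkm.loc["d"])
        assert r >= 0.99

    def test_planted_equal_pair_called_equal_noise_off(self):
        # correlation 1.0: both copies share one latent profile, so the
        # planted "equal" category means equal true proportions per tissue
        counts, fpkm, truth = bf.generate_expression(
            [("a", "d")], None, [1.0], [10**6] * 12, seed=1,
            dispersion=None, bias_categories=["equal"], base_mean=800,
        )
        lib = pd.Series([10**6] * 12, index=counts.columns)
        call = bf.homeolog_bias(("a", "d"), counts, lib)
        assert call.overall == "equal"

    def test_determinism(self):
        kw = dict(n_conditions=6, dispersion=0.1)
        out1 = bf.generate_expression([("a", "d")], (0.3, 0.4, 0.3), [0.5],
                                      [10**6] * 6, seed=7, **kw)
        out2 = bf.generate_expression([("a", "d")], (0.3, 0.4, 0.3), [0.5],
                                      [10**6] * 6, seed=7, **kw)
        assert out1[0].equals(out2[0]) and out1[1].equals(out2[1])

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            bf.generate_expression([("a", "d")], (0, 1, 0), [0.5], [0] * 12, seed=0)
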