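"""Cutpoints, classification modes, confusion metrics and R-squared."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmbpanel.metrics import (
    ConfusionCounts,
    classify_panel,
    confusion,
    metric_suite,
    quantile_cutpoint,
    r_squared,
)


def _series(values, prefix="S"):
    return pd.Series(values, index=[f"{prefix}{i:03d}" for i in range(len(values))])


class TestQuantileCutpoint:
    def test_top_one_of_five(self):
        cut = quantile_cutpoint(_series([5, 4, 3, 2, 1]), 0.20)
        assert cut.k == 1 and cut.wes_value == 5.0
        assert list(cut.truth[cut.truth].index) == ["S000"]

    def test_degenerate_ties_resolved_by_barcode(self, caplog):
        with caplog.at_level("WARNING"):
            cut = quantile_cutpoint(_series([2.0] * 10), 0.20)
        assert cut.k == 2
        assert list(cut.truth[cut.truth].index) == ["S000", "S001"]
        assert "identical" in caplog.text

    def test_177_values_match_sort_and_slice_oracle(self):
        rng = np.random.default_rng(17)
        values = _series(rng.lognormal(0, 0.5, 177))
        cut = quantile_cutpoint(values, 0.20)
        assert cut.k == math.floor(0.20 * 177) == 35
        oracle_high = set(
            values.sort_values(ascending=False, kind="stable").index[:35]
        )  # values distinct w.p. 1, so plain sort suffices
        assert set(cut.truth[cut.truth].index) == oracle_high
        assert cut.wes_value == values.loc[cut.cut_sample]

    def test_small_n_and_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            quantile_cutpoint(_series([1.0]), 0.2)
        with pytest.raises(ValueError, match="fraction"):
            quantile_cutpoint(_series([1.0, 2.0]), 1.2)

    def test_k_at_least_one(self):
        cut = quantile_cutpoint(_series([3.0, 2.0, 1.0]), 0.05)
        assert cut.k == 1


class TestClassifyPanel:
    def test_value_transfer_thresholds(self):
        wes = _series([10.0, 5.0, 0.5])
        cut = quantile_cutpoint(wes, 0.34)  # k=1, wes_value=10 -> use explicit cut below
        cut.wes_value, cut.cut_sample = 5.0, "S001"
        pred = classify_panel(_series([10.0, 0.5, 6.0]), cut, mode="value_transfer")
        assert list(pred) == [True, False, True]

    def test_identity_panel_reproduces_truth_both_modes(self):
        rng = np.random.default_rng(2)
        # integer-valued TMB: ties at the cutpoint are likely, on purpose
        wes = _series(rng.integers(0, 8, 60).astype(float))
        cut = quantile_cutpoint(wes, 0.20)
        for mode in ("value_transfer", "quantile"):
            pred = classify_panel(wes, cut, mode=mode)
            assert (pred == cut.truth).all(), mode

    def test_quantile_mode_high_set_size_fixed(self):
        rng = np.random.default_rng(3)
        panel = _series(rng.lognormal(1, 1, 200))
        cut = quantile_cutpoint(_series(rng.lognormal(0, 0.5, 200)), 0.20)
        pred = classify_panel(panel, cut, mode="quantile")
        assert pred.sum() == math.floor(0.2 * 200) == 40

    def test_unknown_mode_rejected(self):
        cut = quantile_cutpoint(_series([2.0, 1.0]), 0.5)
        with pytest.raises(ValueError, match="mode"):
            classify_panel(_series([1.0, 2.0]), cut, mode="nope")


class TestConfusion:
    def test_enumeration(self):
        truth = _series([True, True, False, False])
        pred = _series([True, False, True, False])
        c = confusion(truth, pred)
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        truth = _series([True, False, True])
        c = confusion(truth, truth.copy())
        assert c.fp == c.fn == 0

    def test_500_random_pairs_match_pairwise_oracle(self):
        rng = np.random.default_rng(4)
        truth = _series(rng.random(500) < 0.3)
        pred = _series(rng.random(500) < 0.4)
        c = confusion(truth, pred)
        oracle = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for t, p in zip(truth, pred):
            oracle[("tp" if p else "fn") if t else ("fp" if p else "tn")] += 1
        assert (c.tp, c.fp, c.fn, c.tn) == tuple(oracle[k] for k in ("tp", "fp", "fn", "tn"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(_series([True]), _series([True, False]))


class TestMetricSuite:
    def test_worked_example(self):
        s = metric_suite(ConfusionCounts(tp=8, fp=20, fn=2, tn=70))
        assert s.accuracy == pytest.approx(0.78)
        assert s.fpr == pytest.approx(0.20)
        assert s.fnr == pytest.approx(0.02)
        assert s.ppa == pytest.approx(0.80)
        assert s.npa == pytest.approx(70 / 90)

    def test_perfect(self):
        s = metric_suite(ConfusionCounts(tp=2, fp=0, fn=0, tn=8))
        assert (s.accuracy, s.ppa, s.npa) == (1.0, 1.0, 1.0)

    def test_undefined_ppa_is_missing_not_zero(self):
        s = metric_suite(ConfusionCounts(tp=0, fp=3, fn=0, tn=7))
        assert math.isnan(s.ppa) and s.npa == 0.7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            metric_suite(ConfusionCounts(0, 0, 0, 0))

    @given(st.tuples(*[st.integers(0, 50)] * 4).filter(lambda t: sum(t) > 0))
    @settings(max_examples=200, deadline=None)
    def test_accuracy_fpr_fnr_sum_to_one_exactly(self, t):
        tp, fp, fn, tn = t
        s = metric_suite(ConfusionCounts(tp, fp, fn, tn))
        # exact because the three share the denominator n
        assert s.accuracy + s.fpr + s.fnr == 1.0


class TestRSquared:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert r_squared(x, 2 * x + 1) == pytest.approx(1.0)

    def test_textbook_formula_oracle(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([3.0, 1.0, 2.0])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        oracle = (cov / (x.std() * y.std())) ** 2
        assert r_squared(x, y) == pytest.approx(oracle)

    def test_constant_input_missing_not_error(self, caplog):
        with caplog.at_level("WARNING"):
            out = r_squared([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert math.isnan(out)
        assert "zero-variance" in caplog.text

    @pytest.mark.parametrize("a,b", [(2.0, 3.0), (0.5, -1.0), (10.0, 0.0)])
    def test_invariant_to_positive_affine_transform(self, a, b):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert r_squared(a * x + b, y) == pytest.approx(r_squared(x, y))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            r_squared([1.0, 2.0], [1.0, 2.0])


def test_quantile_mode_fp_equals_fn_on_distinct_values():
    """Equal-sized predicted and true high sets force fp == fn."""
    rng = np.random.default_rng(12)
    for _ in range(20):
        n = int(rng.integers(10, 80))
        wes = _series(rng.permutation(n).astype(float))
        panel = _series(rng.permutation(n).astype(float))
        cut = quantile_cutpoint(wes, 0.20)
        c = confusion(cut.truth, classify_panel(panel, cut, mode="quantile"))
        assert c.fp == c.fn
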