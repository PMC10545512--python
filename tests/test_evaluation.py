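"""Agreement statistics: Dice, Bland-Altman, error summaries, rank tests."""

import numpy as np
import pandas as pd
import pytest

from cineqc.core_io import LVBP, MYO
from cineqc.errors import ConsistencyError, InsufficientDataError
from cineqc.evaluation import (
    bland_altman,
    dice,
    error_summary,
    group_compare,
    stratified_report,
)
from .conftest import make_stack


def _stack_with(voxel_sets, shape=(1, 20, 20), label=LVBP):
    vox = np.zeros(shape, dtype=np.int16)
    for s, r, c in voxel_sets:
        vox[s, r, c] = label
    return make_stack(vox)


class TestDice:
    def test_identical_masks_are_100(self):
        cells = [(0, r, c) for r in range(3, 9) for c in range(3, 9)]
        a, b = _stack_with(cells), _stack_with(cells)
        assert dice(a, b, LVBP) == pytest.approx(100.0)

    def test_disjoint_masks_are_0(self):
        a = _stack_with([(0, 1, 1), (0, 1, 2)])
        b = _stack_with([(0, 10, 10), (0, 10, 11)])
        assert dice(a, b, LVBP) == pytest.approx(0.0)

    def test_half_overlap_is_50(self):
        a_cells = [(0, 0, c) for c in range(10)] + [(0, 1, c) for c in range(10)]
        b_cells = a_cells[:10] + [(0, 5, c) for c in range(10)]
        assert dice(_stack_with(a_cells), _stack_with(b_cells), LVBP) == pytest.approx(50.0)

    def test_symmetric_and_self_dice(self):
        rng = np.random.default_rng(0)
        a = make_stack((rng.random((2, 10, 10)) < 0.3).astype(np.int16))
        b = make_stack((rng.random((2, 10, 10)) < 0.3).astype(np.int16))
        assert dice(a, b, LVBP) == pytest.approx(dice(b, a, LVBP))
        assert dice(a, a, LVBP) == pytest.approx(100.0)

    def test_random_masks_match_set_arithmetic_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            va = (rng.random((2, 8, 8)) < 0.4).astype(np.int16)
            vb = (rng.random((2, 8, 8)) < 0.4).astype(np.int16)
            sa = {tuple(i) for i in np.argwhere(va == 1)}
            sb = {tuple(i) for i in np.argwhere(vb == 1)}
            expected = (
                float("nan")
                if not sa and not sb
                else 100.0 * 2 * len(sa & sb) / (len(sa) + len(sb))
            )
            got = dice(make_stack(va), make_stack(vb), LVBP)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)

    def test_both_empty_label_is_missing_not_100(self):
        a = _stack_with([(0, 1, 1)])
        b = _stack_with([(0, 1, 1)])
        assert np.isnan(dice(a, b, MYO))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            dice(_stack_with([], shape=(1, 4, 4)), _stack_with([], shape=(2, 4, 4)), LVBP)


class TestBlandAltman:
    def test_identical_measurements(self):
        vals = np.array([10.0, 20.0, 30.0, 40.0])
        ba = bland_altman(vals, vals)
        assert ba.bias == 0 and ba.loa_lower == 0 and ba.loa_upper == 0

    def test_constant_shift(self):
        manual = np.array([10.0, 20.0, 30.0, 40.0])
        ba = bland_altman(manual + 5, manual)
        assert ba.bias == pytest.approx(5.0)
        assert ba.loa_lower == pytest.approx(5.0) and ba.loa_upper == pytest.approx(5.0)
        assert ba.r == pytest.approx(1.0)

    def test_matches_direct_formula_on_random_pairs(self):
        rng = np.random.default_rng(2)
        manual = rng.normal(100, 20, 50)
        auto = manual + rng.normal(2, 5, 50)
        ba = bland_altman(auto, manual)
        diff = auto - manual
        assert ba.bias == pytest.approx(diff.mean())
        assert ba.loa_upper == pytest.approx(diff.mean() + 1.96 * diff.std(ddof=1))
        assert ba.loa_lower == pytest.approx(diff.mean() - 1.96 * diff.std(ddof=1))
        assert ba.r == pytest.approx(np.corrcoef(auto, manual)[0, 1])

    def test_constant_input_has_missing_r(self):
        ba = bland_altman(np.array([5.0, 5.0, 5.0]), np.array([1.0, 2.0, 3.0]))
        assert np.isnan(ba.r)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            bland_altman(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_limits_contain_about_95pct_of_gaussian_differences(self):
        rng = np.random.default_rng(3)
        manual = rng.normal(100, 10, 10_000)
        auto = manual + rng.normal(0, 4, 10_000)
        ba = bland_altman(auto, manual)
        diff = auto - manual
        inside = np.mean((diff >= ba.loa_lower) & (diff <= ba.loa_upper))
        assert 0.93 <= inside <= 0.97


class TestErrorSummary:
    def test_small_example(self):
        med, iqr = error_summary(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert med == pytest.approx(2.0) and iqr == pytest.approx(1.0)

    def test_all_zero_errors(self):
        med, iqr = error_summary(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert med == 0 and iqr == 0

    def test_matches_sorted_percentile_oracle(self):
        rng = np.random.default_rng(4)
        auto, manual = rng.normal(size=1000), rng.normal(size=1000)
        med, iqr = error_summary(auto, manual)
        err = np.sort(np.abs(auto - manual))
        assert med == pytest.approx(np.percentile(err, 50))
        assert iqr == pytest.approx(np.percentile(err, 75) - np.percentile(err, 25))


class TestGroupCompare:
    def test_identical_groups_not_significant(self):
        vals = np.arange(20.0)
        cmp = group_compare(vals, vals.copy(), n_tests=20)
        assert cmp.stars == 0

    def test_large_shift_hits_strictest_tier(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 50)
        b = rng.normal(10, 1, 50)
        cmp = group_compare(a, b, n_tests=20)
        assert cmp.stars == 3  # p < 0.0001/20

    def test_adjusted_threshold_arithmetic(self):
        cmp = group_compare(np.arange(5.0), np.arange(5.0) + 0.1, n_tests=20)
        assert cmp.adjusted_thresholds[0] == pytest.approx(0.01 / 20)
        assert cmp.adjusted_thresholds == (0.0005, 5e-05, 5e-06)

    def test_wilcoxon_against_zero(self):
        diffs = np.array([1.0, 2.0, 1.5, 0.5, 2.5, 1.0, 3.0, 2.0])
        cmp = group_compare(diffs, design="within_vs_zero", n_tests=1)
        assert cmp.p_value < 0.05
        allzero = group_compare(np.zeros(5), design="within_vs_zero")
        assert allzero.p_value == 1.0 and allzero.stars == 0

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            group_compare(np.array([1.0]), np.array([]), n_tests=1)


class TestStratifiedReport:
    @staticmethod
    def _results(rng, n, err_scale, ids):
        ref = rng.normal(150, 20, n)
        return pd.DataFrame(
            {
                "study_id": ids,
                "LVEDV_auto": ref + rng.normal(0, err_scale, n),
                "LVEDV_ref": ref,
            }
        )

    def test_single_stratum_equals_unstratified(self):
        rng = np.random.default_rng(6)
        res = self._results(rng, 10, 2.0, [f"s{i}" for i in range(10)])
        meta = pd.DataFrame({"study_id": res["study_id"], "vendor": ["A"] * 10})
        flat = stratified_report(res)
        strat = stratified_report(res, metadata=meta, stratum="vendor")
        assert flat["strata"]["all"]["metrics"] == strat["strata"]["A"]["metrics"]

    def test_injected_shift_recovered_per_stratum(self):
        rng = np.random.default_rng(7)
        a = self._results(rng, 30, 1.0, [f"a{i}" for i in range(30)])
        b = self._results(rng, 30, 12.0, [f"b{i}" for i in range(30)])
        res = pd.concat([a, b], ignore_index=True)
        meta = pd.DataFrame(
            {"study_id": res["study_id"], "vendor": ["A"] * 30 + ["B"] * 30}
        )
        rep = stratified_report(res, metadata=meta, stratum="vendor")
        med_a = rep["strata"]["A"]["metrics"]["LVEDV"]["median_abs_error"]
        med_b = rep["strata"]["B"]["metrics"]["LVEDV"]["median_abs_error"]
        assert med_b > 3 * med_a
        assert rep["comparisons"]["LVEDV:A|B"]["p_value"] < 0.01

    def test_missing_metadata_marked_insufficient_not_dropped(self):
        rng = np.random.default_rng(8)
        res = self._results(rng, 5, 1.0, [f"s{i}" for i in range(5)])
        meta = pd.DataFrame({"study_id": ["s0", "s1", "s2", "s3"],
                             "vendor": ["A", "A", "A", "A"]})
        rep = stratified_report(res, metadata=meta, stratum="vendor")
        assert rep["strata"]["__missing__"]["insufficient"] is True
        assert rep["strata"]["A"]["n"] == 4
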