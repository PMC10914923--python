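"""The core statistic: editing ratios, background correction and the
two-criterion significance call."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sangeredit.editcall import (EditingTable, build_editing_table,
                                 call_significant_sites, editing_ratio,
                                 summarize_run)
from sangeredit.refmap import SiteMap, enumerate_candidates
from sangeredit.workflow import peak_table_to_quant
import pandas as pd


def make_table(positions, values, group, mode="A_to_G"):
    values = np.asarray(values, dtype=float)
    return EditingTable(mode, positions, ["A"] * len(positions), values,
                        [f"{group[0]}{i}" for i in range(values.shape[1])],
                        group)


class TestEditingRatio:
    @pytest.mark.parametrize("areas,mode,expected", [
        ({"A": 100, "C": 0, "G": 0, "T": 0}, "A_to_G", 0.0),
        ({"A": 0, "C": 0, "G": 250, "T": 0}, "A_to_G", 1.0),
        ({"A": 300, "C": 9, "G": 100, "T": 2}, "A_to_G", 0.25),
        ({"A": 0, "C": 300, "G": 0, "T": 100}, "C_to_T", 0.25),
    ])
    def test_direct_arithmetic(self, areas, mode, expected):
        assert editing_ratio(areas, mode) == pytest.approx(expected)

    def test_zero_total_is_missing_not_error(self):
        assert math.isnan(editing_ratio({"A": 0, "C": 5, "G": 0, "T": 1},
                                        "A_to_G"))

    def test_min_total_area_threshold(self):
        areas = {"A": 3, "C": 0, "G": 1, "T": 0}
        assert math.isnan(editing_ratio(areas, "A_to_G", min_total_area=10))
        assert editing_ratio(areas, "A_to_G", min_total_area=0) == 0.25

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            editing_ratio({"A": -1, "C": 0, "G": 1, "T": 0}, "A_to_G")


class TestSignificance:
    def test_worked_example_all_statistics(self):
        """Sample (0.30, 0.34, 0.32) vs control 0.02: control mean 0.02,
        corrected (0.28, 0.32, 0.30), mean 0.30, sd 0.02; both criteria
        hold, so the site is significant."""
        sample = make_table([4], [[0.30, 0.34, 0.32]], "sample")
        control = make_table([4], [[0.02, 0.02, 0.02]], "control")
        (res,) = call_significant_sites(sample, control)
        assert res.control_mean == pytest.approx(0.02)
        np.testing.assert_allclose(res.corrected_values, [0.28, 0.32, 0.30])
        assert res.corrected_mean == pytest.approx(0.30)
        assert res.corrected_sd == pytest.approx(0.02)
        assert res.raw_mean == pytest.approx(0.32)
        assert res.criterion1 and res.criterion2 and res.significant
        # invariant: corrected mean equals raw mean minus control mean
        assert res.corrected_mean == pytest.approx(
            res.raw_mean - res.control_mean, abs=1e-12)

    def test_sample_equal_to_control_is_not_significant(self):
        sample = make_table([1], [[0.05, 0.06, 0.07]], "sample")
        control = make_table([1], [[0.05, 0.06, 0.07]], "control")
        (res,) = call_significant_sites(sample, control)
        assert res.corrected_mean == pytest.approx(0.0, abs=1e-12)
        assert not res.criterion1 and not res.significant

    def test_high_variance_fails_criterion1_despite_zero_control(self):
        """(0.05, 0.08, 0.02) on a clean control: sd 0.03 so the 3-sigma
        margin (0.09) exceeds the mean (0.05) — not significant even
        though criterion 2 passes by the zero-control rule."""
        sample = make_table([1], [[0.05, 0.08, 0.02]], "sample")
        control = make_table([1], [[0.0, 0.0, 0.0]], "control")
        (res,) = call_significant_sites(sample, control)
        assert res.corrected_sd == pytest.approx(0.03)
        assert res.corrected_mean == pytest.approx(0.05)
        assert not res.criterion1
        assert res.criterion2  # zero-control rule: raw mean > 0
        assert not res.significant

    def test_zero_control_with_zero_sample_fails_criterion2(self):
        sample = make_table([1], [[0.0, 0.0, 0.0]], "sample")
        control = make_table([1], [[0.0, 0.0, 0.0]], "control")
        (res,) = call_significant_sites(sample, control)
        assert not res.criterion2 and not res.significant

    def test_criterion1_strict_criterion2_geq(self):
        # corrected_mean exactly equals 3*sd -> criterion1 false (strict >)
        sample = make_table([1], [[0.3, 0.3, 0.36]], "sample")
        control = make_table([1], [[0.16, 0.16, 0.16]], "control")
        (res,) = call_significant_sites(sample, control)
        sd = np.std([0.14, 0.14, 0.20], ddof=1)
        assert res.corrected_sd == pytest.approx(sd)
        # raw mean 0.32 == 2 * 0.16 -> criterion2 true (>=)
        assert res.criterion2

    def test_strict_criterion2_requires_every_replicate(self):
        sample = make_table([1], [[0.30, 0.30, 0.05]], "sample")
        control = make_table([1], [[0.04, 0.04, 0.04]], "control")
        (lenient,) = call_significant_sites(sample, control)
        (strict,) = call_significant_sites(sample, control,
                                           strict_criterion2=True)
        assert lenient.criterion2
        assert not strict.criterion2

    def test_min_replicates_marks_not_evaluable(self):
        sample = make_table([1], [[0.3, np.nan, np.nan]], "sample")
        control = make_table([1], [[0.0, 0.0, 0.0]], "control")
        (res,) = call_significant_sites(sample, control, min_replicates=3)
        assert not res.evaluable and not res.significant

    def test_mismatched_inputs_rejected(self):
        sample = make_table([1], [[0.1, 0.2, 0.3]], "sample")
        control_sites = make_table([2], [[0.0, 0.0, 0.0]], "control")
        with pytest.raises(ValueError):
            call_significant_sites(sample, control_sites)
        control_mode = make_table([1], [[0.0, 0.0, 0.0]], "control",
                                  mode="C_to_T")
        with pytest.raises(ValueError):
            call_significant_sites(sample, control_mode)

    @given(data=st.data())
    @settings(max_examples=100)
    def test_matches_brute_force_oracle(self, data):
        """On random small tables the caller must agree exactly with a
        straight-line reimplementation of the two criteria."""
        n_sites = data.draw(st.integers(1, 10))
        n_rep = data.draw(st.integers(3, 5))
        vals = data.draw(st.lists(
            st.lists(st.floats(0, 1), min_size=n_rep, max_size=n_rep),
            min_size=n_sites, max_size=n_sites))
        ctrl = data.draw(st.lists(
            st.lists(st.floats(0, 0.2), min_size=n_rep, max_size=n_rep),
            min_size=n_sites, max_size=n_sites))
        positions = list(range(1, n_sites + 1))
        sample = make_table(positions, vals, "sample")
        control = make_table(positions, ctrl, "control")
        results = call_significant_sites(sample, control)
        for s, res in enumerate(results):
            raw = np.array(vals[s], dtype=float)
            cm = float(np.mean(ctrl[s]))
            corrected = raw - cm
            c1 = corrected.mean() - 3 * corrected.std(ddof=1) > 0
            if cm < 1e-9:
                c2 = raw.mean() > 0
            else:
                c2 = raw.mean() >= 2 * cm
            assert res.criterion1 == c1
            assert res.criterion2 == c2
            assert res.significant == (c1 and c2)

    @given(data=st.data())
    @settings(max_examples=50)
    def test_uniform_increase_never_loses_significance(self, data):
        """Raising every sample replicate by the same delta keeps sd fixed
        and can only help both criteria."""
        n_rep = data.draw(st.integers(3, 5))
        vals = data.draw(st.lists(st.floats(0, 0.8),
                                  min_size=n_rep, max_size=n_rep))
        ctrl_val = data.draw(st.floats(0, 0.2))
        delta = data.draw(st.floats(0.001, 0.2))
        delta = min(delta, 1.0 - max(vals))
        sample = make_table([1], [vals], "sample")
        shifted = make_table([1], [[v + delta for v in vals]], "sample")
        control = make_table([1], [[ctrl_val] * n_rep], "control")
        (before,) = call_significant_sites(sample, control)
        (after,) = call_significant_sites(shifted, control)
        if before.significant:
            assert after.significant


class TestBuildTable:
    def _quant(self, rows):
        df = pd.DataFrame(rows, columns=["position", "base", "area_A",
                                         "area_C", "area_G", "area_T"])
        return peak_table_to_quant(df)

    def test_single_replicate_two_base_reference(self):
        cand = enumerate_candidates("AG", "A_to_G")
        pt = self._quant([[1, "A", 300.0, 0, 100.0, 0],
                          [2, "G", 0, 0, 400.0, 0]])
        sm = SiteMap(call_to_ref={0: 1, 1: 2})
        table = build_editing_table([pt], [sm], cand)
        assert table.values.shape == (1, 1)
        assert table.values[0, 0] == pytest.approx(0.25)

    def test_uncovered_site_is_missing_for_that_replicate_only(self):
        cand = enumerate_candidates("AGA", "A_to_G")
        full = self._quant([[1, "A", 100.0, 0, 0, 0],
                            [2, "G", 0, 0, 400.0, 0],
                            [3, "A", 200.0, 0, 200.0, 0]])
        partial = self._quant([[1, "A", 100.0, 0, 100.0, 0]])
        table = build_editing_table(
            [full, partial],
            [SiteMap(call_to_ref={0: 1, 1: 2, 2: 3}),
             SiteMap(call_to_ref={0: 1}, uncovered_ref=[2, 3])],
            cand)
        assert table.values.shape == (2, 2)
        assert table.values[1, 0] == pytest.approx(0.5)
        assert math.isnan(table.values[1, 1])
        assert table.values[0, 1] == pytest.approx(0.5)

    def test_zero_replicates_rejected(self):
        cand = enumerate_candidates("A", "A_to_G")
        with pytest.raises(ValueError):
            build_editing_table([], [], cand)


class TestSummary:
    def test_empty_run_reports_zeros(self):
        s = summarize_run([])
        assert s["n_sites"] == 0 and s["n_significant"] == 0
        assert s["max_position"] is None

    def test_counts_and_tie_break(self):
        sample = make_table([1, 5, 9],
                            [[0.30, 0.31, 0.32],
                             [0.30, 0.31, 0.32],
                             [0.01, 0.015, 0.02]], "sample")
        control = make_table([1, 5, 9], np.zeros((3, 3)) + 0.01, "control")
        results = call_significant_sites(sample, control)
        s = summarize_run(results)
        assert s["n_evaluable"] == 3
        assert s["n_significant"] == 2
        # positions 1 and 5 share the max corrected mean; smaller wins
        assert s["max_position"] == 1
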