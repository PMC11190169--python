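"""Estimator correctness: published desk values, closed-form oracles,
independence limits, symmetry and monotonicity properties, criteria edges."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from faerspv import stats
from faerspv.contingency import ContingencyTable


def table(a, b, c, d):
    return ContingencyTable("drug", "event", "PT", a, b, c, d)


def bate_ic025_oracle(a, b, c, d):
    """Independently coded Bate (1998) posterior-moment IC025."""
    n = a + b + c + d
    a1 = b1 = g11 = 1.0
    al = be = 2.0
    gamma = g11 * (n + al) * (n + be) / ((a + b + a1) * (a + c + b1))
    e_ic = math.log2((a + g11) * (n + al) * (n + be)
                     / ((n + gamma) * (a + b + a1) * (a + c + b1)))
    v_ic = ((n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
            + (n - (a + b) + al - a1) / ((a + b + a1) * (1 + n + al))
            + (n - (a + c) + be - b1) / ((a + c + b1) * (1 + n + be)))
    v_ic /= math.log(2) ** 2
    return e_ic - 2 * math.sqrt(v_ic)


def pearson_chi2_oracle(a, b, c, d):
    """Sum((O-E)^2/E) over the four cells of the independence model."""
    n = a + b + c + d
    obs = np.array([[a, b], [c, d]], dtype=float)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return float(((obs - expected) ** 2 / expected).sum())


class TestPublishedDeskValues:
    # the most-reported adverse event of the study drug
    T = table(5752, 14291, 18587, 1865851)

    def test_ror_with_ci(self):
        ror, lo, hi = stats.ror_with_ci(self.T)
        assert ror == pytest.approx(40.40, abs=0.005)
        assert lo == pytest.approx(39.06, abs=0.005)
        assert hi == pytest.approx(41.8, abs=0.01)

    def test_prr_and_chi2(self):
        prr, chi2, p = stats.prr_with_chi2(self.T)
        assert prr == pytest.approx(29.10, abs=0.005)
        assert chi2 == pytest.approx(120715.28, abs=0.01)
        assert p < 1e-300

    def test_ic_point_estimate(self):
        ic, _ = stats.bcpnn_ic(self.T)
        assert ic == pytest.approx(4.49, abs=0.005)

    def test_ebgm_with_bound(self):
        ebgm, lo = stats.ebgm_with_ci(self.T)
        assert ebgm == pytest.approx(22.46, abs=0.005)
        assert lo == pytest.approx(21.71, abs=0.005)

    def test_second_row_ebgm(self):
        ebgm, lo = stats.ebgm_with_ci(table(207, 19836, 488, 1883950))
        assert ebgm == pytest.approx(28.30, abs=0.005)
        assert lo == pytest.approx(24.04, abs=0.005)

    def test_soc_row(self):
        t = table(69, 19974, 1518, 1882920)
        ror, _, _ = stats.ror_with_ci(t)
        ebgm, lo = stats.ebgm_with_ci(t)
        assert ror == pytest.approx(4.28, abs=0.005)
        assert ebgm == pytest.approx(4.13, abs=0.005)
        assert lo == pytest.approx(3.24, abs=0.005)


class TestIndependenceLimit:
    T = table(10, 90, 100, 900)

    def test_all_point_estimates_unity(self):
        s = stats.compute_stats(self.T)
        assert s.ror == pytest.approx(1.0)
        assert s.prr == pytest.approx(1.0)
        assert s.ebgm == pytest.approx(1.0)
        assert s.ic == pytest.approx(0.0, abs=1e-12)
        assert s.chi2 == pytest.approx(0.0, abs=1e-12)
        assert s.p_value == pytest.approx(1.0)

    def test_ror_ci_straddles_one(self):
        _, lo, hi = stats.ror_with_ci(self.T)
        assert lo < 1 < hi

    def test_no_signal(self):
        crit = stats.evaluate_criteria(stats.compute_stats(self.T))
        assert not crit.any


class TestZeroCellCorrection:
    def test_haldane_anscombe_ror(self):
        # hand evaluation: (3.5*992.5)/(0.5*5.5)
        ror, _, _ = stats.ror_with_ci(table(3, 0, 5, 992))
        assert ror == pytest.approx(3.5 * 992.5 / (0.5 * 5.5), rel=1e-12)
        assert ror == pytest.approx(1263.18, abs=0.005)

    def test_corrected_flag_set(self):
        assert stats.compute_stats(table(3, 0, 5, 992)).corrected
        assert not stats.compute_stats(table(3, 1, 5, 992)).corrected

    def test_error_when_correction_disabled(self):
        with pytest.raises(stats.UndefinedStatisticError):
            stats.ror_with_ci(table(3, 0, 5, 992), zero_correction=False)

    def test_a_zero_ic_undefined(self):
        with pytest.raises(stats.UndefinedStatisticError):
            stats.bcpnn_ic(table(0, 10, 5, 992))


@st.composite
def tables_st(draw, min_cell=5, max_cell=50_000):
    cells = [draw(st.integers(min_cell, max_cell)) for _ in range(4)]
    return table(*cells)


class TestClosedFormOracles:
    @given(tables_st())
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_chi2_equals_expected_counts_formulation(self, t):
        _, chi2, _ = stats.prr_with_chi2(t)
        assert chi2 == pytest.approx(
            pearson_chi2_oracle(t.a, t.b, t.c, t.d), rel=1e-9)

    @given(tables_st(min_cell=1))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_ic_is_log2_of_ebgm(self, t):
        ic, _ = stats.bcpnn_ic(t)
        ebgm, _ = stats.ebgm_with_ci(t)
        assert ic == pytest.approx(math.log2(ebgm), abs=1e-9)

    @given(tables_st(min_cell=1))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_ror_transpose_symmetry(self, t):
        swapped = table(t.a, t.c, t.b, t.d)
        assert stats.ror_with_ci(t)[0] == pytest.approx(
            stats.ror_with_ci(swapped)[0], rel=1e-12)

    def test_prr_lacks_transpose_symmetry(self):
        t, swapped = table(5, 10, 200, 4000), table(5, 200, 10, 4000)
        assert stats.prr_with_chi2(t)[0] != pytest.approx(
            stats.prr_with_chi2(swapped)[0], rel=1e-6)

    def test_ic025_matches_independent_bate_evaluation(self):
        for cells in [(207, 19836, 488, 1883950), (37, 20006, 988, 1883450),
                      (5, 45, 120, 3000)]:
            _, ic_low = stats.bcpnn_ic(table(*cells))
            assert ic_low == pytest.approx(bate_ic025_oracle(*cells), rel=1e-9)


class TestMonotonicity:
    def test_shifting_mass_to_a_increases_all_estimators(self):
        # margins a+b, a+c fixed; d absorbs
        base = None
        for a in range(5, 50, 5):
            t = table(a, 100 - a, 200 - a, 5000 + a)
            s = stats.compute_stats(t)
            cur = (s.ror, s.prr, s.ic, s.ebgm)
            if base is not None:
                assert all(x > y for x, y in zip(cur, base))
            base = cur


class TestCriteriaEdges:
    def mk(self, **kw):
        defaults = dict(table=table(10, 10, 10, 10), ror=5, ror_low=2,
                        ror_high=10, prr=5, chi2=50, p_value=1e-10, ic=1,
                        ic_low=0.5, ebgm=5, ebgm_low=3, corrected=False)
        defaults.update(kw)
        return stats.SignalStats(**defaults)

    def test_small_a_blocks_ror_and_prr(self):
        s = self.mk(table=table(2, 10, 10, 10))
        c = stats.evaluate_criteria(s)
        assert not c.ror_positive and not c.prr_positive
        assert c.bcpnn_positive and c.ebgm_positive

    def test_ebgm_bound_strictly_greater_than_two(self):
        assert not stats.evaluate_criteria(self.mk(ebgm_low=2.0)).ebgm_positive
        assert stats.evaluate_criteria(self.mk(ebgm_low=2.0 + 1e-9)).ebgm_positive

    def test_ror_bound_strictly_greater_than_one(self):
        assert not stats.evaluate_criteria(self.mk(ror_low=1.0)).ror_positive

    def test_prr_and_chi2_thresholds_inclusive(self):
        assert stats.evaluate_criteria(self.mk(prr=2.0, chi2=4.0)).prr_positive
        assert not stats.evaluate_criteria(self.mk(prr=1.999)).prr_positive
        assert not stats.evaluate_criteria(self.mk(chi2=3.999)).prr_positive
        assert not stats.evaluate_criteria(self.mk(p_value=0.05)).prr_positive

    def test_ic_bound_strictly_positive(self):
        assert not stats.evaluate_criteria(self.mk(ic_low=0.0)).bcpnn_positive

    def test_all_four_requires_each(self):
        assert stats.evaluate_criteria(self.mk()).all_four
        assert not stats.evaluate_criteria(self.mk(ic_low=-1)).all_four


class TestDetectSignals:
    def test_empty_input(self):
        assert stats.detect_signals([]) == []

    def test_ranked_by_ebgm05_descending(self, printed_pt):
        tables = [table(r.a, r.b, r.c, r.d) for r in printed_pt.itertuples()]
        for i, (t, r) in enumerate(zip(tables, printed_pt.itertuples())):
            tables[i] = ContingencyTable("tirzepatide", r.pt, "PT",
                                         t.a, t.b, t.c, t.d)
        ranked = stats.detect_signals(tables, rule="all_four")
        bounds = [s.ebgm_low for s, _ in ranked]
        assert bounds == sorted(bounds, reverse=True)
        assert ranked[0][0].table.event == "Gastrooesophageal reflux disease"

    def test_any_rule_is_superset_of_all_four(self):
        tables = [table(5, 95, 100, 4800), table(50, 50, 100, 4800)]
        assert len(stats.detect_signals(tables, rule="any")) >= \
            len(stats.detect_signals(tables, rule="all_four"))

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="rule"):
            stats.detect_signals([table(5, 5, 5, 5)], rule="bogus")


def test_signal_frame_formatting(printed_pt):
    t = ContingencyTable("tirzepatide", "Incorrect dose administered", "PT",
                         5752, 14291, 18587, 1865851)
    frame = stats.signals_to_frame(stats.detect_signals([t], rule="none"))
    shown = stats.format_signal_frame(frame)
    row = shown.iloc[0]
    assert row["ror"] == 40.40 and row["ebgm"] == 22.46
    assert row["p_value"] == "0.00E+00"
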