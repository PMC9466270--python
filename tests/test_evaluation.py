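"""Quality factor, DVH metrics, TCP model, calibration, paired statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosepaint import TCPParams, calibrate_c, paired_wilcoxon, quality_factor, tcp
from dosepaint.evaluation import REPORT_METRICS, compare_plans, dose_metrics, dvh
from dosepaint.volumes import ScalarVolume

from conftest import make_mask, make_volume


def region_of(shape=(10, 10, 10)):
    return make_mask(np.ones(shape))


def flat(values):
    """1-D list of doses laid out on a 3-D grid with a full-region mask."""
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return make_volume(arr), make_mask(np.ones(arr.shape))


class TestQualityFactor:
    def test_identity_plan_scores_hundred(self):
        rx, reg = flat([60.0, 70.0, 80.0])
        qf = quality_factor(rx, rx, reg)
        assert qf.qf_percent == pytest.approx(100.0, abs=1e-12)

    @pytest.mark.parametrize(
        "rx_doses,plan_doses,expected",
        [
            ([80.0], [76.0], 95.0),           # 100 − 100·(4/80)
            ([60.0, 80.0], [60.0, 72.0], 95.0),  # mean of (0, 10%) deviations
        ],
    )
    def test_hand_computed_values(self, rx_doses, plan_doses, expected):
        rx, reg = flat(rx_doses)
        plan, _ = flat(plan_doses)
        assert quality_factor(plan, rx, reg).qf_percent == pytest.approx(expected, abs=1e-12)

    def test_qf_map_mean_matches_scalar(self):
        rng = np.random.default_rng(0)
        rx, reg = flat(rng.uniform(60, 80, size=50))
        plan, _ = flat(rng.uniform(55, 85, size=50))
        res = quality_factor(plan, rx, reg)
        assert np.nanmean(res.qf_map.values) == pytest.approx(res.qf_percent, abs=1e-9)
        assert res.n == 50

    def test_hundred_iff_identical(self):
        rx, reg = flat([60.0, 70.0])
        plan, _ = flat([60.0, 70.0 + 1e-6])
        assert quality_factor(plan, rx, reg).qf_percent < 100.0

    def test_zero_prescription_rejected(self):
        rx, reg = flat([0.0, 60.0])
        with pytest.raises(ValueError):
            quality_factor(rx, rx, reg)


class TestDVH:
    def test_uniform_dose_step_function(self):
        plan, reg = flat([60.0] * 20)
        curve = dvh(plan, reg)
        assert curve.volume_at_dose(59.9) == 1.0
        assert curve.volume_at_dose(60.0) == 1.0
        assert curve.volume_at_dose(60.2) == 0.0

    def test_half_and_half(self):
        plan, reg = flat([59.0] * 10 + [61.0] * 10)
        assert dvh(plan, reg).volume_at_dose(60.0) == pytest.approx(0.5)

    def test_non_increasing_and_anchored(self):
        rng = np.random.default_rng(1)
        plan, reg = flat(rng.uniform(0, 80, size=500))
        curve = dvh(plan, reg)
        assert curve.volume_fraction[0] == 1.0
        assert np.all(np.diff(curve.volume_fraction) <= 0)
        assert curve.volume_fraction[-1] == 0.0

    def test_matches_sort_oracle_at_bin_edges(self):
        rng = np.random.default_rng(2)
        doses = rng.uniform(0, 80, size=1000)
        plan, reg = flat(doses)
        curve = dvh(plan, reg, bin_width_gy=0.5)
        sorted_doses = np.sort(doses)
        for d, v in zip(curve.dose_gy, curve.volume_fraction):
            oracle = 1.0 - np.searchsorted(sorted_doses, d, side="left") / doses.size
            assert v == pytest.approx(oracle, abs=1e-12)


class TestDoseMetrics:
    def test_uniform_region(self):
        plan, reg = flat([60.0] * 30)
        m = dose_metrics(plan, reg, ["Dmean", "Dmax", "Dmin", "D98%", "V60Gy", "V76Gy", "V80Gy"])
        assert m["Dmean"] == m["Dmax"] == m["Dmin"] == m["D98%"] == 60.0
        assert m["V60Gy"] == 100.0 and m["V76Gy"] == 0.0 and m["V80Gy"] == 0.0

    def test_four_level_hand_computation(self):
        plan, reg = flat([50.0, 60.0, 70.0, 80.0])
        m = dose_metrics(plan, reg, ["Dmean", "V60Gy"])
        assert m["Dmean"] == pytest.approx(65.0)
        assert m["V60Gy"] == pytest.approx(75.0)

    def test_d98_matches_percentile_oracle(self):
        rng = np.random.default_rng(3)
        doses = rng.uniform(40, 80, size=1000)
        plan, reg = flat(doses)
        d98 = dose_metrics(plan, reg, ["D98%"])["D98%"]
        # brute-force type-7 interpolation between order statistics
        s = np.sort(doses)
        h = (doses.size - 1) * 0.02
        lo = int(np.floor(h))
        oracle = s[lo] + (h - lo) * (s[lo + 1] - s[lo])
        assert d98 == pytest.approx(oracle, abs=1e-9)

    def test_unknown_metric_rejected(self):
        plan, reg = flat([60.0])
        with pytest.raises(ValueError, match="unknown metric"):
            dose_metrics(plan, reg, ["EUD"])


class TestTCP:
    def test_no_tumour_gives_certain_control(self):
        p, reg = flat([0.0] * 10)
        d, _ = flat([0.0] * 10)
        assert tcp(p, d, reg) == pytest.approx(1.0)

    def test_single_voxel_closed_form(self):
        """One voxel, p=1, D=0: TCP = exp(−C) = exp(−0.032)."""
        p, reg = flat([1.0])
        d, _ = flat([0.0])
        assert tcp(p, d, reg) == pytest.approx(np.exp(-0.032), abs=1e-12)

    def test_matches_explicit_sum(self):
        rng = np.random.default_rng(4)
        pv = rng.uniform(0, 1, size=64)
        dv = rng.uniform(0, 80, size=64)
        p, reg = flat(pv)
        d, _ = flat(dv)
        params = TCPParams(alpha_per_gy=0.12, c_constant=0.032)
        expected = np.exp(-0.032 * np.sum(pv * np.exp(-0.12 * dv)))
        assert tcp(p, d, reg, params) == pytest.approx(expected, rel=1e-12)

    @given(st.integers(0, 63), st.floats(min_value=0.5, max_value=10.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_increasing_in_dose(self, idx, bump):
        rng = np.random.default_rng(5)
        pv = rng.uniform(0.01, 1, size=64)
        dv = rng.uniform(0, 80, size=64)
        p, reg = flat(pv)
        base = tcp(p, make_volume(dv.reshape(-1, 1, 1)), reg)
        dv2 = dv.copy()
        dv2[idx] += bump
        higher = tcp(p, make_volume(dv2.reshape(-1, 1, 1)), reg)
        assert higher >= base

    def test_strictly_decreasing_in_c_and_p(self):
        rng = np.random.default_rng(6)
        pv = rng.uniform(0.01, 1, size=64)
        dv = rng.uniform(0, 80, size=64)
        p, reg = flat(pv)
        d, _ = flat(dv)
        t1 = tcp(p, d, reg, TCPParams(c_constant=0.032))
        t2 = tcp(p, d, reg, TCPParams(c_constant=0.064))
        assert t2 < t1
        p_up, _ = flat(np.minimum(pv + 0.1, 1.0))
        assert tcp(p_up, d, reg) < tcp(p, d, reg)
        assert 0.0 < t1 <= 1.0

    def test_nan_in_region_rejected(self):
        p, reg = flat([np.nan])
        d, _ = flat([60.0])
        with pytest.raises(ValueError):
            tcp(p, d, reg)


class TestCalibrateC:
    def _uniform_case(self, p_total, dose, n=50):
        pv = np.full(n, p_total / n)
        p, reg = flat(pv)
        d, _ = flat(np.full(n, dose))
        return p, d, reg

    def test_closed_form_single_case(self):
        """Uniform dose D and probability mass S give
        C = −ln(target)/(S·e^(−αD)) analytically."""
        alpha, target, dose, s_total = 0.12, 0.27, 60.0, 15000.0
        case = self._uniform_case(s_total, dose)
        c = calibrate_c([case], alpha_per_gy=alpha, target_tcp=target)
        expected = -np.log(target) / (s_total * np.exp(-alpha * dose))
        assert c == pytest.approx(expected, rel=1e-6)

    def test_doubling_mass_halves_c(self):
        a = calibrate_c([self._uniform_case(10000.0, 60.0)], target_tcp=0.27)
        b = calibrate_c([self._uniform_case(20000.0, 60.0)], target_tcp=0.27)
        assert b == pytest.approx(a / 2.0, rel=1e-5)

    def test_recovery_loop_closes(self):
        rng = np.random.default_rng(7)
        cohort = []
        for _ in range(5):
            pv = rng.uniform(0, 1, size=200)
            dv = rng.uniform(55, 65, size=200)
            p, reg = flat(pv)
            d, _ = flat(dv)
            cohort.append((p, d, reg))
        c = calibrate_c(cohort, target_tcp=0.27)
        params = TCPParams(c_constant=c)
        mean_tcp = np.mean([tcp(p, d, reg, params) for p, d, reg in cohort])
        assert mean_tcp == pytest.approx(0.27, abs=1e-5)

    def test_unbracketable_target_rejected(self):
        p, reg = flat([0.0] * 10)  # no tumour mass: TCP is 1 for any C
        d, _ = flat([60.0] * 10)
        with pytest.raises(ValueError, match="bracket"):
            calibrate_c([(p, d, reg)], target_tcp=0.27)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            calibrate_c([])


class TestPairedWilcoxon:
    def test_five_positive_pairs_exact_p(self):
        """All 5 differences positive: two-sided exact p = 2·(1/2⁵) = 0.0625."""
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [0.5, 1.0, 2.0, 3.0, 4.0]
        res = paired_wilcoxon(a, b)
        assert res.p_value == pytest.approx(0.0625, abs=1e-12)
        assert res.statistic == pytest.approx(15.0)

    def test_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(8)
        a = rng.normal(1, 1, size=12)
        b = rng.normal(0, 1, size=12)
        fwd = paired_wilcoxon(a, b)
        rev = paired_wilcoxon(b, a)
        assert rev.statistic == pytest.approx(-fwd.statistic)
        assert rev.p_value == pytest.approx(fwd.p_value, abs=1e-12)

    def test_identical_samples_degenerate(self):
        a = [1.0, 2.0, 3.0]
        res = paired_wilcoxon(a, a)
        assert res.degenerate and res.p_value == 1.0

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.5, 1, size=40)
        b = rng.normal(0.0, 1, size=40)
        res = paired_wilcoxon(a, b)
        assert 0.0 < res.p_value < 1.0 and res.n_nonzero == 40

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1.0, 2.0], [0.0, 1.0])


@pytest.fixture(scope="module")
def small_comparison(phantom, fast_beam):
    from dosepaint import (
        dose_prescription,
        optimize_plan,
        standard_prescription,
        tumour_probability_map,
    )

    prob = tumour_probability_map(
        phantom.adc, phantom.rcbf, phantom.structures, fov=phantom.fov
    )
    dp_rx = dose_prescription(prob, phantom.structures)
    std_rx = standard_prescription(phantom.structures)
    dp = optimize_plan(dp_rx, phantom.structures, beam=fast_beam, mode="dose_painting")
    std = optimize_plan(std_rx, phantom.structures, beam=fast_beam, mode="standard")
    return compare_plans(std, dp, std_rx, dp_rx, prob, phantom.structures), dp, std


class TestComparePlans:
    def test_schema_covers_full_metric_panel(self, small_comparison):
        table, _, _ = small_comparison
        for struct in ("GTV", "CTV", "PTV"):
            metrics = set(table.loc[table["structure"] == struct, "metric"])
            assert metrics == set(REPORT_METRICS)

    def test_identical_plans_zero_differences(self, phantom, small_comparison):
        from dosepaint import standard_prescription, tumour_probability_map

        _, _, std = small_comparison
        prob = tumour_probability_map(
            phantom.adc, phantom.rcbf, phantom.structures, fov=phantom.fov
        )
        std_rx = standard_prescription(phantom.structures)
        table = compare_plans(std, std, std_rx, std_rx, prob, phantom.structures)
        diffs = table["difference"].dropna()
        assert np.allclose(diffs, 0.0)

    def test_dp_tcp_dominates_standard_in_gtv(self, small_comparison):
        """DP delivers ≥ 60 Gy everywhere in the GTV plus a boost, so its
        TCP can only exceed the uniform plan's (TCP is monotone in dose)."""
        table, _, _ = small_comparison
        row = table[(table["structure"] == "GTV") & (table["metric"] == "TCP")]
        assert row["difference"].iloc[0] >= 0.0
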