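import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kesblock.block_analysis import (
    BlockAnalysisError,
    block_amount,
    charge_density,
    charge_per_phase,
    charge_result,
    detect_block_threshold,
    electrode_area,
    fit_sd_curve,
    kes_half_period,
    mean_block_threshold,
    normalize_bd_sd,
    selectivity_index,
)
from kesblock.preprocess import TwitchMetrics
from kesblock.recording_io import ElectrodeSpec
from kesblock.recruitment import sigmoid_blk


def tm(peak, auc=0.0):
    return TwitchMetrics(peak_force_n=peak, auc_ns=auc)


class TestChargeChain:
    @pytest.mark.parametrize(
        "f_khz,expected_us", [(20.0, 25.0), (5.0, 100.0), (10.0, 50.0)]
    )
    def test_half_period(self, f_khz, expected_us):
        assert kes_half_period(f_khz) * 1e6 == pytest.approx(expected_us)

    def test_half_period_rejects_nonpositive(self):
        with pytest.raises(BlockAnalysisError):
            kes_half_period(0.0)

    def test_charge_per_phase_at_20khz_threshold(self):
        # 2.5 mA threshold at the 25 us half-period
        q = charge_per_phase(2.5, 25e-6)
        assert q == pytest.approx(3.979e-8, rel=1e-3)
        assert charge_per_phase(0.0, 25e-6) == 0.0
        assert charge_per_phase(5.0, 25e-6) == pytest.approx(2 * q)

    def test_electrode_area_values(self):
        assert electrode_area(27.5, 1.2) == pytest.approx(1.037e-3, rel=1e-3)
        assert electrode_area(27.5, 0.6) == pytest.approx(5.18e-4, rel=1e-3)
        assert electrode_area(1.0, 1.0) == pytest.approx(math.pi * 1e-5)

    def test_charge_density_composition(self):
        sigma = charge_density(3.979e-8, 1.037e-3)
        assert sigma == pytest.approx(38.4, rel=2e-3)
        assert charge_density(0.0, 1.0) == 0.0
        assert charge_density(1e-8, 0.5) == pytest.approx(2 * charge_density(1e-8, 1.0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        b=st.floats(0.1, 10.0),
        f=st.floats(1.0, 100.0),
        d=st.floats(5.0, 100.0),
        length=st.floats(0.1, 3.0),
    )
    def test_chain_matches_single_expression(self, b, f, d, length):
        # substituting T = 1/(2f) into Q = 2 B T / pi gives Q = B/(pi f),
        # so the whole chain collapses to sigma = B / (pi^2 f diameter length)
        via_chain = charge_result(b, f, ElectrodeSpec(d, length)).sigma_per_phase_uc_cm2
        b_a, f_hz = b * 1e-3, f * 1e3
        d_cm, l_cm = d * 1e-4, length * 1e-1
        closed = b_a / (math.pi**2 * f_hz * d_cm * l_cm) * 1e6
        assert abs(via_chain - closed) <= 1e-12 * abs(closed)


class TestBlockAmount:
    @pytest.mark.parametrize(
        "pre,blk,expected", [(1.0, 0.1, 0.9), (1.0, 1.0, 0.0), (1.0, 1.2, -0.2)]
    )
    def test_formula_including_facilitation(self, pre, blk, expected):
        m = block_amount(tm(pre), tm(blk))
        assert m.blk == pytest.approx(expected)

    def test_zero_pre_rejected(self):
        with pytest.raises(BlockAnalysisError):
            block_amount(tm(0.0), tm(0.1))


class TestBlockThreshold:
    def test_first_crossing(self):
        sweep = [(1.0, 1.0, 0.9), (2.0, 1.0, 0.5), (3.0, 1.0, 0.03)]
        thr = detect_block_threshold(sweep, 10.0)
        assert thr.b_th_ma == 3.0
        assert thr.blocked
        assert thr.t_kes_s == pytest.approx(50e-6)

    def test_never_crossing_returns_sentinel(self):
        sweep = [(1.0, 1.0, 0.9), (2.0, 1.0, 0.6)]
        thr = detect_block_threshold(sweep, 10.0)
        assert thr.b_th_ma is None and not thr.blocked

    def test_closed_form_grid_oracle(self):
        # smallest grid amplitude beyond sigma + ln(19)/beta
        sigma, beta = 1.2, 10.0
        grid = sigma * (0.5 + 0.05 * np.arange(21))
        sweep = [(a, 1.0, 1.0 - sigmoid_blk(a, sigma, beta)) for a in grid]
        thr = detect_block_threshold(sweep, 15.0)
        crossing = sigma + math.log(19) / beta
        expected = grid[np.searchsorted(grid, crossing, side="right")]
        assert thr.b_th_ma == pytest.approx(expected)

    def test_monotone_in_block_peaks(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            amps = np.sort(rng.uniform(0.5, 3.0, size=8))
            amps += 1e-3 * np.arange(8)  # enforce strict increase
            blocks = rng.uniform(0, 1, size=8)
            base = [(a, 1.0, b) for a, b in zip(amps, blocks)]
            raised = [(a, 1.0, min(1.0, b + 0.04)) for a, b in zip(amps, blocks)]
            t0 = detect_block_threshold(base, 10.0)
            t1 = detect_block_threshold(raised, 10.0)
            if t1.blocked:
                assert t0.blocked and t0.b_th_ma <= t1.b_th_ma

    def test_empty_sweep_rejected(self):
        with pytest.raises(BlockAnalysisError):
            detect_block_threshold([], 10.0)

    def test_mean_threshold_skips_sentinels(self):
        a = detect_block_threshold([(1.0, 1.0, 0.01)], 10.0)
        b = detect_block_threshold([(1.0, 1.0, 0.5)], 10.0)
        assert mean_block_threshold([a, b]) == 1.0


class TestSelectivity:
    def test_two_fascicle_difference(self):
        s = selectivity_index({"TF": 0.9, "PF": 0.12}, "TF")
        assert s.s_index == pytest.approx(0.78)

    @pytest.mark.parametrize("tf,pf,expected", [(1.0, 0.0, 1.0), (0.5, 0.5, 0.0)])
    def test_limits(self, tf, pf, expected):
        assert selectivity_index({"TF": tf, "PF": pf}, "TF").s_index == pytest.approx(expected)

    def test_antisymmetric_for_two_fascicles(self):
        blk = {"TF": 0.7, "PF": 0.2}
        assert selectivity_index(blk, "TF").s_index == pytest.approx(
            -selectivity_index(blk, "PF").s_index
        )

    def test_single_fascicle_rejected(self):
        with pytest.raises(BlockAnalysisError):
            selectivity_index({"TF": 0.5}, "TF")


class TestSDCurve:
    def test_exact_recovery_from_weiss_points(self):
        rh, ch = 81.0, 64.0
        pts = [(pw, rh * (1 + ch / pw)) for pw in (10, 25, 50, 100, 250)]
        fit = fit_sd_curve(pts)
        assert fit.rheobase_ua == pytest.approx(rh, rel=1e-6)
        assert fit.chronaxie_us == pytest.approx(ch, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_threshold_at_chronaxie_is_twice_rheobase(self):
        fit = fit_sd_curve([(pw, 50 * (1 + 80 / pw)) for pw in (10, 40, 80, 160)])
        thr_at_ch = fit.rheobase_ua * (1 + fit.chronaxie_us / fit.chronaxie_us)
        assert thr_at_ch == pytest.approx(2 * fit.rheobase_ua)

    def test_noisy_recovery_monte_carlo(self):
        # 5% multiplicative noise, 8 pulse widths, 200 draws
        rng = np.random.default_rng(11)
        rh, ch = 81.0, 64.0
        pws = np.array([10, 20, 35, 60, 90, 130, 180, 250], dtype=float)
        errs_rh, errs_ch = [], []
        for _ in range(200):
            thr = rh * (1 + ch / pws) * (1 + 0.05 * rng.standard_normal(8))
            fit = fit_sd_curve(np.column_stack([pws, thr]))
            errs_rh.append(abs(fit.rheobase_ua - rh) / rh)
            errs_ch.append(abs(fit.chronaxie_us - ch) / ch)
        assert np.median(errs_rh) < 0.10
        assert np.median(errs_ch) < 0.10

    def test_degenerate_points_rejected(self):
        with pytest.raises(BlockAnalysisError):
            fit_sd_curve([(50, 100.0), (50, 100.0), (50, 100.0)])


class TestBDNormalization:
    def test_anchor_maps_to_one(self):
        curve = {100.0: 0.74, 50.0: 1.2, 33.3: 1.8, 25.0: 2.5, 16.7: 3.98}
        norm = normalize_bd_sd(curve)
        ref = np.interp(17.0, sorted(curve), [curve[k] for k in sorted(curve)])
        assert norm[16.7] == pytest.approx(3.98 / ref)
        interp_back = np.interp(17.0, sorted(norm), [norm[k] for k in sorted(norm)])
        assert interp_back == pytest.approx(1.0)

    def test_scale_invariance(self):
        curve = {10.0: 2.0, 17.0: 4.0, 30.0: 6.0}
        a = normalize_bd_sd(curve)
        b = normalize_bd_sd({k: 7.3 * v for k, v in curve.items()})
        for k in curve:
            assert a[k] == pytest.approx(b[k])

    def test_linear_threshold_curve_closed_form(self):
        # B_TH linear in frequency -> value at half-period T is c/T;
        # normalized curve is 17/T
        curve = {t: 5.0 / t for t in (10.0, 17.0, 25.0, 50.0, 100.0)}
        norm = normalize_bd_sd(curve)
        for t in curve:
            assert norm[t] == pytest.approx(17.0 / t)

    def test_out_of_range_reference_rejected(self):
        with pytest.raises(BlockAnalysisError):
            normalize_bd_sd({20.0: 1.0, 30.0: 2.0})
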