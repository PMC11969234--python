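import math

import numpy as np
import pytest

from conftest import FS_TEST, simulate_sel
from kesblock.preprocess import (
    AveragedTwitch,
    PreprocessError,
    bandpass,
    phase_metrics,
    segment_phases,
    subtract_baseline,
    triggered_average,
    twitch_metrics,
)
from kesblock.recording_io import ForceRecording


def flat_rec(force, fs=1000.0, triggers=(), **kw):
    return ForceRecording(
        sampling_rate_hz=fs,
        force_n=np.asarray(force, dtype=float),
        activation_triggers_s=np.asarray(triggers, dtype=float),
        **kw,
    )


class TestBaseline:
    def test_constant_offset_removed(self):
        rec = flat_rec(0.3 * np.ones(3000), blank_end_s=1.0)
        out = subtract_baseline(rec)
        assert np.mean(out.force_n[:1000]) == pytest.approx(0.0, abs=1e-12)
        assert np.ptp(out.force_n) == 0.0

    def test_zero_mean_trace_unchanged(self):
        rng = np.random.default_rng(0)
        force = rng.normal(size=3000)
        force[:1000] -= force[:1000].mean()
        rec = flat_rec(force)
        out = subtract_baseline(rec)
        assert np.allclose(out.force_n, force, atol=1e-12)

    def test_drift_left_for_filter(self):
        # only the blank-window mean is removed; slope survives
        t = np.arange(5000) / 1000.0
        drift = 0.05 * t
        rec = flat_rec(drift)
        out = subtract_baseline(rec)
        manual = drift - drift[:1000].mean()
        assert np.allclose(out.force_n, manual, atol=1e-14)

    def test_short_blank_rejected(self):
        rec = flat_rec(np.zeros(3000), blank_end_s=0.5)
        with pytest.raises(PreprocessError, match="blank"):
            subtract_baseline(rec)


class TestBandpass:
    def test_passband_gain_at_5hz(self):
        fs = 5000.0
        t = np.arange(int(20 * fs)) / fs
        rec = flat_rec(np.sin(2 * math.pi * 5.0 * t), fs=fs)
        out = bandpass(rec).force_n
        mid = out[int(5 * fs) : int(15 * fs)]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.01)

    def test_kilohertz_carrier_removed(self):
        # a 1 kHz component (KES artifact surrogate) must be attenuated >= 99%
        fs = 30000.0
        t = np.arange(int(4 * fs)) / fs
        rec = flat_rec(np.sin(2 * math.pi * 1000.0 * t), fs=fs)
        out = bandpass(rec).force_n
        assert np.max(np.abs(out[int(fs) : int(3 * fs)])) < 0.01

    def test_dc_step_asymptotically_removed(self):
        fs = 1000.0
        force = np.ones(int(120 * fs))
        out = bandpass(flat_rec(force, fs=fs)).force_n
        assert abs(out[int(60 * fs)]) < 0.02

    def test_cutoff_above_nyquist_rejected(self):
        rec = flat_rec(np.zeros(1000), fs=150.0)
        with pytest.raises(PreprocessError, match="Nyquist"):
            bandpass(rec, lp_hz=100.0)


class TestSegmentation:
    def test_canonical_protocol_split(self, quiet_phys, truth_10khz):
        rec = simulate_sel(1.0, quiet_phys, truth_10khz)
        seg = segment_phases(rec)
        assert seg["pre"].size == 10
        assert seg["block"].size == 20
        assert seg["post"].size == 10

    def test_trigger_exactly_at_onset_goes_to_block(self):
        rec = flat_rec(np.zeros(9000), triggers=[2.8, 3.0, 3.2],
                       kes_onset_s=3.0, kes_offset_s=7.0, blank_end_s=1.0)
        seg = segment_phases(rec)
        assert list(seg["pre"]) == [2.8]
        assert list(seg["block"]) == [3.0, 3.2]

    def test_onset_recording_pre_post_empty(self):
        rec = flat_rec(np.zeros(9000), kes_onset_s=3.0, kes_offset_s=7.0)
        seg = segment_phases(rec)
        assert seg["pre"].size == 0 and seg["post"].size == 0
        assert seg.windows["block"] == (3.0, 7.0)

    def test_missing_gate_rejected(self):
        rec = flat_rec(np.zeros(9000))
        with pytest.raises(PreprocessError, match="gate"):
            segment_phases(rec)


class TestTriggeredAverage:
    def test_identical_twitches_average_exactly(self, quiet_phys, truth_10khz):
        rec = simulate_sel(0.0, quiet_phys, truth_10khz)
        seg = segment_phases(rec)
        avg = triggered_average(rec, seg["block"], discard_first=10)
        single_start = int(seg["block"][10] * FS_TEST)
        single = rec.force_n[single_start : single_start + avg.force_n.size]
        assert np.max(np.abs(avg.force_n - single)) < 1e-14
        assert avg.n_averaged == 10

    def test_pre_phase_averages_ten(self, quiet_phys, truth_10khz):
        rec = simulate_sel(0.0, quiet_phys, truth_10khz)
        seg = segment_phases(rec)
        assert triggered_average(rec, seg["pre"]).n_averaged == 10

    def test_noise_reduction_scales_with_sqrt_n(self):
        # averaging 10 windows of iid noise leaves ~ sigma/sqrt(10)
        sigma, n_win, fs = 0.5, 10, 1000.0
        resid = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            force = rng.normal(0, sigma, size=int(fs * 3))
            rec = flat_rec(force, fs=fs, triggers=0.2 * np.arange(1, n_win + 1))
            avg = triggered_average(rec, rec.activation_triggers_s)
            resid.append(np.std(avg.force_n))
        expected = sigma / math.sqrt(n_win)
        assert np.mean(resid) == pytest.approx(expected, rel=0.2)

    def test_permutation_invariance_over_retained(self, quiet_phys, truth_10khz):
        rec = simulate_sel(0.8, quiet_phys, truth_10khz)
        seg = segment_phases(rec)
        trig = seg["block"][10:]
        a = triggered_average(rec, trig)
        b = triggered_average(rec, trig[::-1])
        assert np.allclose(a.force_n, b.force_n, atol=1e-15)

    def test_all_discarded_rejected(self, quiet_phys, truth_10khz):
        rec = simulate_sel(0.0, quiet_phys, truth_10khz)
        seg = segment_phases(rec)
        with pytest.raises(PreprocessError, match="discard"):
            triggered_average(rec, seg["pre"], discard_first=10)


class TestTwitchMetrics:
    def test_unit_triangle_closed_form(self):
        fs = 10000.0
        t = np.arange(int(0.2 * fs)) / fs
        tri = np.clip(1.0 - np.abs(t - 0.05) / 0.05, 0, None)
        m = twitch_metrics(AveragedTwitch(t, tri, 1))
        assert m.peak_force_n == pytest.approx(1.0)
        assert m.auc_ns == pytest.approx(0.05, rel=1e-6)

    def test_all_zero_twitch(self):
        t = np.arange(200) / 1000.0
        m = twitch_metrics(AveragedTwitch(t, np.zeros(200), 1))
        assert (m.peak_force_n, m.auc_ns) == (0.0, 0.0)

    def test_twitch_kernel_peak_and_auc_closed_form(self):
        # g(t) = (t/Tc)exp(1-t/Tc): peak 1 at Tc; integral over [0, W]
        # equals e*Tc*(1 - exp(-W/Tc)(1 + W/Tc))
        fs, tc, w = 30000.0, 0.03, 0.2
        t = np.arange(int(w * fs)) / fs
        g = (t / tc) * np.exp(1 - t / tc)
        m = twitch_metrics(AveragedTwitch(t, g, 1))
        auc_exact = math.e * tc * (1 - math.exp(-w / tc) * (1 + w / tc))
        assert m.peak_force_n == pytest.approx(1.0, rel=1e-6)
        assert m.auc_ns == pytest.approx(auc_exact, rel=1e-4)

    def test_empty_window_rejected(self):
        with pytest.raises(PreprocessError, match="empty"):
            twitch_metrics(AveragedTwitch(np.empty(0), np.empty(0), 0))


class TestPipelineLinearity:
    def test_scaling_recording_scales_metrics(self, quiet_phys, truth_10khz):
        rec = simulate_sel(1.0, quiet_phys, truth_10khz)
        scaled = ForceRecording(
            sampling_rate_hz=rec.sampling_rate_hz,
            force_n=3.0 * rec.force_n,
            activation_triggers_s=rec.activation_triggers_s,
            kes_onset_s=rec.kes_onset_s,
            kes_offset_s=rec.kes_offset_s,
            blank_end_s=rec.blank_end_s,
            condition=rec.condition,
        )
        m1 = phase_metrics(rec)
        m2 = phase_metrics(scaled)
        for phase in m1:
            assert m2[phase].peak_force_n == pytest.approx(3 * m1[phase].peak_force_n, rel=1e-9)
            assert m2[phase].auc_ns == pytest.approx(3 * m1[phase].auc_ns, rel=1e-9)

    def test_noiseless_average_matches_single_twitch_metrics(self, quiet_phys, truth_10khz):
        rec = simulate_sel(0.9, quiet_phys, truth_10khz)
        seg = segment_phases(rec)
        avg = triggered_average(rec, seg["block"], discard_first=10)
        single = triggered_average(rec, seg["block"][10:11])
        ma, ms = twitch_metrics(avg), twitch_metrics(single)
        assert ma.peak_force_n == pytest.approx(ms.peak_force_n, abs=1e-9)
        assert ma.auc_ns == pytest.approx(ms.auc_ns, abs=1e-9)
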