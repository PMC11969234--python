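import numpy as np
import pytest

from conftest import FS_TEST, sel_condition, simulate_sel
from kesblock.preprocess import segment_phases, triggered_average
from kesblock.recording_io import TrialCondition
from kesblock.synthetic_data import (
    BlockGroundTruth,
    MusclePhysiology,
    OnsetGroundTruth,
    ProtocolError,
    SweepSpec,
    make_protocol,
    simulate_dataset,
    simulate_recording,
    twitch_kernel,
)


class TestProtocol:
    def test_three_phase_layout_and_trigger_counts(self):
        # 2 s pre / 4 s block / 2 s post at 5 Hz after a 1 s blank
        p = make_protocol("SEL", sel_condition(15.0, 1.0))
        assert p.duration_s == pytest.approx(9.0)
        seg_pre = p.triggers_s()[p.triggers_s() < p.kes_onset_s]
        seg_block = p.triggers_s()[
            (p.triggers_s() >= p.kes_onset_s) & (p.triggers_s() < p.kes_offset_s)
        ]
        seg_post = p.triggers_s()[p.triggers_s() >= p.kes_offset_s]
        assert (seg_pre.size, seg_block.size, seg_post.size) == (10, 20, 10)

    def test_onset_kind_silences_activation(self):
        p = make_protocol("ONSET", sel_condition(10.0, 0.6))
        assert p.triggers_s().size == 0
        assert p.condition.activation_amplitude_ua == 0.0
        assert p.kes_enabled

    def test_ideal_block_disables_all_stimuli_in_block(self):
        p = make_protocol("FATIGUE-ideal-block", sel_condition(10.0, 1.0))
        assert p.condition.kes_amplitude_ma == 0.0
        assert not p.kes_enabled
        trig = p.triggers_s()
        assert trig.size == 20  # 10 pre + 10 post only
        assert not np.any((trig >= p.kes_onset_s) & (trig < p.kes_offset_s))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ProtocolError, match="unknown"):
            make_protocol("RAMP", sel_condition())


class TestSimulateRecording:
    def test_no_kes_equal_peaks_without_fatigue(self, quiet_phys, truth_10khz):
        rec = simulate_sel(0.0, quiet_phys, truth_10khz)
        trig = rec.activation_triggers_s
        peaks = [
            rec.force_n[int(t * FS_TEST) : int((t + 0.2) * FS_TEST)].max() for t in trig
        ]
        assert np.ptp(peaks) == 0.0

    def test_fatigue_declines_peaks_monotonically(self, truth_10khz):
        phys = MusclePhysiology(
            noise_sd_n=0, drift_amplitude_n=0, fatigue_rate=0.01, recovery_rate_per_s=0
        )
        rec = simulate_sel(0.0, phys, truth_10khz)
        trig = rec.activation_triggers_s
        peaks = np.array(
            [rec.force_n[int(t * FS_TEST) : int((t + 0.2) * FS_TEST)].max() for t in trig]
        )
        assert np.all(np.diff(peaks) < 0)

    def test_saturated_block_zeroes_block_phase_only(self, quiet_phys, truth_10khz):
        # amplitude far above sigma: sigmoid saturates at full block
        rec = simulate_sel(50.0, quiet_phys, truth_10khz)
        seg = segment_phases(rec)
        blk = triggered_average(rec, seg["block"], discard_first=0)
        pre = triggered_average(rec, seg["pre"])
        assert np.max(np.abs(blk.force_n)) < 1e-12
        assert pre.force_n.max() == pytest.approx(1.0)

    def test_same_seed_bit_identical(self, truth_10khz):
        phys = MusclePhysiology()  # noise and drift on
        a = simulate_sel(1.0, phys, truth_10khz, seed=42)
        b = simulate_sel(1.0, phys, truth_10khz, seed=42)
        assert np.array_equal(a.force_n, b.force_n)
        c = simulate_sel(1.0, phys, truth_10khz, seed=43)
        assert not np.array_equal(a.force_n, c.force_n)

    def test_force_finite_trigger_count_and_duration(self, truth_10khz):
        phys = MusclePhysiology()
        onset = OnsetGroundTruth()
        rec = simulate_sel(1.2, phys, truth_10khz, onset=onset, seed=7)
        assert np.all(np.isfinite(rec.force_n))
        assert rec.activation_triggers_s.size == 40
        p = make_protocol("SEL", sel_condition())
        assert abs(rec.duration_s - p.duration_s) <= 1.0 / FS_TEST

    def test_facilitation_off_subthreshold_peaks_match_pre(self, quiet_phys, truth_10khz):
        phys_gain = MusclePhysiology(
            noise_sd_n=0, drift_amplitude_n=0, fatigue_rate=0,
            recovery_rate_per_s=0, facilitation_gain=1.3,
        )
        amp = 0.5 * truth_10khz.sigma_true_ma  # BLK_true ~ 0.25%
        off = simulate_sel(amp, quiet_phys, truth_10khz)
        on = simulate_sel(amp, phys_gain, truth_10khz, facilitation=True)
        seg = segment_phases(off)
        pre = triggered_average(off, seg["pre"]).force_n.max()
        blk_off = triggered_average(off, seg["block"], 10).force_n.max()
        blk_on = triggered_average(on, segment_phases(on)["block"], 10).force_n.max()
        # without facilitation the sub-threshold block twitch only reflects
        # the (small) true block; with it the twitch exceeds pre-block
        assert blk_off == pytest.approx(pre * (1 - truth_10khz.blk(amp)), rel=1e-9)
        assert blk_on > pre

    def test_non_finite_parameters_rejected(self, quiet_phys):
        with pytest.raises(ValueError, match="non-finite"):
            simulate_recording(
                make_protocol("SEL", sel_condition(10.0, np.nan)),
                quiet_phys,
                BlockGroundTruth(1.2, 10.0),
            )


class TestSimulateDataset:
    def test_sel_sweep_grid_and_manifest(self, tmp_path, quiet_phys):
        sweep = SweepSpec(kind="SEL", frequencies_khz=(10.0, 15.0, 20.0))
        manifest = simulate_dataset(
            sweep, seed=3, out_dir=tmp_path, phys=quiet_phys, sampling_rate_hz=FS_TEST
        )
        assert len(manifest) == 63  # 3 frequencies x 21 amplitudes
        assert manifest["kes_frequency_khz"].nunique() == 3
        for rel in manifest["recording"]:
            assert (tmp_path / rel).with_suffix(".csv").exists()

    def test_fatigue_sweep_produces_both_scenarios(self, tmp_path, quiet_phys):
        sweep = SweepSpec(kind="FATIGUE", frequencies_khz=(10.0,), n_repeats=10)
        manifest = simulate_dataset(
            sweep, seed=3, out_dir=tmp_path, phys=quiet_phys, sampling_rate_hz=FS_TEST
        )
        counts = manifest["protocol_kind"].value_counts()
        assert counts["FATIGUE-no-KES"] == 10
        assert counts["FATIGUE-ideal-block"] == 10

    def test_seeded_dataset_reproducible(self, tmp_path, quiet_phys):
        sweep = SweepSpec(
            kind="SEL", frequencies_khz=(10.0,), ratio_stop=0.7, dataset_id="A"
        )
        m1 = simulate_dataset(sweep, 9, tmp_path / "r1", quiet_phys, sampling_rate_hz=FS_TEST)
        m2 = simulate_dataset(sweep, 9, tmp_path / "r2", quiet_phys, sampling_rate_hz=FS_TEST)
        assert m1.equals(m2)
        for rel in m1["recording"]:
            a = (tmp_path / "r1" / rel).with_suffix(".csv").read_bytes()
            b = (tmp_path / "r2" / rel).with_suffix(".csv").read_bytes()
            assert a == b

    def test_empty_grid_rejected(self, tmp_path):
        with pytest.raises(ProtocolError, match="empty"):
            simulate_dataset(
                SweepSpec(kind="SEL", frequencies_khz=()), 0, tmp_path
            )


def test_twitch_kernel_peaks_at_contraction_time():
    t = np.linspace(0, 0.2, 20001)
    g = twitch_kernel(t, 0.03)
    assert g.max() == pytest.approx(1.0, abs=1e-6)
    assert t[g.argmax()] == pytest.approx(0.03, abs=1e-4)
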