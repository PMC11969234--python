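"""Synthetic isometric-force generator with known ground truth.

The generator emulates the structure the downstream analysis assumes: a 1 s
blank, a pre-block phase of 5 Hz evoked twitches, a block phase during which
kilohertz stimulation (KES) attenuates twitches according to a sigmoid
recruitment law, an onset transient at KES switch-on, and a post-block phase.
Twitch-by-twitch fatigue with time-based recovery, sub-threshold
facilitation, sensor noise and slow baseline drift are all optional and
parameterised, so every downstream estimator has a recoverable target.

Model summary
-------------
* Twitch kernel: ``g(t) = (t/T_c) exp(1 - t/T_c)``, peak 1 at ``t = T_c``
  (the classic two-parameter twitch shape), truncated at one inter-stimulus
  interval so successive twitches do not overlap at 5 Hz.
* Block law: during the block phase the twitch gain is multiplied by
  ``1 - BLK_true(I_KES)`` where ``BLK_true`` is the logistic recruitment
  sigmoid with ground-truth parameters ``(sigma_true, beta_true)``.
* Onset transient: gamma-shaped pulse ``A (x) exp(1 - x)``, ``x = (t - t_on)/tau``,
  whose 10%-of-peak crossing times have a closed form via the Lambert W
  function, making the onset-duration estimator analytically checkable.
* Fatigue: geometric per-twitch decline proportional to the transmitted
  activation, with exponential recovery toward full force at
  ``recovery_rate`` per second whenever the muscle rests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import lambertw

from .recording_io import (
    ElectrodeSpec,
    ForceRecording,
    TrialCondition,
    write_manifest,
    write_recording,
)
from .recruitment import sigmoid_blk

#: 10%-of-peak crossings of x*exp(1-x): solutions of x e^(1-x) = 0.1.
ONSET_X10_LO = float(-lambertw(-0.1 / math.e, 0).real)
ONSET_X10_HI = float(-lambertw(-0.1 / math.e, -1).real)
#: TD of a unit-tau gamma onset kernel, in units of tau.
ONSET_X10_SPAN = ONSET_X10_HI - ONSET_X10_LO

#: KES amplitude (as a fraction of sigma_true) below which sub-threshold
#: facilitation applies when enabled.
FACILITATION_CUTOFF = 0.75


class ProtocolError(ValueError):
    """Raised for unknown protocol kinds or degenerate sweep grids."""


@dataclass(frozen=True)
class MusclePhysiology:
    """Muscle and sensor parameters of the simulated preparation.

    max_twitch_force in newtons; contraction_time (T_c) in seconds;
    fatigue_rate is the fractional per-twitch force decline while the fiber
    pool is driven; recovery_rate is the fractional per-second recovery of
    the force deficit while the pool rests; facilitation_gain >= 1 scales
    twitches under sub-threshold KES when facilitation is enabled; noise_sd
    (N) is additive white sensor noise and drift_amplitude/drift_period
    parameterise a slow sinusoidal baseline wander.
    """

    max_twitch_force_n: float = 1.0
    contraction_time_s: float = 0.030
    relaxation_shape: float = 1.0
    fatigue_rate: float = 0.006
    recovery_rate_per_s: float = 0.02
    facilitation_gain: float = 1.0
    noise_sd_n: float = 0.01
    drift_amplitude_n: float = 0.02
    drift_period_s: float = 60.0

    def __post_init__(self) -> None:
        if not (self.max_twitch_force_n > 0 and self.contraction_time_s > 0):
            raise ValueError("max_twitch_force and contraction_time must be > 0")
        if not (0 <= self.fatigue_rate < 1):
            raise ValueError("fatigue_rate must be in [0, 1)")
        if self.recovery_rate_per_s < 0 or self.noise_sd_n < 0:
            raise ValueError("recovery_rate and noise_sd must be >= 0")
        if self.facilitation_gain < 1:
            raise ValueError("facilitation_gain must be >= 1")


@dataclass(frozen=True)
class BlockGroundTruth:
    """True sigmoid recruitment parameters at one KES frequency."""

    sigma_true_ma: float
    beta_true_per_ma: float

    def __post_init__(self) -> None:
        if not (self.sigma_true_ma > 0 and self.beta_true_per_ma > 0):
            raise ValueError("sigma_true and beta_true must be positive")

    def blk(self, i_kes_ma: float) -> float:
        return sigmoid_blk(i_kes_ma, self.sigma_true_ma, self.beta_true_per_ma)


@dataclass(frozen=True)
class OnsetGroundTruth:
    """Parameters of the KES-onset transient.

    ``onset_duration_s`` is the true 10%-to-10% duration (TD) of the gamma
    kernel at the 10 kHz reference frequency; both peak and duration shrink
    proportionally to 10 kHz / f_KES, mirroring the observed attenuation of
    the onset at higher blocking frequencies.  ``spillover_fraction`` scales
    the transient seen from the non-target fascicle.
    """

    onset_peak_n: float = 1.5
    onset_duration_s: float = 0.8
    onset_shape: str = "gamma"
    spillover_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.onset_peak_n < 0 or self.onset_duration_s < 0:
            raise ValueError("onset peak and duration must be >= 0")
        if not 0 <= self.spillover_fraction <= 1:
            raise ValueError("spillover_fraction must lie in [0, 1]")
        if self.onset_shape not in ("gamma", "triangle"):
            raise ValueError(f"unknown onset_shape {self.onset_shape!r}")


#: Default ground-truth 50%-block amplitudes (mA) per KES frequency (kHz),
#: anchored to the reported per-frequency mean block thresholds.
DEFAULT_SIGMA_BY_FREQ = {5.0: 0.74, 10.0: 1.2, 15.0: 1.8, 20.0: 2.5, 25.0: 3.2, 30.0: 3.98}
#: Default recruitment rates (1/mA): decreasing with frequency.
DEFAULT_BETA_BY_FREQ = {5.0: 14.0, 10.0: 12.0, 15.0: 10.0, 20.0: 8.0, 25.0: 7.0, 30.0: 6.0}
#: Spillover block truth seen from the peroneal fascicle: much higher sigma,
#: shallow slope, so PF block stays partial over the tested amplitude range.
DEFAULT_PF_TRUTH = {
    5.0: BlockGroundTruth(1.6, 1.5),
    10.0: BlockGroundTruth(2.4, 1.5),
    15.0: BlockGroundTruth(3.9, 1.5),
    20.0: BlockGroundTruth(5.8, 1.5),
    25.0: BlockGroundTruth(7.2, 1.5),
    30.0: BlockGroundTruth(8.8, 1.5),
}


def default_truth(frequency_khz: float, fascicle: str = "TF") -> BlockGroundTruth:
    """Ground-truth recruitment parameters for a frequency and fascicle."""
    if fascicle == "PF":
        table = DEFAULT_PF_TRUTH
        if frequency_khz in table:
            return table[frequency_khz]
        raise KeyError(f"no default PF truth at {frequency_khz} kHz")
    sig = DEFAULT_SIGMA_BY_FREQ.get(frequency_khz)
    bet = DEFAULT_BETA_BY_FREQ.get(frequency_khz)
    if sig is None or bet is None:
        raise KeyError(f"no default truth at {frequency_khz} kHz")
    return BlockGroundTruth(sig, bet)


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolSpec:
    """Phase layout and stimulus gating of one trial.

    Timeline (seconds from recording start): a stimulus-free blank, then
    pre-block, block and post-block phases.  Activation pulses run at
    ``pulse_rate_hz`` during the phases listed in ``activation_phases``;
    the KES gate spans exactly the block phase when ``kes_enabled``.
    """

    kind: str
    condition: TrialCondition
    blank_s: float = 1.0
    pre_s: float = 2.0
    block_s: float = 4.0
    post_s: float = 2.0
    pulse_rate_hz: float = 5.0
    activation_phases: tuple[str, ...] = ("pre", "block", "post")
    kes_enabled: bool = True

    @property
    def pre_start_s(self) -> float:
        return self.blank_s

    @property
    def kes_onset_s(self) -> float:
        return self.blank_s + self.pre_s

    @property
    def kes_offset_s(self) -> float:
        return self.kes_onset_s + self.block_s

    @property
    def duration_s(self) -> float:
        return self.blank_s + self.pre_s + self.block_s + self.post_s

    def phase_window(self, phase: str) -> tuple[float, float]:
        starts = {
            "pre": self.pre_start_s,
            "block": self.kes_onset_s,
            "post": self.kes_offset_s,
        }
        spans = {"pre": self.pre_s, "block": self.block_s, "post": self.post_s}
        return starts[phase], starts[phase] + spans[phase]

    def triggers_s(self) -> np.ndarray:
        """Activation trigger timestamps across the gated phases."""
        isi = 1.0 / self.pulse_rate_hz
        out: list[np.ndarray] = []
        for phase in ("pre", "block", "post"):
            if phase not in self.activation_phases:
                continue
            start, end = self.phase_window(phase)
            n = int(round((end - start) * self.pulse_rate_hz))
            out.append(start + isi * np.arange(n))
        if not out:
            return np.empty(0)
        return np.concatenate(out)


def make_protocol(kind: str, condition: TrialCondition, **overrides) -> ProtocolSpec:
    """Build the three-phase protocol for one trial.

    ``B_TH`` and ``SEL`` run activation throughout with KES gated to the
    block phase.  ``ONSET`` silences the activation train entirely (the KES
    transient is observed in isolation).  ``FATIGUE-no-KES`` keeps the KES
    amplitude at zero; ``FATIGUE-ideal-block`` additionally switches the
    activation off during the block phase, emulating a perfect block with no
    stimulation delivered at all.
    """
    if kind not in ("B_TH", "SEL", "ONSET", "FATIGUE-no-KES", "FATIGUE-ideal-block"):
        raise ProtocolError(f"unknown protocol kind {kind!r}")
    activation: tuple[str, ...] = ("pre", "block", "post")
    kes_enabled = True
    if kind == "ONSET":
        activation = ()
        condition = replace(condition, activation_amplitude_ua=0.0)
    elif kind == "FATIGUE-no-KES":
        kes_enabled = False
        condition = replace(condition, kes_amplitude_ma=0.0)
    elif kind == "FATIGUE-ideal-block":
        kes_enabled = False
        activation = ("pre", "post")
        condition = replace(condition, kes_amplitude_ma=0.0)
    condition = replace(condition, protocol_kind=kind)
    return ProtocolSpec(
        kind=kind,
        condition=condition,
        activation_phases=activation,
        kes_enabled=kes_enabled,
        **overrides,
    )


# ---------------------------------------------------------------------------
# single-trial simulation
# ---------------------------------------------------------------------------


def twitch_kernel(t: np.ndarray, contraction_time_s: float) -> np.ndarray:
    """Unit twitch ``(t/T_c) exp(1 - t/T_c)`` for t >= 0 (0 elsewhere)."""
    x = np.asarray(t, dtype=float) / contraction_time_s
    out = np.where(x > 0, x * np.exp(1.0 - np.clip(x, 0, 500.0)), 0.0)
    return out


def onset_kernel(x: np.ndarray, shape: str = "gamma") -> np.ndarray:
    """Unit-peak onset transient on the normalised axis ``x = (t-t0)/tau``.

    ``gamma``: x exp(1-x); 10% crossings at ONSET_X10_LO/HI.
    ``triangle``: rise over x in [0,1], fall over [1,2]; 10% crossings at
    0.1 and 1.9.
    """
    x = np.asarray(x, dtype=float)
    if shape == "gamma":
        return np.where(x > 0, x * np.exp(1.0 - np.clip(x, 0, 500.0)), 0.0)
    if shape == "triangle":
        return np.clip(1.0 - np.abs(x - 1.0), 0.0, None)
    raise ValueError(f"unknown onset shape {shape!r}")


def onset_true_td(onset: OnsetGroundTruth, frequency_khz: float) -> float:
    """Closed-form 10%-to-10% duration of the simulated onset transient."""
    scale = 10.0 / frequency_khz
    if onset.onset_peak_n == 0 or onset.onset_duration_s == 0:
        return 0.0
    if onset.onset_shape == "gamma":
        return onset.onset_duration_s * scale
    # triangle: kernel spans x in [0, 2] with crossings at 0.1 and 1.9;
    # onset_duration_s is again the TD at 10 kHz.
    return onset.onset_duration_s * scale


def _onset_tau(onset: OnsetGroundTruth, frequency_khz: float) -> float:
    scale = 10.0 / frequency_khz
    if onset.onset_shape == "gamma":
        return onset.onset_duration_s * scale / ONSET_X10_SPAN
    return onset.onset_duration_s * scale / 1.8


def simulate_recording(
    protocol: ProtocolSpec,
    phys: MusclePhysiology,
    truth: BlockGroundTruth,
    onset: OnsetGroundTruth | None = None,
    seed: int = 0,
    sampling_rate_hz: float = 30_000.0,
    facilitation: bool = False,
    electrodes: tuple[ElectrodeSpec, ...] = (),
) -> ForceRecording:
    """Simulate one force recording for a protocol with known ground truth.

    Each activation trigger adds a twitch kernel scaled by the current
    muscle force state and by the transmitted activation (1 - BLK during the
    KES gate).  The KES onset transient, fatigue/recovery dynamics,
    facilitation, white noise and sinusoidal drift are applied as configured.
    Same ``seed`` (with identical parameters) reproduces the trace bit for
    bit.
    """
    for name, val in (
        ("sigma_true", truth.sigma_true_ma),
        ("beta_true", truth.beta_true_per_ma),
        ("kes_amplitude", protocol.condition.kes_amplitude_ma),
    ):
        if not math.isfinite(val):
            raise ValueError(f"non-finite parameter {name}")
    rng = np.random.default_rng(seed)
    fs = float(sampling_rate_hz)
    n = int(round(protocol.duration_s * fs))
    force = np.zeros(n)
    cond = protocol.condition
    i_kes = cond.kes_amplitude_ma

    blk_true = truth.blk(i_kes) if (protocol.kes_enabled and i_kes > 0) else 0.0
    gain = 1.0
    if (
        facilitation
        and protocol.kes_enabled
        and 0 < i_kes < FACILITATION_CUTOFF * truth.sigma_true_ma
    ):
        gain = phys.facilitation_gain

    isi = 1.0 / protocol.pulse_rate_hz
    kernel_len = int(round(isi * fs))  # truncated at one inter-stimulus interval
    kernel = twitch_kernel(np.arange(kernel_len) / fs, phys.contraction_time_s)

    triggers = protocol.triggers_s()
    state = 1.0  # current force capacity, 1 = rested
    prev_t = triggers[0] if triggers.size else 0.0
    for trig in triggers:
        dt = trig - prev_t
        if phys.recovery_rate_per_s > 0 and dt > 0:
            state = 1.0 - (1.0 - state) * math.exp(-phys.recovery_rate_per_s * dt)
        prev_t = trig
        in_block = protocol.kes_onset_s <= trig < protocol.kes_offset_s
        transmit = (1.0 - blk_true) * gain if in_block else 1.0
        amp = phys.max_twitch_force_n * state * transmit
        i0 = int(round(trig * fs))
        seg = min(kernel_len, n - i0)
        if seg > 0 and amp != 0.0:
            force[i0 : i0 + seg] += amp * kernel[:seg]
        state *= 1.0 - phys.fatigue_rate * min(transmit, 1.0)

    observes_target = cond.fascicle_a == cond.fascicle_b
    if onset is not None and protocol.kes_enabled and i_kes > 0 and onset.onset_peak_n > 0:
        peak = onset.onset_peak_n * (10.0 / cond.kes_frequency_khz)
        if not observes_target:
            peak *= onset.spillover_fraction
        tau = _onset_tau(onset, cond.kes_frequency_khz)
        if peak > 0 and tau > 0:
            i0 = int(round(protocol.kes_onset_s * fs))
            span = int(round(min(30.0 * tau, protocol.duration_s) * fs))
            idx = np.arange(i0, min(i0 + span, n))
            x = (idx / fs - protocol.kes_onset_s) / tau
            force[idx] += peak * onset_kernel(x, onset.onset_shape)

    sign = 1.0 if cond.fascicle_a == "TF" else -1.0
    force *= sign

    t = np.arange(n) / fs
    if phys.drift_amplitude_n > 0:
        phase = rng.uniform(0, 2 * math.pi)
        force += phys.drift_amplitude_n * np.sin(
            2 * math.pi * t / phys.drift_period_s + phase
        )
    if phys.noise_sd_n > 0:
        force += rng.normal(0.0, phys.noise_sd_n, size=n)

    return ForceRecording(
        sampling_rate_hz=fs,
        force_n=force,
        activation_triggers_s=triggers,
        kes_onset_s=protocol.kes_onset_s,
        kes_offset_s=protocol.kes_offset_s,
        blank_end_s=protocol.blank_s,
        axis_convention="TF-positive",
        condition=cond,
        electrodes=electrodes,
    )


# ---------------------------------------------------------------------------
# dataset sweeps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepSpec:
    """Grid specification for a simulated dataset.

    Amplitude grids follow the amplitude-sweep design: ratios of the
    ground-truth 50%-block amplitude from ``ratio_start`` to ``ratio_stop``
    in ``ratio_step`` increments (defaults 0.5..1.5 by 0.05, i.e. 21 cells).
    FATIGUE sweeps ignore the amplitude grid and produce ``n_repeats``
    repetitions of each control scenario.
    """

    kind: str
    frequencies_khz: tuple[float, ...] = (10.0, 15.0, 20.0)
    ratio_start: float = 0.5
    ratio_stop: float = 1.5
    ratio_step: float = 0.05
    n_repeats: int = 10
    fascicle_a: str = "TF"
    dataset_id: str = "DS0"
    animal_id: str = "SYN0"
    electrode_pair_id: str = "PAIR0"

    def ratios(self) -> np.ndarray:
        n = int(round((self.ratio_stop - self.ratio_start) / self.ratio_step)) + 1
        return self.ratio_start + self.ratio_step * np.arange(n)


def default_electrodes(rng: np.random.Generator) -> tuple[ElectrodeSpec, ElectrodeSpec]:
    """Draw an aLIFE/bLIFE pair with realistic geometry spread."""
    a_len = float(np.clip(rng.normal(0.6, 0.3), 0.2, 1.5))
    b_len = float(np.clip(rng.normal(1.2, 0.4), 0.4, 2.4))
    return (
        ElectrodeSpec(27.5, a_len, float(np.clip(rng.normal(28.0, 12.5), 5, 80)), "aLIFE"),
        ElectrodeSpec(27.5, b_len, float(np.clip(rng.normal(8.9, 2.3), 2, 20)), "bLIFE"),
    )


def simulate_dataset(
    sweep: SweepSpec,
    seed: int,
    out_dir: str | Path,
    phys: MusclePhysiology | None = None,
    onset: OnsetGroundTruth | None = None,
    truth_by_freq: Mapping[float, BlockGroundTruth] | None = None,
    sampling_rate_hz: float = 30_000.0,
    facilitation: bool = False,
) -> pd.DataFrame:
    """Simulate one dataset sweep; write recordings and return the manifest.

    One recording is produced per (frequency, amplitude) cell — or per
    repetition and scenario for FATIGUE sweeps — with the per-row RNG stream
    derived from ``(seed, row index)`` so the dataset is reproducible
    row-wise.  Manifest rows link each recording file to its condition and
    ground truth.
    """
    if not sweep.frequencies_khz or (
        sweep.kind not in ("FATIGUE-no-KES", "FATIGUE-ideal-block")
        and sweep.ratios().size == 0
    ):
        raise ProtocolError("empty sweep grid")
    phys = phys or MusclePhysiology()
    onset = OnsetGroundTruth() if onset is None else onset
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pair_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xE1,)))
    alife, blife = default_electrodes(pair_rng)

    rows: list[dict] = []
    row_idx = 0

    def cells():
        if sweep.kind == "FATIGUE":
            for rep in range(sweep.n_repeats):
                yield "FATIGUE-no-KES", sweep.frequencies_khz[0], 0.0, rep
            for rep in range(sweep.n_repeats):
                yield "FATIGUE-ideal-block", sweep.frequencies_khz[0], 0.0, rep
        elif sweep.kind in ("FATIGUE-no-KES", "FATIGUE-ideal-block"):
            for rep in range(sweep.n_repeats):
                yield sweep.kind, sweep.frequencies_khz[0], 0.0, rep
        else:
            for f in sweep.frequencies_khz:
                for r in sweep.ratios():
                    yield sweep.kind, f, float(r), 0

    for kind, freq, ratio, rep in cells():
        # Amplitude grids are ratios of the tibial-fascicle threshold (the
        # B_avg rule): spillover sweeps in PF share the TF amplitude axis.
        tf_truth = (
            truth_by_freq[freq]
            if truth_by_freq is not None
            else default_truth(freq, "TF")
        )
        truth = (
            tf_truth if sweep.fascicle_a == "TF" else default_truth(freq, "PF")
        )
        amp = ratio * tf_truth.sigma_true_ma if ratio else 0.0
        cond = TrialCondition(
            kes_frequency_khz=freq,
            kes_amplitude_ma=amp,
            protocol_kind=kind,
            fascicle_a=sweep.fascicle_a,
            fascicle_b="TF",
            animal_id=sweep.animal_id,
            electrode_pair_id=sweep.electrode_pair_id,
            dataset_id=sweep.dataset_id,
            amplitude_ratio=ratio or None,
        )
        protocol = make_protocol(kind, cond)
        row_seed = np.random.SeedSequence(seed, spawn_key=(row_idx,))
        rec = simulate_recording(
            protocol,
            phys,
            truth,
            onset,
            seed=row_seed,
            sampling_rate_hz=sampling_rate_hz,
            facilitation=facilitation,
            electrodes=(alife, blife),
        )
        stem = f"{sweep.dataset_id}_{kind}_{freq:g}kHz_{row_idx:04d}"
        write_recording(rec, out_dir / stem)
        rows.append(
            {
                "recording": stem,
                "dataset_id": sweep.dataset_id,
                "animal_id": sweep.animal_id,
                "electrode_pair_id": sweep.electrode_pair_id,
                "protocol_kind": kind,
                "kes_frequency_khz": freq,
                "kes_amplitude_ma": amp,
                "amplitude_ratio": ratio if ratio else np.nan,
                "repetition": rep,
                "fascicle_a": sweep.fascicle_a,
                "fascicle_b": "TF",
                "blife_diameter_um": blife.wire_diameter_um,
                "blife_length_mm": blife.active_length_mm,
                "sigma_true_ma": truth.sigma_true_ma,
                "beta_true_per_ma": truth.beta_true_per_ma,
                "blk_true": truth.blk(amp) if amp > 0 and kind in ("B_TH", "SEL") else 0.0,
            }
        )
        row_idx += 1

    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / f"{sweep.dataset_id}_manifest.csv")
    return manifest


def simulate_replica(
    out_dir: str | Path,
    seed: int,
    n_bth: int = 2,
    n_sel_tf: int = 2,
    n_sel_pf: int = 2,
    n_onset_tf: int = 2,
    n_onset_pf: int = 1,
    n_fatigue: int = 2,
    sel_frequencies: tuple[float, ...] = (10.0, 15.0, 20.0),
    bth_frequencies: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
    ratio_step: float = 0.05,
    fatigue_repeats: int = 10,
    sampling_rate_hz: float = 5000.0,
    phys: MusclePhysiology | None = None,
    onset: OnsetGroundTruth | None = None,
) -> pd.DataFrame:
    """Simulate a study-shaped collection of datasets and one joint manifest.

    Produces ``n_bth`` threshold sweeps across the full frequency range,
    amplitude sweeps in the target fascicle (``n_sel_tf``) and spillover
    sweeps observed from the peroneal fascicle (``n_sel_pf``), onset
    datasets for both observation sides, and fatigue control datasets.
    Dataset counts default to a scaled-down replica; pass larger counts to
    approach the full study layout.
    """
    out_dir = Path(out_dir)
    manifests = []
    specs: list[SweepSpec] = []
    for i in range(n_bth):
        specs.append(
            SweepSpec(
                kind="B_TH", frequencies_khz=bth_frequencies, ratio_step=ratio_step,
                dataset_id=f"BTH{i}", animal_id=f"SYN{i % 3}", electrode_pair_id=f"P{i}",
            )
        )
    for i in range(n_sel_tf):
        specs.append(
            SweepSpec(
                kind="SEL", frequencies_khz=sel_frequencies, ratio_step=ratio_step,
                dataset_id=f"SEL{i}", animal_id=f"SYN{i % 3}", electrode_pair_id=f"PS{i}",
            )
        )
    for i in range(n_sel_pf):
        specs.append(
            SweepSpec(
                kind="SEL", frequencies_khz=sel_frequencies, ratio_step=ratio_step,
                fascicle_a="PF", dataset_id=f"SEL{n_sel_tf + i}",
                animal_id=f"SYN{i % 3}", electrode_pair_id=f"PP{i}",
            )
        )
    for i in range(n_onset_tf + n_onset_pf):
        specs.append(
            SweepSpec(
                kind="ONSET", frequencies_khz=sel_frequencies, ratio_step=0.5,
                fascicle_a="TF" if i < n_onset_tf else "PF",
                dataset_id=f"ONSET{i}", animal_id=f"SYN{i % 3}",
                electrode_pair_id=f"PO{i}",
            )
        )
    for i in range(n_fatigue):
        specs.append(
            SweepSpec(
                kind="FATIGUE", frequencies_khz=(10.0,), n_repeats=fatigue_repeats,
                dataset_id=f"FATIGUE{i}", animal_id=f"SYN{i % 3}",
                electrode_pair_id=f"PF{i}",
            )
        )
    for k, spec in enumerate(specs):
        sub_seed = int(np.random.SeedSequence(seed, spawn_key=(k,)).generate_state(1)[0] % (2**31))
        manifests.append(
            simulate_dataset(
                spec, seed=sub_seed, out_dir=out_dir, phys=phys, onset=onset,
                sampling_rate_hz=sampling_rate_hz,
            )
        )
    manifest = pd.concat(manifests, ignore_index=True)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def simulate_sd_points(
    rheobase_ua: float = 81.0,
    chronaxie_us: float = 64.0,
    pulse_widths_us: Sequence[float] = (10, 25, 50, 100, 150, 200, 250),
    noise_frac: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Strength-duration sample points from the hyperbolic threshold law.

    Thresholds follow ``I(PW) = I_rh (1 + t_ch / PW)`` with optional
    multiplicative lognormal-free Gaussian noise of relative sd
    ``noise_frac``.
    """
    rng = np.random.default_rng(seed)
    pw = np.asarray(pulse_widths_us, dtype=float)
    thr = rheobase_ua * (1.0 + chronaxie_us / pw)
    if noise_frac > 0:
        thr = thr * (1.0 + noise_frac * rng.standard_normal(pw.size))
    return pd.DataFrame({"pw_us": pw, "threshold_ua": thr})


__all__ = [
    "BlockGroundTruth",
    "DEFAULT_BETA_BY_FREQ",
    "DEFAULT_PF_TRUTH",
    "DEFAULT_SIGMA_BY_FREQ",
    "FACILITATION_CUTOFF",
    "MusclePhysiology",
    "ONSET_X10_HI",
    "ONSET_X10_LO",
    "ONSET_X10_SPAN",
    "OnsetGroundTruth",
    "ProtocolError",
    "ProtocolSpec",
    "SweepSpec",
    "default_electrodes",
    "default_truth",
    "make_protocol",
    "onset_kernel",
    "onset_true_td",
    "simulate_dataset",
    "simulate_recording",
    "simulate_replica",
    "simulate_sd_points",
    "twitch_kernel",
]
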