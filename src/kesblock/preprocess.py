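"""Raw-recording preprocessing: baseline, band-pass, phases, twitch averages.

The chain turns a force recording into per-phase stimulus-triggered averaged
twitches and their scalar metrics:

1. subtract the baseline estimated over the 1 s stimulus-free blank,
2. zero-phase band-pass (0.1–100 Hz by default) to remove drift and any
   residual high-frequency content,
3. split the trace into pre-block / block / post-block phases using the KES
   gate timestamps, assigning triggers by the half-open rule
   ``[kes_onset, kes_offset)``,
4. average the aligned twitch windows of each phase (discarding the first 10
   block twitches so the KES onset does not contaminate the average),
5. reduce the averaged twitch to its peak force and area under the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording_io import ForceRecording, oriented_force


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PhaseSegments:
    """Trigger subsets and windows of the three protocol phases."""

    windows: dict[str, tuple[float, float]]
    triggers: dict[str, np.ndarray]

    def __getitem__(self, phase: str) -> np.ndarray:
        return self.triggers[phase]


@dataclass(frozen=True)
class AveragedTwitch:
    """Stimulus-triggered average over one phase; time 0 at the trigger."""

    time_s: np.ndarray
    force_n: np.ndarray
    n_averaged: int
    phase: str = ""


@dataclass(frozen=True)
class TwitchMetrics:
    """Peak force (N) and AUC (N*s) of an averaged twitch."""

    peak_force_n: float
    auc_ns: float
    phase: str = ""
    n_averaged: int = 0

    def value(self, basis: str) -> float:
        if basis == "peak":
            return self.peak_force_n
        if basis == "AUC":
            return self.auc_ns
        raise ValueError(f"unknown metric basis {basis!r}")


def subtract_baseline(rec: ForceRecording, blank_s: float = 1.0) -> ForceRecording:
    """Remove the mean force measured over the pre-protocol blank window.

    Requires at least ``blank_s`` seconds of blank recording; the returned
    recording has (numerically) zero mean over that window.
    """
    if rec.blank_end_s < blank_s:
        raise PreprocessError(
            f"blank window is {rec.blank_end_s} s; need >= {blank_s} s"
        )
    n_blank = int(round(blank_s * rec.sampling_rate_hz))
    baseline = float(np.mean(rec.force_n[:n_blank]))
    return ForceRecording(
        sampling_rate_hz=rec.sampling_rate_hz,
        force_n=rec.force_n - baseline,
        activation_triggers_s=rec.activation_triggers_s,
        kes_onset_s=rec.kes_onset_s,
        kes_offset_s=rec.kes_offset_s,
        blank_end_s=rec.blank_end_s,
        axis_convention=rec.axis_convention,
        condition=rec.condition,
        electrodes=rec.electrodes,
    )


def bandpass(
    rec: ForceRecording, hp_hz: float = 0.1, lp_hz: float = 100.0
) -> ForceRecording:
    """Zero-phase band-pass: 2nd-order Butterworth high-pass at ``hp_hz``
    cascaded with a 4th-order Butterworth low-pass at ``lp_hz``.

    Both sections are applied forward-backward (``sosfiltfilt``) so twitch
    peak timing is preserved.  Passing ``hp_hz=None`` or ``lp_hz=None``
    skips that section.
    """
    fs = rec.sampling_rate_hz
    nyq = fs / 2.0
    if lp_hz is not None and lp_hz >= nyq:
        raise PreprocessError(f"low-pass cutoff {lp_hz} Hz >= Nyquist {nyq} Hz")
    if hp_hz is not None and hp_hz >= nyq:
        raise PreprocessError(f"high-pass cutoff {hp_hz} Hz >= Nyquist {nyq} Hz")
    force = rec.force_n
    if hp_hz is not None:
        # A 2nd-order section at hp_hz/fs ~ 1e-6 is numerically unstable at
        # acquisition rates, so the slow trend is estimated on a decimated
        # grid (<= ~2 kHz), zero-phase low-passed at hp_hz, interpolated
        # back and subtracted: an equivalent zero-phase high-pass that is
        # well conditioned at any sampling rate.
        stride = max(1, int(fs // 2000))
        coarse = force[::stride]
        fs_c = fs / stride
        sos = signal.butter(2, hp_hz, btype="lowpass", fs=fs_c, output="sos")
        trend_c = signal.sosfiltfilt(sos, coarse)
        t_c = np.arange(coarse.size) * stride
        trend = np.interp(np.arange(force.size), t_c, trend_c)
        force = force - trend
    if lp_hz is not None:
        sos = signal.butter(4, lp_hz, btype="lowpass", fs=fs, output="sos")
        force = signal.sosfiltfilt(sos, force)
    return ForceRecording(
        sampling_rate_hz=fs,
        force_n=force,
        activation_triggers_s=rec.activation_triggers_s,
        kes_onset_s=rec.kes_onset_s,
        kes_offset_s=rec.kes_offset_s,
        blank_end_s=rec.blank_end_s,
        axis_convention=rec.axis_convention,
        condition=rec.condition,
        electrodes=rec.electrodes,
    )


def segment_phases(
    rec: ForceRecording,
    kes_onset_s: float | None = None,
    kes_offset_s: float | None = None,
) -> PhaseSegments:
    """Assign triggers to pre/block/post phases around the KES gate.

    The gate defaults to the recording's stored KES timestamps; a trigger
    exactly at ``kes_onset`` belongs to the block phase (half-open rule).
    Recordings without activation triggers (onset protocol) yield empty
    pre/post subsets and the block window equal to the gate.
    """
    onset = kes_onset_s if kes_onset_s is not None else rec.kes_onset_s
    offset = kes_offset_s if kes_offset_s is not None else rec.kes_offset_s
    if onset is None or offset is None:
        raise PreprocessError("recording has no KES gate timestamps")
    trig = rec.activation_triggers_s
    return PhaseSegments(
        windows={
            "pre": (rec.blank_end_s, onset),
            "block": (onset, offset),
            "post": (offset, rec.duration_s),
        },
        triggers={
            "pre": trig[trig < onset],
            "block": trig[(trig >= onset) & (trig < offset)],
            "post": trig[trig >= offset],
        },
    )


def triggered_average(
    rec: ForceRecording,
    triggers_s: np.ndarray,
    discard_first: int = 0,
    window_s: float = 0.2,
    phase: str = "",
) -> AveragedTwitch:
    """Mean force over aligned post-trigger windows.

    ``window_s`` defaults to the 5 Hz inter-stimulus interval (200 ms).  For
    the block phase pass ``discard_first=10`` to drop the onset-contaminated
    twitches.  The trace is oriented so the observed fascicle pulls positive
    before averaging.
    """
    triggers = np.asarray(triggers_s, dtype=float)[discard_first:]
    if triggers.size == 0:
        raise PreprocessError("no twitches left to average after discarding")
    force = oriented_force(rec)
    fs = rec.sampling_rate_hz
    n_win = int(round(window_s * fs))
    segs = []
    for t in triggers:
        i0 = int(round(t * fs))
        if i0 + n_win > force.size:
            continue
        segs.append(force[i0 : i0 + n_win])
    if not segs:
        raise PreprocessError("all twitch windows fall outside the recording")
    mean = np.mean(np.stack(segs), axis=0)
    return AveragedTwitch(
        time_s=np.arange(n_win) / fs, force_n=mean, n_averaged=len(segs), phase=phase
    )


def twitch_metrics(
    avg: AveragedTwitch, rectify: bool = True, baseline_samples: int = 1
) -> TwitchMetrics:
    """Peak force and trapezoidal AUC of an averaged twitch.

    The averaged twitch is first referenced to its own window-start baseline
    (mean of the opening ``baseline_samples`` samples, i.e. the force at the
    trigger before the mechanical response develops), which removes residual
    slow offsets left by high-pass filtering of long twitch trains; slow
    offsets are effectively constant over a 200 ms window.  With the default
    rectified-positive convention, the negative part of the signed force is
    then clipped before both the peak search and the integral, so the
    metrics are non-negative and insensitive to filter undershoot.
    """
    if avg.force_n.size == 0:
        raise PreprocessError("empty twitch window")
    force = avg.force_n
    if baseline_samples > 0:
        force = force - float(np.mean(force[:baseline_samples]))
    force = np.clip(force, 0.0, None) if rectify else force
    peak = float(np.max(force))
    auc = float(np.trapezoid(force, avg.time_s))
    return TwitchMetrics(
        peak_force_n=peak, auc_ns=auc, phase=avg.phase, n_averaged=avg.n_averaged
    )


def phase_metrics(
    rec: ForceRecording,
    hp_hz: float | None = 0.1,
    lp_hz: float | None = 100.0,
    discard_first_block: int = 10,
    window_s: float = 0.2,
    rectify: bool = True,
) -> dict[str, TwitchMetrics]:
    """Full preprocessing chain: baseline, filter, segment, average, reduce.

    Returns TwitchMetrics keyed by phase for the phases that contain
    triggers.
    """
    rec = subtract_baseline(rec)
    if hp_hz is not None or lp_hz is not None:
        rec = bandpass(rec, hp_hz, lp_hz)
    segments = segment_phases(rec)
    out: dict[str, TwitchMetrics] = {}
    for phase in ("pre", "block", "post"):
        trig = segments[phase]
        discard = discard_first_block if phase == "block" else 0
        if trig.size <= discard:
            continue
        avg = triggered_average(rec, trig, discard, window_s, phase=phase)
        out[phase] = twitch_metrics(avg, rectify=rectify)
    return out


__all__ = [
    "AveragedTwitch",
    "PhaseSegments",
    "PreprocessError",
    "TwitchMetrics",
    "bandpass",
    "phase_metrics",
    "segment_phases",
    "subtract_baseline",
    "triggered_average",
    "twitch_metrics",
]
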