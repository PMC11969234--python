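"""KES onset-response metrics: peak force, AUC and 10%-to-10% duration.

When kilohertz stimulation switches on, a brief burst of asynchronous firing
produces a force transient (the onset response).  With the activation train
silenced, the transient is characterised by its peak force, its area under
the curve, and its time duration

    TD = t_0.1f - t_0.1i

where t_0.1i and t_0.1f are the first and last times the response equals 10%
of its peak (linearly interpolated between samples).  Metrics are normalized
to the within-dataset maximum before group comparisons, so TD and the
normalized metrics are invariant to uniform force scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .recording_io import ForceRecording, oriented_force

log = logging.getLogger(__name__)


class OnsetError(ValueError):
    pass


@dataclass(frozen=True)
class OnsetMetrics:
    """Onset transient summary; a zero-onset sentinel has all fields 0."""

    peak_force_n: float
    auc_ns: float
    td_s: float
    t_start_s: float
    t_end_s: float
    fascicle: str = "TF"
    censored: bool = False
    kes_frequency_khz: float | None = None
    amplitude_ratio: float | None = None
    dataset_id: str = ""


def _crossings(t: np.ndarray, y: np.ndarray, level: float) -> tuple[float, float]:
    """First up-crossing and last down-crossing of ``level``, linearly
    interpolated between samples."""
    above = y >= level
    idx = np.nonzero(above)[0]
    first, last = idx[0], idx[-1]
    if first == 0:
        t_start = t[0]
    else:
        f0, f1 = y[first - 1], y[first]
        t_start = t[first - 1] + (level - f0) / (f1 - f0) * (t[first] - t[first - 1])
    if last == y.size - 1:
        t_end = t[-1]
    else:
        f0, f1 = y[last], y[last + 1]
        t_end = t[last] + (f0 - level) / (f0 - f1) * (t[last + 1] - t[last])
    return float(t_start), float(t_end)


def onset_metrics(
    rec: ForceRecording,
    kes_onset_s: float | None = None,
    search_window_s: float | None = None,
    rel_threshold: float = 0.1,
    fascicle: str | None = None,
) -> OnsetMetrics:
    """Measure the onset transient after KES switch-on.

    The peak is the maximum rectified force in ``[kes_onset,
    kes_onset + search_window]`` (window defaults to the block phase); the
    AUC is integrated over the 10%-bounded interval.  An all-nonpositive
    window yields the zero-onset sentinel.  When the response has not
    decayed below threshold by the end of the window, TD is right-censored
    at the window length and flagged.
    """
    onset = kes_onset_s if kes_onset_s is not None else rec.kes_onset_s
    if onset is None:
        raise OnsetError("recording has no KES onset timestamp")
    if search_window_s is None:
        if rec.kes_offset_s is not None:
            search_window_s = rec.kes_offset_s - onset
        else:
            search_window_s = rec.duration_s - onset
    cond = rec.condition
    fasc = fascicle or (cond.fascicle_a if cond else "TF")
    force = np.clip(oriented_force(rec, fasc), 0.0, None)
    fs = rec.sampling_rate_hz
    i0 = int(round(onset * fs))
    i1 = min(int(round((onset + search_window_s) * fs)), force.size)
    win = force[i0:i1]
    t = np.arange(i0, i1) / fs
    meta = dict(
        fascicle=fasc,
        kes_frequency_khz=cond.kes_frequency_khz if cond else None,
        amplitude_ratio=cond.amplitude_ratio if cond else None,
        dataset_id=cond.dataset_id if cond else "",
    )
    peak = float(np.max(win)) if win.size else 0.0
    if peak <= 0:
        return OnsetMetrics(0.0, 0.0, 0.0, onset, onset, **meta)
    level = rel_threshold * peak
    t_start, t_end = _crossings(t, win, level)
    censored = bool(win[-1] >= level)
    sel = (t >= t_start) & (t <= t_end)
    tt = np.concatenate([[t_start], t[sel], [t_end]])
    yy = np.concatenate(
        [[np.interp(t_start, t, win)], win[sel], [np.interp(t_end, t, win)]]
    )
    auc = float(np.trapezoid(yy, tt))
    return OnsetMetrics(
        peak_force_n=peak,
        auc_ns=auc,
        td_s=t_end - t_start,
        t_start_s=t_start,
        t_end_s=t_end,
        censored=censored,
        **meta,
    )


def normalize_onset(metrics: Sequence[OnsetMetrics]) -> list[OnsetMetrics]:
    """Divide peak, AUC and TD by their within-dataset maxima.

    The maxima of the returned list map to 1.  An all-zero dataset (no
    measurable onset anywhere) is an error.
    """
    if not metrics:
        raise OnsetError("empty metrics list")
    max_peak = max(m.peak_force_n for m in metrics)
    max_auc = max(m.auc_ns for m in metrics)
    max_td = max(m.td_s for m in metrics)
    if max_peak <= 0:
        raise OnsetError("all-zero onset dataset cannot be normalized")
    return [
        replace(
            m,
            peak_force_n=m.peak_force_n / max_peak,
            auc_ns=m.auc_ns / max_auc if max_auc > 0 else 0.0,
            td_s=m.td_s / max_td if max_td > 0 else 0.0,
        )
        for m in metrics
    ]


def onset_table(metrics: Iterable[OnsetMetrics], normalized: Iterable[OnsetMetrics] | None = None) -> pd.DataFrame:
    raw = list(metrics)
    norm = list(normalized) if normalized is not None else [None] * len(raw)
    rows = []
    for m, nm in zip(raw, norm):
        row = {
            "dataset_id": m.dataset_id,
            "kes_frequency_khz": m.kes_frequency_khz,
            "amplitude_ratio": m.amplitude_ratio,
            "fascicle": m.fascicle,
            "peak_force_n": m.peak_force_n,
            "auc_ns": m.auc_ns,
            "td_s": m.td_s,
            "censored": m.censored,
        }
        if nm is not None:
            row.update(
                norm_peak=nm.peak_force_n, norm_auc=nm.auc_ns, norm_td=nm.td_s
            )
        rows.append(row)
    return pd.DataFrame(rows)


def onset_summary(
    metrics: Sequence[OnsetMetrics],
    ratio_levels: Sequence[float] = (0.5, 1.0, 1.5),
    frequency_levels: Sequence[float] = (10.0, 15.0, 20.0),
) -> pd.DataFrame:
    """Group mean/sd of normalized onset metrics by amplitude ratio,
    frequency and observed fascicle.

    Amplitude ratios are snapped to the nearest requested level.  Empty
    groups are dropped with a log warning.
    """
    if not metrics:
        raise OnsetError("empty metrics list")
    df = onset_table(metrics)
    levels = np.asarray(ratio_levels, dtype=float)
    df = df[df["kes_frequency_khz"].isin(frequency_levels)]
    df = df.dropna(subset=["amplitude_ratio"])
    if df.empty:
        raise OnsetError("no metrics match the requested grouping keys")
    df = df.assign(
        ratio_level=levels[
            np.argmin(np.abs(df["amplitude_ratio"].to_numpy()[:, None] - levels), axis=1)
        ]
    )
    out = (
        df.groupby(["fascicle", "kes_frequency_khz", "ratio_level"])
        .agg(
            mean_peak=("peak_force_n", "mean"),
            sd_peak=("peak_force_n", "std"),
            mean_auc=("auc_ns", "mean"),
            sd_auc=("auc_ns", "std"),
            mean_td=("td_s", "mean"),
            sd_td=("td_s", "std"),
            n=("td_s", "size"),
        )
        .reset_index()
    )
    expected = len(ratio_levels) * len(frequency_levels)
    for fasc, grp in out.groupby("fascicle"):
        if len(grp) < expected:
            log.warning(
                "onset summary for %s has %d of %d groups; empty groups dropped",
                fasc,
                len(grp),
                expected,
            )
    return out


__all__ = [
    "OnsetError",
    "OnsetMetrics",
    "normalize_onset",
    "onset_metrics",
    "onset_summary",
    "onset_table",
]
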