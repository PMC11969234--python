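"""Data model and on-disk formats for isometric force recordings.

A recording is a single-axis force trace (plantarflexion positive by
convention) sampled uniformly, together with the activation-stimulus trigger
timestamps, the kilohertz-stimulation (KES) gate, and the trial metadata
needed by the analysis: KES frequency and amplitude, activation pulse
parameters, the fascicles carrying the activating and blocking electrodes,
and the electrode geometry used for charge-density calculations.

On disk a recording is a two-column delimited text file (``time_s,force_N``)
plus a UTF-8 JSON sidecar holding the sampling rate, triggers, KES gate and
metadata.  The format is human-inspectable and language-neutral; the sidecar
is schema-versioned through a ``format_version`` field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

FORMAT_VERSION = "1.0"

#: Observed-axis conventions: which rotation direction is stored as positive.
AXIS_CONVENTIONS = ("TF-positive", "PF-positive")

#: Fascicles of the rat sciatic nerve handled by the pipeline.
FASCICLES = ("TF", "PF")

PROTOCOL_KINDS = (
    "B_TH",
    "SEL",
    "ONSET",
    "FATIGUE-no-KES",
    "FATIGUE-ideal-block",
)

#: Nominal KES frequency range (kHz) accepted as plausible trial metadata.
KES_FREQUENCY_RANGE_KHZ = (1.0, 100.0)


class RecordingFormatError(ValueError):
    """Raised when a recording file or its sidecar cannot be parsed."""


class ManifestError(ValueError):
    """Raised when a dataset manifest violates referential integrity."""


@dataclass(frozen=True)
class ElectrodeSpec:
    """Geometry and impedance of one intrafascicular electrode (LIFE).

    wire_diameter is in micrometres, active_length in millimetres,
    impedance_1khz in kilo-ohms.  role distinguishes the activating
    electrode (``aLIFE``) from the blocking electrode (``bLIFE``).
    """

    wire_diameter_um: float
    active_length_mm: float
    impedance_1khz_kohm: float | None = None
    role: str = "bLIFE"

    def __post_init__(self) -> None:
        if not (self.wire_diameter_um > 0):
            raise ValueError("wire_diameter_um must be positive")
        if not (self.active_length_mm > 0):
            raise ValueError("active_length_mm must be positive")
        if self.role not in ("aLIFE", "bLIFE"):
            raise ValueError(f"unknown electrode role {self.role!r}")


@dataclass(frozen=True)
class TrialCondition:
    """Stimulation parameters and identifiers of a single trial.

    ``kes_frequency_khz``/``kes_amplitude_ma`` are the KES sine frequency and
    amplitude (I_KES); ``activation_amplitude_ua``/``activation_pw_us`` are
    the supra-threshold biphasic activation pulse parameters delivered at
    5 Hz.  ``fascicle_a`` is the fascicle carrying the activating electrode,
    hence the fascicle whose muscles the force axis observes; ``fascicle_b``
    carries the blocking electrode (tibial fascicle throughout).
    """

    kes_frequency_khz: float
    kes_amplitude_ma: float
    protocol_kind: str
    activation_amplitude_ua: float = 324.0  # 4 x mean rheobase (81 uA)
    activation_pw_us: float = 64.0  # mean chronaxie
    fascicle_a: str = "TF"
    fascicle_b: str = "TF"
    animal_id: str = "SYN0"
    electrode_pair_id: str = "PAIR0"
    dataset_id: str = "DS0"
    amplitude_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.protocol_kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.protocol_kind!r}")
        if self.fascicle_a not in FASCICLES or self.fascicle_b not in FASCICLES:
            raise ValueError("fascicles must be 'TF' or 'PF'")
        if self.kes_amplitude_ma < 0:
            raise ValueError("kes_amplitude_ma must be >= 0")


@dataclass
class ForceRecording:
    """Uniformly sampled force trace plus triggers and acquisition metadata.

    ``force_n`` is newtons along a single axis; with the default
    ``TF-positive`` convention, positive force is plantarflexion (tibial
    muscles).  All timestamps are seconds from recording start.  A blank
    (stimulus-free) segment of at least 1 s precedes the protocol and ends
    at ``blank_end_s``; it anchors the baseline estimate.
    """

    sampling_rate_hz: float
    force_n: np.ndarray
    activation_triggers_s: np.ndarray
    kes_onset_s: float | None = None
    kes_offset_s: float | None = None
    blank_end_s: float = 1.0
    axis_convention: str = "TF-positive"
    condition: TrialCondition | None = None
    electrodes: tuple[ElectrodeSpec, ...] = ()

    def __post_init__(self) -> None:
        self.force_n = np.asarray(self.force_n, dtype=float)
        self.activation_triggers_s = np.asarray(
            self.activation_triggers_s, dtype=float
        )

    @property
    def duration_s(self) -> float:
        return self.force_n.size / self.sampling_rate_hz

    def time_s(self) -> np.ndarray:
        return np.arange(self.force_n.size) / self.sampling_rate_hz


def oriented_force(rec: ForceRecording, fascicle: str | None = None) -> np.ndarray:
    """Force trace oriented so the observed muscle group pulls positive.

    ``fascicle`` defaults to the condition's ``fascicle_a`` (the activated,
    hence observed, fascicle).  Under the ``TF-positive`` axis convention a
    peroneal (PF) twitch is dorsiflexion and recorded negative; analysis
    metrics are fascicle-agnostic, so the trace is sign-flipped here.
    """
    if fascicle is None:
        fascicle = rec.condition.fascicle_a if rec.condition else "TF"
    positive = rec.axis_convention.split("-", 1)[0]
    sign = 1.0 if fascicle == positive else -1.0
    return sign * rec.force_n


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: ForceRecording, path: str | Path) -> Path:
    """Write ``<path>.csv`` (time_s,force_N) and ``<path>.json`` sidecar.

    The force column is written with ``repr`` precision so the round trip is
    lossless.  Returns the CSV path.
    """
    path = Path(path).with_suffix(".csv")
    time = np.arange(rec.force_n.size) / rec.sampling_rate_hz
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s,force_N\n")
        fh.writelines(
            f"{t!r},{f!r}\n" for t, f in zip(time.tolist(), rec.force_n.tolist())
        )
    meta = {
        "format_version": FORMAT_VERSION,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "blank_end_s": rec.blank_end_s,
        "axis_convention": rec.axis_convention,
        "activation_triggers_s": rec.activation_triggers_s.tolist(),
        "kes_onset_s": rec.kes_onset_s,
        "kes_offset_s": rec.kes_offset_s,
        "condition": asdict(rec.condition) if rec.condition else None,
        "electrodes": [asdict(e) for e in rec.electrodes],
    }
    _sidecar_path(path).write_text(
        json.dumps(meta, indent=1, sort_keys=True), encoding="utf-8"
    )
    return path


def read_recording(path: str | Path) -> ForceRecording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`RecordingFormatError` naming the missing or malformed
    section when either file is damaged.
    """
    path = Path(path).with_suffix(".csv")
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise RecordingFormatError(f"missing force table {path}")
    if not sidecar.exists():
        raise RecordingFormatError(f"missing sidecar {sidecar}")
    try:
        table = pd.read_csv(path, dtype=float, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise RecordingFormatError(f"{path}: cannot parse force table: {exc}") from exc
    if list(table.columns) != ["time_s", "force_N"]:
        raise RecordingFormatError(
            f"{path}: expected header 'time_s,force_N', got {list(table.columns)}"
        )
    try:
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise RecordingFormatError(f"{sidecar}: invalid JSON: {exc}") from exc
    for key in ("sampling_rate_hz", "activation_triggers_s", "blank_end_s"):
        if key not in meta:
            raise RecordingFormatError(f"{sidecar}: missing section {key!r}")
    condition = meta.get("condition")
    electrodes = tuple(ElectrodeSpec(**e) for e in meta.get("electrodes", []))
    return ForceRecording(
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        force_n=table["force_N"].to_numpy(),
        activation_triggers_s=np.asarray(meta["activation_triggers_s"], dtype=float),
        kes_onset_s=meta.get("kes_onset_s"),
        kes_offset_s=meta.get("kes_offset_s"),
        blank_end_s=float(meta["blank_end_s"]),
        axis_convention=meta.get("axis_convention", "TF-positive"),
        condition=TrialCondition(**condition) if condition else None,
        electrodes=electrodes,
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_recording(
    rec: ForceRecording,
    condition: TrialCondition | None = None,
    pulse_rate_hz: float = 5.0,
    jitter_tol: float = 0.01,
) -> list[str]:
    """Return invariant violations as strings; empty list means valid.

    Checks the type invariants (sampling rate above twice the 100 Hz low-pass
    cutoff, finite force, ordered in-range triggers, ordered KES gate) and,
    when triggers are present, that their cadence matches the nominal
    activation pulse rate within ``jitter_tol`` relative jitter.
    """
    v: list[str] = []
    cond = condition or rec.condition
    if not rec.sampling_rate_hz > 200.0:
        v.append(f"sampling_rate_hz {rec.sampling_rate_hz} must exceed 200 Hz")
    if not np.all(np.isfinite(rec.force_n)):
        v.append("force trace contains non-finite samples")
    if rec.axis_convention not in AXIS_CONVENTIONS:
        v.append(f"unknown axis_convention {rec.axis_convention!r}")
    trig = rec.activation_triggers_s
    if trig.size:
        if np.any(np.diff(trig) <= 0):
            v.append("activation triggers are not strictly increasing")
        if trig[0] < 0 or trig[-1] >= rec.duration_s:
            v.append("activation triggers fall outside the record duration")
        if trig.size > 1:
            isi = np.diff(trig)
            nominal = 1.0 / pulse_rate_hz
            worst = float(np.max(np.abs(isi - nominal)) / nominal)
            if worst > jitter_tol:
                v.append(
                    f"trigger cadence deviates from {pulse_rate_hz} Hz by "
                    f"{worst:.1%} (tolerance {jitter_tol:.0%})"
                )
    if (rec.kes_onset_s is None) != (rec.kes_offset_s is None):
        v.append("kes_onset_s and kes_offset_s must both be set or both absent")
    elif rec.kes_onset_s is not None and not rec.kes_onset_s < rec.kes_offset_s:
        v.append("kes_onset_s must precede kes_offset_s")
    if cond is not None:
        lo, hi = KES_FREQUENCY_RANGE_KHZ
        if not (lo <= cond.kes_frequency_khz <= hi):
            v.append(
                f"kes_frequency_khz {cond.kes_frequency_khz} outside [{lo}, {hi}]"
            )
    return v


# ---------------------------------------------------------------------------
# dataset manifest
# ---------------------------------------------------------------------------

MANIFEST_KEY = [
    "animal_id",
    "electrode_pair_id",
    "protocol_kind",
    "kes_frequency_khz",
    "kes_amplitude_ma",
]


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    manifest.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    """Load a manifest CSV and enforce referential integrity.

    Every referenced recording file must exist (relative to the manifest
    directory) and the (animal, electrode pair, protocol, frequency,
    amplitude) key must be unique per row.
    """
    path = Path(path)
    manifest = pd.read_csv(path)
    validate_manifest(manifest, base_dir=path.parent, check_files=check_files)
    return manifest


def validate_manifest(
    manifest: pd.DataFrame,
    base_dir: str | Path | None = None,
    check_files: bool = True,
) -> None:
    if "recording" not in manifest.columns:
        raise ManifestError("manifest lacks a 'recording' column")
    missing = [c for c in MANIFEST_KEY if c not in manifest.columns]
    if missing:
        raise ManifestError(f"manifest lacks key columns {missing}")
    key = MANIFEST_KEY + (["repetition"] if "repetition" in manifest.columns else [])
    dup = manifest.duplicated(subset=key)
    if dup.any():
        rows = manifest.index[dup].tolist()
        raise ManifestError(f"duplicate manifest keys at rows {rows}")
    if check_files and base_dir is not None:
        base = Path(base_dir)
        for rel in manifest["recording"]:
            if not (base / rel).with_suffix(".csv").exists():
                raise ManifestError(f"referenced recording missing: {rel}")


def load_zenodo_archive(path: str | Path):  # pragma: no cover - stub
    """Adapter stub for the published in vivo dataset archive.

    The internal layout of the deposited archive is not documented alongside
    the study, so no parser is provided; convert the deposit to the CSV +
    JSON sidecar format of this module to analyse it with this pipeline.
    """
    raise NotImplementedError(
        "The deposited archive layout is undocumented; convert recordings to "
        "the kesblock CSV + JSON sidecar format instead."
    )


__all__ = [
    "AXIS_CONVENTIONS",
    "ElectrodeSpec",
    "FASCICLES",
    "FORMAT_VERSION",
    "ForceRecording",
    "ManifestError",
    "MANIFEST_KEY",
    "PROTOCOL_KINDS",
    "RecordingFormatError",
    "TrialCondition",
    "load_zenodo_archive",
    "oriented_force",
    "read_manifest",
    "read_recording",
    "validate_manifest",
    "validate_recording",
    "write_manifest",
    "write_recording",
]
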