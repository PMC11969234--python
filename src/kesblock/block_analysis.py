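"""Conduction-block quantities: charge safety chain, block amount,
block-threshold detection, interfascicular selectivity, SD/BD curves.

Charge chain (electrode safety at the block threshold)::

    T_KES            = 1 / (2 f_KES)          half-period of the KES sine
    Q_per_phase      = 2 B_TH T_KES / pi       charge injected per half-cycle
    S_LIFE           = pi * diameter * length  active-site area
    sigma_per_phase  = Q_per_phase / S_LIFE    charge density (uC/cm^2)

Block amount at a KES amplitude, from a twitch metric X (peak or AUC)::

    BLK = 1 - X_block / X_pre

Negative BLK is meaningful: sub-threshold KES can facilitate activation.
The block threshold B_TH is the smallest swept amplitude whose block-phase
peak drops below 5% of its own pre-block peak (BLK > 0.95).  Selectivity of
fascicle i is its block amount minus the mean block amount of the other
fascicles; for the two-fascicle case, S_TF = BLK_TF - BLK_PF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .preprocess import TwitchMetrics
from .recording_io import ElectrodeSpec, TrialCondition


class BlockAnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class BlockMeasurement:
    """Amount of conduction block for one trial and metric basis."""

    blk: float
    basis: str = "peak"
    condition: TrialCondition | None = None

    def __post_init__(self) -> None:
        if self.blk > 1.0 + 1e-12:
            raise ValueError("blk cannot exceed 1")


@dataclass(frozen=True)
class BlockThreshold:
    """Detected block threshold at one KES frequency.

    ``b_th_ma`` is None when no swept amplitude reached the block criterion
    ("not blocked within tested range" is a value, not an error).
    """

    kes_frequency_khz: float
    b_th_ma: float | None
    t_kes_s: float
    blocked: bool
    electrode: ElectrodeSpec | None = None


@dataclass(frozen=True)
class ChargeResult:
    q_per_phase_c: float
    s_life_cm2: float
    sigma_per_phase_uc_cm2: float


@dataclass(frozen=True)
class SDCurve:
    """Weiss-model strength-duration fit: I(PW) = I_rh (1 + t_ch / PW)."""

    pw_us: np.ndarray
    threshold_ua: np.ndarray
    rheobase_ua: float
    chronaxie_us: float
    r_squared: float


@dataclass(frozen=True)
class SelectivityResult:
    s_index: float
    target: str
    blk_by_fascicle: dict[str, float]
    n_fascicles: int


# ---------------------------------------------------------------------------
# charge chain
# ---------------------------------------------------------------------------


def kes_half_period(f_kes_khz: float) -> float:
    """Half-period (s) of the KES sine at ``f_kes_khz`` kilohertz."""
    if not f_kes_khz > 0:
        raise BlockAnalysisError("KES frequency must be positive")
    return 1.0 / (2.0 * f_kes_khz * 1e3)


def charge_per_phase(b_th_ma: float, t_kes_s: float) -> float:
    """Charge (C) injected in one half-cycle of a sine of amplitude B_TH."""
    if b_th_ma < 0 or t_kes_s < 0:
        raise BlockAnalysisError("amplitude and half-period must be >= 0")
    return 2.0 * (b_th_ma * 1e-3) * t_kes_s / math.pi


def electrode_area(diameter_um: float, length_mm: float) -> float:
    """Cylindrical active-site area (cm^2) of a LIFE wire."""
    if not (diameter_um > 0 and length_mm > 0):
        raise BlockAnalysisError("diameter and length must be positive")
    return math.pi * (diameter_um * 1e-4) * (length_mm * 1e-1)


def charge_density(q_c: float, s_cm2: float) -> float:
    """Charge density per phase in uC/cm^2."""
    if not s_cm2 > 0:
        raise BlockAnalysisError("electrode area must be positive")
    return q_c / s_cm2 * 1e6


def charge_result(
    b_th_ma: float, f_kes_khz: float, electrode: ElectrodeSpec
) -> ChargeResult:
    """Full chain from threshold and frequency to charge density."""
    q = charge_per_phase(b_th_ma, kes_half_period(f_kes_khz))
    s = electrode_area(electrode.wire_diameter_um, electrode.active_length_mm)
    return ChargeResult(q, s, charge_density(q, s))


# ---------------------------------------------------------------------------
# block amount / threshold / selectivity
# ---------------------------------------------------------------------------


def block_amount(
    x_pre: TwitchMetrics, x_block: TwitchMetrics, basis: str = "peak",
    condition: TrialCondition | None = None,
) -> BlockMeasurement:
    """BLK = 1 - X_block/X_pre on a common metric basis.

    Negative values are retained: they indicate sub-threshold facilitation
    (the block-phase twitch exceeding the pre-block twitch).
    """
    pre = x_pre.value(basis)
    if not pre > 0:
        raise BlockAnalysisError("pre-block metric must be positive")
    return BlockMeasurement(1.0 - x_block.value(basis) / pre, basis, condition)


def detect_block_threshold(
    sweep: Sequence[tuple[float, float, float]],
    kes_frequency_khz: float,
    block_fraction: float = 0.05,
    electrode: ElectrodeSpec | None = None,
) -> BlockThreshold:
    """First swept amplitude whose block-phase peak falls below
    ``block_fraction`` of its own pre-block peak.

    ``sweep`` is an ordered list of (amplitude mA, pre-block peak,
    block-phase peak) with strictly increasing amplitudes.  If no amplitude
    crosses, a "not blocked" sentinel (``b_th_ma=None, blocked=False``) is
    returned.
    """
    if len(sweep) == 0:
        raise BlockAnalysisError("empty amplitude sweep")
    amps = np.asarray([s[0] for s in sweep], dtype=float)
    if np.any(np.diff(amps) <= 0):
        raise BlockAnalysisError("sweep amplitudes must be strictly increasing")
    t_kes = kes_half_period(kes_frequency_khz)
    for amp, pre, blk in sweep:
        if not pre > 0:
            raise BlockAnalysisError("pre-block peak must be positive")
        if blk < block_fraction * pre:
            return BlockThreshold(kes_frequency_khz, float(amp), t_kes, True, electrode)
    return BlockThreshold(kes_frequency_khz, None, t_kes, False, electrode)


def selectivity_index(
    blk_by_fascicle: Mapping[str, float], target: str
) -> SelectivityResult:
    """Block in the target fascicle minus the mean block elsewhere."""
    if target not in blk_by_fascicle:
        raise BlockAnalysisError(f"target fascicle {target!r} not measured")
    if len(blk_by_fascicle) < 2:
        raise BlockAnalysisError("selectivity needs at least two fascicles")
    others = [v for k, v in blk_by_fascicle.items() if k != target]
    s = blk_by_fascicle[target] - float(np.mean(others))
    return SelectivityResult(s, target, dict(blk_by_fascicle), len(blk_by_fascicle))


def mean_block_threshold(thresholds: Sequence[BlockThreshold]) -> float:
    """Arithmetic mean of the detected thresholds (B_avg); ignores
    not-blocked sentinels.  Raises when nothing was blocked."""
    vals = [t.b_th_ma for t in thresholds if t.blocked]
    if not vals:
        raise BlockAnalysisError("no blocked threshold available for averaging")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# strength-duration / block-duration curves
# ---------------------------------------------------------------------------


def fit_sd_curve(
    points: Sequence[tuple[float, float]] | np.ndarray,
) -> SDCurve:
    """Least-squares Weiss fit of threshold vs pulse width.

    ``I(PW) = I_rh (1 + t_ch/PW)`` is linear in ``1/PW``, so the fit is the
    exact linear least-squares solution; rheobase is the intercept and
    chronaxie the slope/intercept ratio.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise BlockAnalysisError("points must be (pw_us, threshold_ua) pairs")
    pw, thr = arr[:, 0], arr[:, 1]
    if np.unique(pw).size < 3:
        raise BlockAnalysisError("need >= 3 distinct pulse widths")
    design = np.column_stack([np.ones_like(pw), 1.0 / pw])
    coef, *_ = np.linalg.lstsq(design, thr, rcond=None)
    intercept, slope = coef
    if not (intercept > 0 and slope > 0):
        raise BlockAnalysisError(
            "degenerate strength-duration data: non-positive rheobase or chronaxie"
        )
    pred = design @ coef
    ss_res = float(np.sum((thr - pred) ** 2))
    ss_tot = float(np.sum((thr - np.mean(thr)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SDCurve(pw, thr, float(intercept), float(slope / intercept), r2)


def normalize_bd_sd(
    values_by_half_period_us: Mapping[float, float],
    reference_us: float = 17.0,
) -> dict[float, float]:
    """Normalize a threshold or charge-density curve to its value at the
    17 us half-period anchor (1/(2*30 kHz) rounded).

    The anchor is linearly interpolated in half-period between the two
    nearest measured points when not sampled exactly.
    """
    if not values_by_half_period_us:
        raise BlockAnalysisError("empty curve")
    hp = np.asarray(sorted(values_by_half_period_us), dtype=float)
    val = np.asarray([values_by_half_period_us[h] for h in hp], dtype=float)
    if reference_us < hp[0] or reference_us > hp[-1]:
        raise BlockAnalysisError(
            f"no value at or interpolable to {reference_us} us half-period"
        )
    ref = float(np.interp(reference_us, hp, val))
    if ref == 0:
        raise BlockAnalysisError("reference value is zero")
    return {float(h): float(v / ref) for h, v in values_by_half_period_us.items()}


__all__ = [
    "BlockAnalysisError",
    "BlockMeasurement",
    "BlockThreshold",
    "ChargeResult",
    "SDCurve",
    "SelectivityResult",
    "block_amount",
    "charge_density",
    "charge_per_phase",
    "charge_result",
    "detect_block_threshold",
    "electrode_area",
    "fit_sd_curve",
    "kes_half_period",
    "mean_block_threshold",
    "normalize_bd_sd",
    "selectivity_index",
]
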