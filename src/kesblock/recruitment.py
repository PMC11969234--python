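"""Sigmoid recruitment curves of block amount versus KES amplitude.

The block amount BLK as a function of KES amplitude I is modelled by the
logistic recruitment law

    BLK(I) = 1 / (1 + exp(-beta (I - sigma)))

where sigma (mA) is the amplitude producing 50% block and beta (1/mA) sets
the recruitment rate (slope of the linear region).  Fits are bounded
nonlinear least squares within 0.5 < sigma < 3 mA and 3 < beta < 30 /mA so
the parameters cannot collapse onto either extreme; fits that end pinned at
a bound are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

SIGMA_BOUNDS_MA = (0.5, 3.0)
BETA_BOUNDS_PER_MA = (3.0, 30.0)


class RecruitmentError(ValueError):
    pass


@dataclass(frozen=True)
class RecruitmentFit:
    sigma_ma: float
    beta_per_ma: float
    r_squared: float
    basis: str = "peak"
    kes_frequency_khz: float | None = None
    n_points: int = 0
    at_bound: bool = False
    dataset_id: str = ""


def sigmoid_blk(i_kes_ma, sigma_ma: float, beta_per_ma: float):
    """Logistic block amount; numerically saturating for large arguments."""
    z = np.clip(beta_per_ma * (np.asarray(i_kes_ma, dtype=float) - sigma_ma), -500, 500)
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if out.ndim == 0 else out


def block_threshold_amplitude(
    sigma_ma: float, beta_per_ma: float, block_fraction: float = 0.05
) -> float:
    """Amplitude at which the sigmoid crosses 1 - block_fraction.

    Closed-form inversion: sigma + ln((1-f)/f)/beta; ln(19)/beta for the 5%
    criterion.
    """
    f = block_fraction
    return sigma_ma + np.log((1.0 - f) / f) / beta_per_ma


def fit_recruitment(
    amplitudes_ma: Sequence[float],
    blk: Sequence[float],
    kes_frequency_khz: float | None = None,
    basis: str = "peak",
    dataset_id: str = "",
    n_starts: int = 5,
    bound_tol: float = 1e-3,
) -> RecruitmentFit:
    """Bounded nonlinear least-squares fit of the recruitment sigmoid.

    Negative BLK points (sub-threshold facilitation) are retained.  A
    trust-region solver is restarted from ``n_starts`` points on a
    sigma x beta lattice to avoid local minima on noisy low-n curves; the
    best solution by residual norm wins.  ``at_bound`` is set when either
    parameter lands within ``bound_tol`` (relative to the bound range) of a
    boundary.
    """
    x = np.asarray(amplitudes_ma, dtype=float)
    y = np.asarray(blk, dtype=float)
    if x.size != y.size or x.size < 5:
        raise RecruitmentError("need >= 5 (amplitude, BLK) points")
    if np.ptp(y) == 0:
        raise RecruitmentError("all BLK values identical; sigmoid fit undefined")

    lo = np.array([SIGMA_BOUNDS_MA[0], BETA_BOUNDS_PER_MA[0]])
    hi = np.array([SIGMA_BOUNDS_MA[1], BETA_BOUNDS_PER_MA[1]])

    def residual(p):
        return sigmoid_blk(x, p[0], p[1]) - y

    sig0 = np.clip(np.interp(0.5, np.clip(y, 0, 1), x), lo[0] + 1e-6, hi[0] - 1e-6)
    starts = [np.array([sig0, 10.0])]
    sig_grid = np.linspace(lo[0], hi[0], n_starts + 1)[1:-1]
    beta_grid = np.geomspace(lo[1] * 1.2, hi[1] * 0.8, max(1, n_starts - 1))
    for s, b in zip(sig_grid, beta_grid):
        starts.append(np.array([s, b]))
    best = None
    for p0 in starts:
        try:
            res = least_squares(residual, p0, bounds=(lo, hi), method="trf")
        except Exception:  # noqa: BLE001 - keep trying other starts
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        final = np.nan if best is None else float(np.linalg.norm(best.fun))
        raise RecruitmentError(f"sigmoid fit failed to converge (residual {final})")
    sigma, beta = best.x
    pred = sigmoid_blk(x, sigma, beta)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    span = hi - lo
    at_bound = bool(
        np.any((best.x - lo) < bound_tol * span) or np.any((hi - best.x) < bound_tol * span)
    )
    return RecruitmentFit(
        sigma_ma=float(sigma),
        beta_per_ma=float(beta),
        r_squared=r2,
        basis=basis,
        kes_frequency_khz=kes_frequency_khz,
        n_points=int(x.size),
        at_bound=at_bound,
        dataset_id=dataset_id,
    )


def summarize_fits(
    fits: Iterable[RecruitmentFit],
    amplitude_grid_ma: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-frequency mean parameters and the mean-parameter sigmoid.

    Returns one row per KES frequency with mean sigma, mean beta, mean R^2,
    the fit count, and (when a grid is given) the mean-parameter sigmoid
    sampled on the common amplitude grid.
    """
    fits = list(fits)
    if not fits:
        raise RecruitmentError("no fits to summarize")
    df = pd.DataFrame(
        {
            "kes_frequency_khz": [f.kes_frequency_khz for f in fits],
            "sigma_ma": [f.sigma_ma for f in fits],
            "beta_per_ma": [f.beta_per_ma for f in fits],
            "r_squared": [f.r_squared for f in fits],
        }
    )
    rows = []
    for freq, grp in df.groupby("kes_frequency_khz", dropna=False):
        row = {
            "kes_frequency_khz": freq,
            "mean_sigma_ma": grp["sigma_ma"].mean(),
            "mean_beta_per_ma": grp["beta_per_ma"].mean(),
            "mean_r_squared": grp["r_squared"].mean(),
            "n_fits": len(grp),
        }
        if amplitude_grid_ma is not None:
            row["mean_curve"] = sigmoid_blk(
                amplitude_grid_ma, row["mean_sigma_ma"], row["mean_beta_per_ma"]
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("kes_frequency_khz").reset_index(drop=True)


__all__ = [
    "BETA_BOUNDS_PER_MA",
    "RecruitmentError",
    "RecruitmentFit",
    "SIGMA_BOUNDS_MA",
    "block_threshold_amplitude",
    "fit_recruitment",
    "sigmoid_blk",
    "summarize_fits",
]
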