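"""Muscle-fatigue index and scenario grouping.

Fatigue is quantified by comparing a twitch metric X (peak force or AUC)
between the pre-block and post-block phases:

    decrease = |X_pre - X_post| / X_pre
    f_X      = 1 - decrease

Trials are grouped into four scenarios: the two control protocols
``no-KES`` (activation throughout, KES off) and ``ideal-block`` (all
stimulation off during the block phase), plus two groups derived from the
measured block amount of amplitude-sweep trials: ``weak-block``
(0 < BLK < 0.25) and ``strong-block`` (BLK > 0.75).  The boundaries are
open; trials at exactly 25% or 75% block stay ungrouped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .block_analysis import BlockMeasurement
from .preprocess import TwitchMetrics

log = logging.getLogger(__name__)

WEAK_BLOCK_RANGE = (0.0, 0.25)
STRONG_BLOCK_MIN = 0.75

SCENARIOS = ("no-KES", "weak-block", "strong-block", "ideal-block")


class FatigueError(ValueError):
    pass


@dataclass(frozen=True)
class FatigueResult:
    f_x: float
    decrease: float
    basis: str = "peak"
    scenario: str | None = None
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if abs(self.f_x + self.decrease - 1.0) > 1e-12:
            raise ValueError("f_x + decrease must equal 1")


def fatigue_index(
    x_pre: TwitchMetrics, x_post: TwitchMetrics, basis: str = "peak",
    scenario: str | None = None, dataset_id: str = "",
) -> FatigueResult:
    """Fatigue index f_X and the relative pre-to-post decrease.

    The absolute value guards the (rare) case of post-block force exceeding
    pre-block force; both directions count as deviation from full recovery.
    """
    pre = x_pre.value(basis)
    if not pre > 0:
        raise FatigueError("pre-block metric must be positive")
    decrease = abs(pre - x_post.value(basis)) / pre
    return FatigueResult(1.0 - decrease, decrease, basis, scenario, dataset_id)


def assign_block_group(blk: BlockMeasurement | float) -> str | None:
    """weak-block for 0 < BLK < 0.25, strong-block for BLK > 0.75,
    otherwise None (ungrouped)."""
    val = blk.blk if isinstance(blk, BlockMeasurement) else float(blk)
    if WEAK_BLOCK_RANGE[0] < val < WEAK_BLOCK_RANGE[1]:
        return "weak-block"
    if val > STRONG_BLOCK_MIN:
        return "strong-block"
    return None


def fatigue_scenarios(trials: pd.DataFrame, basis: str = "peak") -> pd.DataFrame:
    """Label eligible trials with their fatigue scenario and index.

    ``trials`` must carry one row per analysed trial with columns
    ``protocol_kind``, ``x_pre``, ``x_post`` and (for amplitude-sweep rows)
    ``blk``.  FATIGUE control rows map directly to no-KES / ideal-block;
    sweep rows are grouped by their measured block amount and ungrouped rows
    are dropped.  Sweep rows without a BLK value are skipped with a warning.
    """
    required = {"protocol_kind", "x_pre", "x_post"}
    missing = required - set(trials.columns)
    if missing:
        raise FatigueError(f"trials table lacks columns {sorted(missing)}")
    rows = []
    for idx, row in trials.iterrows():
        kind = row["protocol_kind"]
        if kind == "FATIGUE-no-KES":
            scenario = "no-KES"
        elif kind == "FATIGUE-ideal-block":
            scenario = "ideal-block"
        elif kind == "SEL":
            blk = row.get("blk", np.nan)
            if pd.isna(blk):
                log.warning("trial %s: SEL row without BLK value skipped", idx)
                continue
            scenario = assign_block_group(float(blk))
            if scenario is None:
                continue
        else:
            continue
        pre, post = float(row["x_pre"]), float(row["x_post"])
        if not pre > 0:
            log.warning("trial %s: non-positive pre-block metric skipped", idx)
            continue
        decrease = abs(pre - post) / pre
        rows.append(
            {
                "trial": idx,
                "dataset_id": row.get("dataset_id", ""),
                "scenario": scenario,
                "basis": basis,
                "f_x": 1.0 - decrease,
                "decrease": decrease,
            }
        )
    return pd.DataFrame(
        rows, columns=["trial", "dataset_id", "scenario", "basis", "f_x", "decrease"]
    )


def scenario_means(fatigue_table: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd decrease per scenario, ordered no-KES, weak, strong, ideal."""
    out = (
        fatigue_table.groupby("scenario")
        .agg(mean_decrease=("decrease", "mean"), sd_decrease=("decrease", "std"), n=("decrease", "size"))
        .reindex(SCENARIOS)
        .dropna(subset=["mean_decrease"])
        .reset_index()
    )
    return out


__all__ = [
    "FatigueError",
    "FatigueResult",
    "SCENARIOS",
    "STRONG_BLOCK_MIN",
    "WEAK_BLOCK_RANGE",
    "assign_block_group",
    "fatigue_index",
    "fatigue_scenarios",
    "scenario_means",
]
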