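"""Statistical comparisons and the end-to-end analysis pipeline.

The statistical layer mirrors the comparisons used to summarise block
thresholds and metrics across datasets: per-dataset linear and quadratic
regressions of threshold on KES frequency, Spearman rank correlations (with
exact permutation p-values at small n), one-way repeated-measures ANOVA with
Bonferroni-corrected pairwise post-hocs, and the unpaired t-test.

``run_pipeline`` ties the package together: it walks a dataset manifest,
preprocesses every recording, and emits delimited-text tables for block
amounts, thresholds with charge densities, selectivity, recruitment fits,
onset metrics and fatigue, plus a machine-readable run log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import platform
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from . import __version__
from .block_analysis import (
    charge_result,
    detect_block_threshold,
    selectivity_index,
)
from .fatigue_analysis import fatigue_scenarios, scenario_means
from .onset_analysis import normalize_onset, onset_metrics, onset_table, onset_summary
from .preprocess import phase_metrics
from .recording_io import ElectrodeSpec, read_manifest, read_recording
from .recruitment import fit_recruitment, summarize_fits, RecruitmentError

log = logging.getLogger(__name__)

#: Stable float formatting for byte-reproducible tables.
FLOAT_FORMAT = "%.10g"


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionResult:
    model: str  # 'linear' | 'quadratic'
    coefficients: tuple[float, ...]
    std_errors: tuple[float, ...]
    r_squared: float
    quadratic_term_p: float | None = None
    dataset_id: str = ""


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


# ---------------------------------------------------------------------------
# regressions and correlations
# ---------------------------------------------------------------------------


def threshold_frequency_regression(
    thresholds: pd.DataFrame,
    freq_col: str = "kes_frequency_khz",
    value_col: str = "b_th_ma",
    dataset_col: str = "dataset_id",
) -> list[tuple[RegressionResult, RegressionResult]]:
    """Per-dataset linear and quadratic OLS of threshold on frequency.

    Datasets with fewer than 3 frequencies are skipped with a warning.  The
    quadratic term's coefficient test supplies its significance; by nesting,
    the quadratic R^2 is never below the linear R^2.
    """
    out = []
    for ds, grp in thresholds.groupby(dataset_col):
        grp = grp.dropna(subset=[value_col])
        if grp[freq_col].nunique() < 3:
            log.warning("dataset %s: fewer than 3 frequencies, regression skipped", ds)
            continue
        f = grp[freq_col].to_numpy(dtype=float)
        y = grp[value_col].to_numpy(dtype=float)
        lin = sm.OLS(y, sm.add_constant(f)).fit()
        quad = sm.OLS(y, sm.add_constant(np.column_stack([f, f**2]))).fit()
        out.append(
            (
                RegressionResult(
                    "linear",
                    tuple(lin.params),
                    tuple(lin.bse),
                    float(lin.rsquared),
                    None,
                    str(ds),
                ),
                RegressionResult(
                    "quadratic",
                    tuple(quad.params),
                    tuple(quad.bse),
                    float(quad.rsquared),
                    float(quad.pvalues[-1]),
                    str(ds),
                ),
            )
        )
    return out


def spearman_corr(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 9
) -> ComparisonResult:
    """Spearman rank correlation with exact permutation p at small n.

    For n <= ``exact_max_n`` (no asymptotics trustworthy there) the p-value
    is computed by full enumeration of rank pairings; beyond that the usual
    t-approximation is used.  Constant input yields the undefined-correlation
    sentinel (NaN statistic and p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ComparisonResult("Spearman", math.nan, math.nan)
    rho = float(stats.spearmanr(x, y).statistic)
    if x.size <= exact_max_n:
        res = stats.permutation_test(
            (x,),
            lambda xs: stats.spearmanr(xs, y).statistic,
            permutation_type="pairings",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        p = float(res.pvalue)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return ComparisonResult("Spearman", rho, p)


# ---------------------------------------------------------------------------
# ANOVA / t-tests
# ---------------------------------------------------------------------------


def _to_wide(values: pd.DataFrame) -> pd.DataFrame:
    """Accept wide (subjects x conditions) or long (subject, condition,
    value) layouts; return complete-case wide."""
    if {"subject", "condition", "value"}.issubset(values.columns):
        wide = values.pivot(index="subject", columns="condition", values="value")
    else:
        wide = values.copy()
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        log.warning("dropping subjects with missing cells: %s", list(incomplete))
        wide = wide.dropna(axis=0)
    return wide


def greenhouse_geisser_epsilon(wide: pd.DataFrame) -> float:
    """Greenhouse–Geisser sphericity epsilon of a subjects x conditions
    table (reported alongside the omnibus test, not applied by default)."""
    s = np.cov(wide.to_numpy(dtype=float), rowvar=False)
    k = s.shape[0]
    mean_diag = np.trace(s) / k
    mean_all = s.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(s**2) - 2 * k * np.sum(s.mean(axis=1) ** 2) + k**2 * mean_all**2)
    return float(num / den) if den > 0 else 1.0


def rm_anova_bonferroni(values: pd.DataFrame) -> list[ComparisonResult]:
    """Repeated-measures ANOVA plus Bonferroni-corrected pairwise post-hocs.

    ``values`` is a subjects x conditions table (or long format with
    ``subject``/``condition``/``value`` columns).  Subjects with missing
    cells are dropped with a warning.  Returns the omnibus F first, then one
    ComparisonResult per condition pair with the Bonferroni-multiplied
    paired-t p-value (multiplier = number of pairs, capped at 1).
    """
    wide = _to_wide(values)
    if wide.shape[1] < 2 or wide.shape[0] < 2:
        raise StatsError("need >= 2 conditions and >= 2 complete subjects")
    long = wide.reset_index(names="subject").melt(
        id_vars="subject", var_name="condition", value_name="value"
    )
    if np.allclose(np.ptp(wide.to_numpy(), axis=1), 0):
        # no within-subject variation at all: F is 0/0; report the null result
        results = [ComparisonResult("rm-ANOVA", 0.0, 1.0, tuple(map(str, wide.columns)))]
    else:
        fit = AnovaRM(long, depvar="value", subject="subject", within=["condition"]).fit()
        f_val = float(fit.anova_table["F Value"].iloc[0])
        p_val = float(fit.anova_table["Pr > F"].iloc[0])
        if math.isnan(f_val):  # zero residual variance edge case
            f_val, p_val = 0.0, 1.0
        results = [
            ComparisonResult("rm-ANOVA", f_val, min(p_val, 1.0), tuple(map(str, wide.columns)))
        ]
    pairs = list(combinations(wide.columns, 2))
    m = len(pairs)
    for a, b in pairs:
        t = stats.ttest_rel(wide[a], wide[b])
        p_raw = 1.0 if math.isnan(t.pvalue) else float(t.pvalue)
        stat = 0.0 if math.isnan(t.statistic) else float(t.statistic)
        results.append(
            ComparisonResult(
                "Bonferroni post-hoc", stat, min(1.0, m * p_raw), (str(a), str(b))
            )
        )
    return results


def unpaired_ttest(
    a: Sequence[float], b: Sequence[float], pooled: bool = True
) -> ComparisonResult:
    """Two-sided unpaired t-test; classic pooled-variance by default, Welch
    behind the flag.  Two zero-variance samples with equal means yield the
    p = 1 sentinel."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each sample needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return ComparisonResult("unpaired t", 0.0, 1.0)
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return ComparisonResult("unpaired t", float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All analysis thresholds surfaced with their standard defaults."""

    hp_hz: float | None = 0.1
    lp_hz: float | None = 100.0
    discard_first_block: int = 10
    window_s: float = 0.2
    rectify: bool = True
    block_fraction: float = 0.05  # B_TH rule: block peak < 5% of pre peak
    onset_rel_threshold: float = 0.1  # TD measured between 10% crossings
    weak_block_max: float = 0.25
    strong_block_min: float = 0.75
    basis: str = "peak"
    pooled_ttest: bool = True
    subject_unit: str = "dataset_id"
    b_avg_scope: str = "global"  # per-frequency mean threshold scope
    format_version: str = "1.0"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    pass


def _trial_metrics(rec, cfg: PipelineConfig) -> dict:
    metrics = phase_metrics(
        rec,
        hp_hz=cfg.hp_hz,
        lp_hz=cfg.lp_hz,
        discard_first_block=cfg.discard_first_block,
        window_s=cfg.window_s,
        rectify=cfg.rectify,
    )
    out: dict = {}
    for phase, m in metrics.items():
        out[f"{phase}_peak"] = m.peak_force_n
        out[f"{phase}_auc"] = m.auc_ns
    if "pre" in metrics and "block" in metrics and metrics["pre"].peak_force_n > 0:
        out["blk_peak"] = 1.0 - metrics["block"].peak_force_n / metrics["pre"].peak_force_n
        if metrics["pre"].auc_ns > 0:
            out["blk_auc"] = 1.0 - metrics["block"].auc_ns / metrics["pre"].auc_ns
    return out


def run_pipeline(
    manifest: str | Path | pd.DataFrame,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    base_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Analyse every manifest row and write the report bundle.

    Writes delimited-text tables (trials, thresholds+charge, selectivity,
    recruitment fits and their per-frequency summary, onset raw/normalized
    and grouped, fatigue with scenario means) plus ``summary.json`` and a
    ``run_log.json`` recording the inputs, config hash, seed and library
    versions.  Per-trial failures are recorded and the remaining trials
    continue; the returned dict carries the tables and the error list.
    """
    cfg = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(manifest, (str, Path)):
        base_dir = Path(base_dir) if base_dir else Path(manifest).parent
        mdf = read_manifest(manifest)
    else:
        if base_dir is None:
            raise PipelineError("base_dir required when passing a manifest frame")
        base_dir = Path(base_dir)
        mdf = manifest
    if mdf.empty:
        raise PipelineError("empty manifest")

    trial_rows: list[dict] = []
    onset_rows = []
    errors: list[dict] = []
    for idx, row in mdf.iterrows():
        try:
            rec = read_recording(base_dir / row["recording"])
            kind = row["protocol_kind"]
            info = {
                "trial": idx,
                "recording": row["recording"],
                "dataset_id": row.get("dataset_id", ""),
                "animal_id": row.get("animal_id", ""),
                "protocol_kind": kind,
                "kes_frequency_khz": row.get("kes_frequency_khz", np.nan),
                "kes_amplitude_ma": row.get("kes_amplitude_ma", np.nan),
                "amplitude_ratio": row.get("amplitude_ratio", np.nan),
                "fascicle_a": row.get("fascicle_a", "TF"),
                "blife_diameter_um": row.get("blife_diameter_um", np.nan),
                "blife_length_mm": row.get("blife_length_mm", np.nan),
            }
            if kind == "ONSET":
                om = onset_metrics(rec, rel_threshold=cfg.onset_rel_threshold)
                onset_rows.append(om)
                info.update(
                    onset_peak=om.peak_force_n, onset_auc=om.auc_ns, onset_td=om.td_s
                )
            else:
                info.update(_trial_metrics(rec, cfg))
            trial_rows.append(info)
        except Exception as exc:  # noqa: BLE001 - per-trial isolation
            log.error("trial %s (%s) failed: %s", idx, row.get("recording"), exc)
            errors.append({"trial": int(idx), "recording": str(row.get("recording")), "error": str(exc)})

    trials = pd.DataFrame(trial_rows)
    tables: dict[str, pd.DataFrame] = {"trials": trials}

    basis_col = "blk_peak" if cfg.basis == "peak" else "blk_auc"

    # --- block thresholds and charge densities -----------------------------
    thr_rows = []
    bth_like = trials[trials["protocol_kind"].isin(["B_TH", "SEL"])] if not trials.empty else trials
    if not trials.empty and not bth_like.empty:
        for (ds, freq), grp in bth_like.groupby(["dataset_id", "kes_frequency_khz"]):
            grp = grp.dropna(subset=["pre_peak", "block_peak"]).sort_values("kes_amplitude_ma")
            grp = grp[grp["fascicle_a"] == "TF"]
            if grp.empty:
                continue
            sweep = list(
                zip(grp["kes_amplitude_ma"], grp["pre_peak"], grp["block_peak"])
            )
            try:
                thr = detect_block_threshold(sweep, freq, cfg.block_fraction)
            except Exception as exc:  # noqa: BLE001
                errors.append({"trial": None, "recording": f"{ds}@{freq}kHz", "error": str(exc)})
                continue
            rec_row = {
                "dataset_id": ds,
                "kes_frequency_khz": freq,
                "b_th_ma": thr.b_th_ma,
                "t_kes_us": thr.t_kes_s * 1e6,
                "blocked": thr.blocked,
            }
            d_um, l_mm = grp["blife_diameter_um"].iloc[0], grp["blife_length_mm"].iloc[0]
            if thr.blocked and np.isfinite(d_um) and np.isfinite(l_mm):
                cr = charge_result(thr.b_th_ma, freq, ElectrodeSpec(d_um, l_mm))
                rec_row.update(
                    q_per_phase_c=cr.q_per_phase_c,
                    s_life_cm2=cr.s_life_cm2,
                    charge_density_uc_cm2=cr.sigma_per_phase_uc_cm2,
                )
            thr_rows.append(rec_row)
    thresholds = pd.DataFrame(thr_rows)
    tables["thresholds"] = thresholds

    # --- selectivity --------------------------------------------------------
    sel_rows = []
    sel = trials[trials["protocol_kind"] == "SEL"] if not trials.empty else trials
    if not trials.empty and not sel.empty and basis_col in sel.columns:
        for (freq, ratio), grp in sel.dropna(subset=["amplitude_ratio"]).groupby(
            ["kes_frequency_khz", "amplitude_ratio"]
        ):
            by_fasc = grp.groupby("fascicle_a")[basis_col].mean()
            if {"TF", "PF"}.issubset(by_fasc.index):
                s = selectivity_index(by_fasc.to_dict(), "TF")
                sel_rows.append(
                    {
                        "kes_frequency_khz": freq,
                        "amplitude_ratio": ratio,
                        "blk_tf": by_fasc["TF"],
                        "blk_pf": by_fasc["PF"],
                        "s_tf": s.s_index,
                    }
                )
    tables["selectivity"] = pd.DataFrame(sel_rows)

    # --- recruitment fits ---------------------------------------------------
    fits = []
    fit_rows = []
    if not trials.empty and not sel.empty and basis_col in sel.columns:
        tf_sel = sel[sel["fascicle_a"] == "TF"].dropna(subset=[basis_col])
        for (ds, freq), grp in tf_sel.groupby(["dataset_id", "kes_frequency_khz"]):
            if len(grp) < 5:
                continue
            try:
                fit = fit_recruitment(
                    grp["kes_amplitude_ma"].to_numpy(),
                    grp[basis_col].to_numpy(),
                    kes_frequency_khz=freq,
                    basis=cfg.basis,
                    dataset_id=str(ds),
                )
            except RecruitmentError as exc:
                errors.append({"trial": None, "recording": f"{ds}@{freq}kHz", "error": str(exc)})
                continue
            fits.append(fit)
            fit_rows.append(
                {
                    "dataset_id": ds,
                    "kes_frequency_khz": freq,
                    "basis": fit.basis,
                    "sigma_ma": fit.sigma_ma,
                    "beta_per_ma": fit.beta_per_ma,
                    "r_squared": fit.r_squared,
                    "n_points": fit.n_points,
                    "at_bound": fit.at_bound,
                }
            )
    tables["recruitment_fits"] = pd.DataFrame(fit_rows)
    tables["recruitment_summary"] = (
        summarize_fits(fits) if fits else pd.DataFrame()
    )

    # --- onset --------------------------------------------------------------
    if onset_rows:
        by_ds: dict[str, list] = {}
        for m in onset_rows:
            by_ds.setdefault(m.dataset_id, []).append(m)
        raw_all, norm_all = [], []
        for ds, ms in by_ds.items():
            try:
                norm = normalize_onset(ms)
            except Exception as exc:  # noqa: BLE001
                errors.append({"trial": None, "recording": f"onset:{ds}", "error": str(exc)})
                continue
            raw_all.extend(ms)
            norm_all.extend(norm)
        tables["onset"] = onset_table(raw_all, norm_all)
        try:
            tables["onset_summary"] = onset_summary(norm_all)
        except Exception as exc:  # noqa: BLE001
            errors.append({"trial": None, "recording": "onset_summary", "error": str(exc)})
            tables["onset_summary"] = pd.DataFrame()
    else:
        tables["onset"] = pd.DataFrame()
        tables["onset_summary"] = pd.DataFrame()

    # --- fatigue ------------------------------------------------------------
    if not trials.empty:
        pre_col = "pre_peak" if cfg.basis == "peak" else "pre_auc"
        post_col = "post_peak" if cfg.basis == "peak" else "post_auc"
        eligible = trials[
            trials["protocol_kind"].isin(["FATIGUE-no-KES", "FATIGUE-ideal-block", "SEL"])
        ].copy()
        if not eligible.empty and pre_col in eligible.columns:
            eligible = eligible.rename(columns={pre_col: "x_pre", post_col: "x_post"})
            if basis_col in eligible.columns:
                eligible["blk"] = eligible[basis_col]
            eligible = eligible[eligible["fascicle_a"] == "TF"]
            fatigue = fatigue_scenarios(eligible.dropna(subset=["x_pre", "x_post"]), cfg.basis)
            tables["fatigue"] = fatigue
            tables["fatigue_summary"] = scenario_means(fatigue) if not fatigue.empty else pd.DataFrame()
        else:
            tables["fatigue"] = pd.DataFrame()
            tables["fatigue_summary"] = pd.DataFrame()

    # --- write bundle -------------------------------------------------------
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False, float_format=FLOAT_FORMAT)
    summary = {
        "n_trials": int(len(mdf)),
        "n_analysed": int(len(trials)),
        "n_errors": len(errors),
        "tables": {name: int(len(df)) for name, df in tables.items()},
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    run_log = {
        "config": json.loads(cfg.to_json()),
        "config_hash": cfg.digest(),
        "seed": seed,
        "manifest_rows": int(len(mdf)),
        "errors": errors,
        "versions": {
            "kesblock": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "python": platform.python_version(),
        },
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=1, sort_keys=True))
    return {"tables": tables, "errors": errors, "summary": summary}


__all__ = [
    "ComparisonResult",
    "FLOAT_FORMAT",
    "PipelineConfig",
    "PipelineError",
    "RegressionResult",
    "StatsError",
    "greenhouse_geisser_epsilon",
    "rm_anova_bonferroni",
    "run_pipeline",
    "spearman_corr",
    "threshold_frequency_regression",
    "unpaired_ttest",
]
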