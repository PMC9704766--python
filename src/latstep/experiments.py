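"""Batch simulation harnesses and band comparisons.

Reproduces the two numerical experiment designs used to probe the
stepping-regulation model:

* :func:`run_batch` — many independent simulations of one maneuver
  schedule, summarized per step index (means/SDs of foot placements,
  step variables and goal errors; prediction ellipses at labeled steps).
* :func:`rho_sweep` — hold the control proportion rho constant at every
  step, sweep it over a grid, and test whether any constant value keeps
  the simulated means and SDs of body position and step width inside
  reference bands at every step of the maneuver.  Reference bands stand
  in for experimental 95% confidence intervals and may come from data or
  from the model itself (:func:`make_model_bands`).

Sweep aggregation is two-level, matching the stated procedure: per
batch, means and SDs over that batch's simulations; then the overall
mean of the batch means and the overall mean of the batch SDs across
batches (never pooled across batches).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ellipse import PredictionEllipse, fit_covariance, prediction_ellipse
from .maneuver import ManeuverSchedule, ScheduleEntry
from .regulator import RegulatorParams, default_position_params, default_width_params
from .stepper import EnsembleResult, simulate_ensemble

__all__ = [
    "BatchSummary",
    "ReferenceBands",
    "run_batch",
    "summarize_ensemble",
    "compare_to_bands",
    "make_model_bands",
    "constant_rho_schedule",
    "rho_sweep",
]

_VARS = ("z_L", "z_R", "z_B", "w", "F_zB", "F_w")


@dataclass
class BatchSummary:
    """Per-step summary of one batch of simulations.

    ``stats`` is indexed by step_index with columns ``mean_<var>`` and
    ``sd_<var>`` for var in z_L, z_R, z_B, w, F_zB, F_w; ``ellipses``
    maps step index -> fitted 95% prediction ellipse.
    """

    stats: pd.DataFrame
    ellipses: dict[int, PredictionEllipse] = field(default_factory=dict)
    n_sims: int = 0
    seed: int | None = None


@dataclass
class ReferenceBands:
    """Per-step intervals for simulated statistics to be judged against.

    ``table`` columns: step_index, variable (z_B | w), stat (mean | sd),
    low, high, provenance (experimental | synthetic).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"step_index", "variable", "stat", "low", "high"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"bands table missing columns: {sorted(missing)}")
        if (self.table["low"] > self.table["high"]).any():
            raise ValueError("bands must satisfy low <= high")

    def widened(self, margin: float) -> "ReferenceBands":
        t = self.table.copy()
        t["low"] -= margin
        t["high"] += margin
        return ReferenceBands(t)


def _ensemble_arrays(res: EnsembleResult) -> dict[str, np.ndarray]:
    F_zB, F_w = res.errors()
    return {
        "z_L": res.z_L,
        "z_R": res.z_R,
        "z_B": res.z_B,
        "w": res.w,
        "F_zB": F_zB,
        "F_w": F_w,
    }


def summarize_ensemble(res: EnsembleResult) -> pd.DataFrame:
    """Mean and SD (ddof=1) of each stepping variable at each step index."""
    arrays = _ensemble_arrays(res)
    data: dict[str, np.ndarray] = {}
    for name, arr in arrays.items():
        data[f"mean_{name}"] = arr.mean(axis=0)
        data[f"sd_{name}"] = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
    df = pd.DataFrame(data, index=pd.Index(res.step_indices, name="step_index"))
    return df


def run_batch(
    schedule: ManeuverSchedule,
    n_sims: int,
    seed: int | np.random.Generator,
    reg_zB: RegulatorParams | None = None,
    reg_w: RegulatorParams | None = None,
    start_index: int | None = None,
    stop_index: int | None = None,
    ellipse_steps: Iterable[int] | None = None,
) -> BatchSummary:
    """Simulate ``n_sims`` maneuvers and summarize them per step index.

    Prediction ellipses are fitted at ``ellipse_steps`` (default: the
    schedule's labeled steps) from the [z_L, z_R] clouds.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    if reg_zB is None:
        reg_zB = default_position_params(schedule.entry(schedule.min_index).goal.z_B_star)
    if reg_w is None:
        reg_w = default_width_params(schedule.entry(schedule.min_index).goal.w_star)
    res = simulate_ensemble(
        schedule, n_sims, reg_zB, reg_w, rng=seed, start_index=start_index, stop_index=stop_index
    )
    stats = summarize_ensemble(res)
    if ellipse_steps is None:
        ellipse_steps = sorted(set(schedule.labels.values()))
    ellipses: dict[int, PredictionEllipse] = {}
    idx_lookup = {int(i): j for j, i in enumerate(res.step_indices)}
    for step in ellipse_steps:
        if int(step) not in idx_lookup:
            continue
        j = idx_lookup[int(step)]
        pts = np.column_stack([res.z_L[:, j], res.z_R[:, j]])
        center, C = fit_covariance(pts)
        ellipses[int(step)] = prediction_ellipse(center, C, n_points=n_sims)
    return BatchSummary(
        stats=stats,
        ellipses=ellipses,
        n_sims=n_sims,
        seed=seed if isinstance(seed, int) else None,
    )


def compare_to_bands(summary: BatchSummary | pd.DataFrame, bands: ReferenceBands) -> pd.DataFrame:
    """Judge summarized statistics against reference bands.

    Returns the bands table with the simulated ``value`` and a boolean
    ``inside`` column (closed intervals).  Band rows whose step index is
    absent from the summary raise a configuration error.
    """
    stats = summary.stats if isinstance(summary, BatchSummary) else summary
    rows = []
    for _, b in bands.table.iterrows():
        idx = int(b["step_index"])
        col = f"{b['stat']}_{b['variable']}"
        if idx not in stats.index:
            raise ValueError(f"summary has no step index {idx} required by the bands")
        if col not in stats.columns:
            raise ValueError(f"summary has no statistic {col!r}")
        value = float(stats.loc[idx, col])
        rows.append(
            {
                "step_index": idx,
                "variable": b["variable"],
                "stat": b["stat"],
                "value": value,
                "low": float(b["low"]),
                "high": float(b["high"]),
                "inside": bool(b["low"] <= value <= b["high"]),
            }
        )
    return pd.DataFrame(rows)


def _batch_stats(
    schedule: ManeuverSchedule,
    n_batches: int,
    n_sims: int,
    seed: int,
    reg_zB: RegulatorParams,
    reg_w: RegulatorParams,
    start_index: int | None,
    stop_index: int | None,
) -> tuple[np.ndarray, list[pd.DataFrame]]:
    """Per-batch summary frames, seeded independently per batch."""
    seqs = np.random.SeedSequence(seed).spawn(n_batches)
    frames = []
    for ss in seqs:
        res = simulate_ensemble(
            schedule,
            n_sims,
            reg_zB,
            reg_w,
            rng=np.random.default_rng(ss),
            start_index=start_index,
            stop_index=stop_index,
        )
        frames.append(summarize_ensemble(res))
    return frames[0].index.to_numpy(), frames


def two_level_summary(frames: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Overall mean of batch means and mean of batch SDs, per step index."""
    stacked = pd.concat(frames, keys=range(len(frames)))
    return stacked.groupby(level=1).mean()


def make_model_bands(
    schedule: ManeuverSchedule,
    n_batches: int,
    n_sims: int,
    seed: int,
    reg_zB: RegulatorParams | None = None,
    reg_w: RegulatorParams | None = None,
    level: float = 0.95,
    variables: Sequence[str] = ("z_B", "w"),
    stats: Sequence[str] = ("mean", "sd"),
    start_index: int | None = None,
    stop_index: int | None = None,
    step_indices: Iterable[int] | None = None,
) -> ReferenceBands:
    """Synthetic reference bands: percentile range of per-batch statistics.

    Emulates bootstrapped experimental confidence bands with the model
    itself as the data-generating process; provenance is 'synthetic'.
    """
    if reg_zB is None:
        reg_zB = default_position_params(schedule.entry(schedule.min_index).goal.z_B_star)
    if reg_w is None:
        reg_w = default_width_params(schedule.entry(schedule.min_index).goal.w_star)
    _, frames = _batch_stats(
        schedule, n_batches, n_sims, seed, reg_zB, reg_w, start_index, stop_index
    )
    stacked = pd.concat(frames, keys=range(len(frames)))
    lo_q, hi_q = 100.0 * (1.0 - level) / 2.0, 100.0 * (1.0 + level) / 2.0
    rows = []
    keep = None if step_indices is None else {int(i) for i in step_indices}
    for idx in frames[0].index:
        if keep is not None and int(idx) not in keep:
            continue
        for var in variables:
            for stat in stats:
                col = f"{stat}_{var}"
                vals = stacked[col].xs(idx, level=1).to_numpy()
                rows.append(
                    {
                        "step_index": int(idx),
                        "variable": var,
                        "stat": stat,
                        "low": float(np.percentile(vals, lo_q)),
                        "high": float(np.percentile(vals, hi_q)),
                        "provenance": "synthetic",
                    }
                )
    return ReferenceBands(pd.DataFrame(rows))


def constant_rho_schedule(schedule: ManeuverSchedule, rho: float) -> ManeuverSchedule:
    """Schedule with rho held constant and noise multipliers reset to 1.

    Goals are kept: a constant-rho model still follows the maneuver's
    stepping goals, but applies no step-specific regulation changes.
    """
    entries = {
        i: ScheduleEntry(goal=e.goal, rho=rho, sigma_a_multiplier=1.0)
        for i, e in schedule.entries.items()
    }
    return ManeuverSchedule(
        entries=entries,
        labels=dict(schedule.labels),
        anchor_index=schedule.anchor_index,
        anchor_foot=schedule.anchor_foot,
    )


def rho_sweep(
    schedule: ManeuverSchedule,
    rho_grid: Sequence[float],
    n_batches: int,
    n_sims: int,
    bands: ReferenceBands,
    seed: int,
    reg_zB: RegulatorParams | None = None,
    reg_w: RegulatorParams | None = None,
    start_index: int | None = None,
    stop_index: int | None = None,
) -> tuple[pd.DataFrame, dict[float, pd.DataFrame]]:
    """Constant-rho sweep against reference bands.

    For each rho in the grid, the schedule's goals are kept but rho is
    held constant at every step (noise multipliers reset to 1);
    ``n_batches`` batches of ``n_sims`` simulations are aggregated
    two-level, and the rho passes iff every banded statistic falls
    inside its interval at every step.

    Returns (per-rho pass/fail table, per-rho overall summary frames).
    """
    if any(r < 0 or r > 1 for r in rho_grid):
        raise ValueError("rho grid must lie within [0, 1]")
    if reg_zB is None:
        reg_zB = default_position_params(schedule.entry(schedule.min_index).goal.z_B_star)
    if reg_w is None:
        reg_w = default_width_params(schedule.entry(schedule.min_index).goal.w_star)
    rows = []
    summaries: dict[float, pd.DataFrame] = {}
    for j, rho in enumerate(rho_grid):
        sched = constant_rho_schedule(schedule, rho)
        _, frames = _batch_stats(
            sched, n_batches, n_sims, seed + j, reg_zB, reg_w, start_index, stop_index
        )
        overall = two_level_summary(frames)
        summaries[float(rho)] = overall
        comparison = compare_to_bands(overall, bands)
        rows.append(
            {
                "rho": float(rho),
                "passed": bool(comparison["inside"].all()),
                "n_outside": int((~comparison["inside"]).sum()),
                "n_checks": int(len(comparison)),
            }
        )
    return pd.DataFrame(rows), summaries
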