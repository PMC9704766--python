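"""Stepping-data interchange, preprocessing, and synthetic experiments.

Stepping time series travel as tidy delimited text with one row per
step.  Schema (version 1): ``participant_id, trial_id, maneuver_id,
step_index, moving_foot, z_L_m, z_R_m`` plus optional ``z_B_m, w_m,
path_label, cue_flag``.  Comma and tab delimiters are auto-detected;
derived columns are recomputed from the feet and, when present in the
file, cross-checked.

Preprocessing mirrors the experimental pipeline for lane-change
maneuvers between two parallel paths: every maneuver is normalized to a
constant left-to-right direction (leftward maneuvers mirrored) and
re-indexed so that step 0 is the last step taken on the original path
(:func:`align_maneuvers`); steady-state stepping goals are estimated
from steps outside the closed exclusion window [-5, +10] around the
transition (:func:`estimate_steady_goals`); per-step goal errors use
the pre-transition position goal through step 0 and the post-transition
goal from step 1 (:func:`stepping_errors`).

:func:`generate_synthetic_experiment` emulates the study design — 20
participants x 4 lane changes between paths 0.6 m apart, with flanking
steady-state walking — using the stepping model itself as the generator,
and stands in for archived experimental data in all tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import StepGoal
from .maneuver import (
    FourStepConfig,
    ManeuverSchedule,
    four_step_schedule,
    mirror_schedule,
)
from .regulator import RegulatorParams, default_position_params, default_width_params
from .stepper import StepRecord, simulate_ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMA_COLUMNS",
    "REQUIRED_COLUMNS",
    "SteadyStateEstimates",
    "read_stepping_csv",
    "write_stepping_csv",
    "records_to_table",
    "align_maneuvers",
    "classify_strategy",
    "estimate_steady_goals",
    "stepping_errors",
    "estimate_epsilon",
    "generate_synthetic_experiment",
    "default_lane_change_schedule",
    "make_crossover_fixture",
    "make_multistep_fixture",
]

REQUIRED_COLUMNS = ["maneuver_id", "step_index", "moving_foot", "z_L_m", "z_R_m"]
SCHEMA_COLUMNS = [
    "participant_id",
    "trial_id",
    "maneuver_id",
    "step_index",
    "moving_foot",
    "z_L_m",
    "z_R_m",
    "z_B_m",
    "w_m",
    "path_label",
    "cue_flag",
]

#: Tolerance (m) for cross-checking stored z_B/w against the feet.
_CONSISTENCY_TOL = 1e-6

#: Minimum net body displacement (m) for a maneuver to count as a crossing.
_MIN_DISPLACEMENT = 0.1

#: Closed step-index window around the transition excluded from
#: steady-state estimates.
EXCLUSION_WINDOW = (-5, 10)


@dataclass(frozen=True)
class SteadyStateEstimates:
    """Steady-state stepping goals and variability, from aligned data.

    SDs feed the regulators' additive-noise defaults: ``sd_w`` for the
    step-width regulator, ``sd_zB`` (about per-path means) for the
    body-position regulator.
    """

    w_star: float
    z_B_star_left_path: float
    z_B_star_right_path: float
    sd_w: float
    sd_zB: float
    n_steps: int


# ---------------------------------------------------------------------------
# interchange


def _derive_step_vars(table: pd.DataFrame, check: bool = True) -> pd.DataFrame:
    table = table.copy()
    z_B = 0.5 * (table["z_L_m"] + table["z_R_m"])
    w = table["z_R_m"] - table["z_L_m"]
    for col, derived in (("z_B_m", z_B), ("w_m", w)):
        if check and col in table.columns and table[col].notna().any():
            bad = (table[col] - derived).abs() > _CONSISTENCY_TOL
            if bad.any():
                logger.warning(
                    "%s inconsistent with feet beyond %.1e m in rows %s; recomputed",
                    col,
                    _CONSISTENCY_TOL,
                    list(table.index[bad][:20]),
                )
        table[col] = derived
    return table


def read_stepping_csv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a stepping table (comma- or tab-delimited) and validate it.

    ``column_map`` renames foreign column headers to the documented
    schema (``{"their_name": "schema_name"}``), accommodating deposits
    whose naming differs from ours.
    """
    try:
        table = pd.read_csv(path, sep=None, engine="python")
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed stepping file {path}: {exc}") from exc
    if column_map:
        table = table.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"stepping file {path} is missing required columns: {missing}")
    for col in ("z_L_m", "z_R_m"):
        values = pd.to_numeric(table[col], errors="coerce")
        bad = values.isna() & table[col].notna()
        if bad.any():
            lines = [int(i) + 2 for i in table.index[bad][:10]]  # header is line 1
            raise ValueError(f"non-numeric {col} in {path} at line(s) {lines}")
        table[col] = values
    table["step_index"] = table["step_index"].astype(int)
    foot = table["moving_foot"].astype(str).str.lower()
    if not foot.isin(["left", "right"]).all():
        bad = sorted(set(foot[~foot.isin(["left", "right"])]))
        raise ValueError(f"moving_foot must be 'left' or 'right', found {bad}")
    table["moving_foot"] = foot
    return _derive_step_vars(table)


def write_stepping_csv(table: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a stepping table with derived columns filled in."""
    table = _derive_step_vars(table, check=False)
    cols = [c for c in SCHEMA_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, sep=sep, index=False)


def records_to_table(
    records: Sequence[StepRecord], participant_id: str = "P01", trial_id: str = "T1"
) -> pd.DataFrame:
    """Tabulate simulated step records in the interchange schema."""
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "trial_id": trial_id,
            "maneuver_id": [r.maneuver_id for r in records],
            "step_index": [r.step_index for r in records],
            "moving_foot": [r.moving_foot for r in records],
            "z_L_m": [r.z_L for r in records],
            "z_R_m": [r.z_R for r in records],
            "z_B_m": [r.z_B for r in records],
            "w_m": [r.w for r in records],
        }
    )


# ---------------------------------------------------------------------------
# alignment and classification


def _maneuver_geometry(rows: pd.DataFrame, n_edge: int = 3) -> tuple[float, float]:
    """(original path center, new path center) from the trace's ends."""
    rows = rows.sort_values("step_index")
    start = float(rows["z_B_m"].iloc[:n_edge].mean())
    end = float(rows["z_B_m"].iloc[-n_edge:].mean())
    return start, end


def _moving_foot_placement(rows: pd.DataFrame) -> pd.Series:
    return rows["z_L_m"].where(rows["moving_foot"] == "left", rows["z_R_m"])


def _mirror_rows(rows: pd.DataFrame) -> pd.DataFrame:
    """Left/right mirror: z -> -z with feet relabeled (z_L' = -z_R)."""
    out = rows.copy()
    out["z_L_m"], out["z_R_m"] = -rows["z_R_m"].to_numpy(), -rows["z_L_m"].to_numpy()
    out["moving_foot"] = rows["moving_foot"].map({"left": "right", "right": "left"})
    if "path_label" in out.columns:
        out["path_label"] = rows["path_label"].map(
            lambda s: {"left": "right", "right": "left"}.get(s, s)
        )
    return _derive_step_vars(out, check=False)


def align_maneuvers(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize every maneuver to left-to-right with step 0 at initiation.

    Initiation is the last step taken on the original path: step 0 is
    the step immediately before the first moving-foot placement at or
    beyond the midline between the two path centers (ties count as the
    new path).  Leftward maneuvers are mirrored.  Maneuvers with no
    detectable crossing are excluded and logged.  Idempotent.
    """
    table = _derive_step_vars(table, check=False)
    aligned = []
    for mid, rows in table.groupby("maneuver_id", sort=False):
        rows = rows.sort_values("step_index").reset_index(drop=True)
        start, end = _maneuver_geometry(rows)
        if abs(end - start) < _MIN_DISPLACEMENT:
            logger.warning("maneuver %s excluded: no detectable path crossing", mid)
            continue
        if end < start:
            rows = _mirror_rows(rows)
            start, end = -start, -end
        midline = 0.5 * (start + end)
        beyond = _moving_foot_placement(rows) >= midline
        crossing_pos = int(np.argmax(beyond.to_numpy())) if beyond.any() else None
        if crossing_pos is None or crossing_pos == 0:
            logger.warning("maneuver %s excluded: crossing step not identifiable", mid)
            continue
        initiation_index = int(rows["step_index"].iloc[crossing_pos - 1])
        rows["step_index"] = rows["step_index"] - initiation_index
        aligned.append(rows)
    if not aligned:
        raise ValueError("no maneuvers survived alignment")
    return pd.concat(aligned, ignore_index=True)


def classify_strategy(maneuver_rows: pd.DataFrame) -> str:
    """Classify an aligned maneuver's crossing strategy.

    Returns ``'ipsilateral_single_step'`` (the typical strategy: the
    first foot on the new-path side is the right/ipsilateral foot),
    ``'crossover'`` (first crossing foot contralateral), or
    ``'multi_step'`` (extra partial steps were needed to reach the new
    path).  A step counts as "between the paths" when the body position
    z_B lies in the middle half of the gap between the path centers; the
    usual strategies place at most one step there (the crossing step),
    while a staircase-style maneuver places two or more.
    """
    rows = _derive_step_vars(maneuver_rows, check=False)
    rows = rows.sort_values("step_index").reset_index(drop=True)
    start, end = _maneuver_geometry(rows)
    midline = 0.5 * (start + end)
    placement = _moving_foot_placement(rows)
    beyond = placement >= midline
    if not beyond.any():
        raise ValueError("maneuver never crosses the midline; align/exclude first")
    first_cross = int(np.argmax(beyond.to_numpy()))
    in_gap = (rows["z_B_m"] - midline).abs() < 0.25 * abs(end - start)
    if int(in_gap.sum()) > 1:
        return "multi_step"
    direction_foot = "right" if end > start else "left"
    if rows["moving_foot"].iloc[first_cross] != direction_foot:
        return "crossover"
    return "ipsilateral_single_step"


# ---------------------------------------------------------------------------
# steady-state goals and errors


def _steady_masks(table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    lo, hi = EXCLUSION_WINDOW
    pre = table["step_index"] < lo
    post = table["step_index"] > hi
    return pre, post


def estimate_steady_goals(table: pd.DataFrame) -> SteadyStateEstimates:
    """Steady-state stepping goals from steps outside the exclusion window.

    ``w*`` is the mean step width pooled across both paths; the position
    goal is estimated per path (pre-transition = left path, post = right
    path, after alignment).  SDs are about the respective means.
    """
    table = _derive_step_vars(table, check=False)
    pre, post = _steady_masks(table)
    if not pre.any() or not post.any():
        raise ValueError(
            "no steady-state steps outside the exclusion window "
            f"[{EXCLUSION_WINDOW[0]}, {EXCLUSION_WINDOW[1]}] on one or both paths"
        )
    steady = table[pre | post]
    zB_pre = float(table.loc[pre, "z_B_m"].mean())
    zB_post = float(table.loc[post, "z_B_m"].mean())
    dev_zB = pd.concat(
        [table.loc[pre, "z_B_m"] - zB_pre, table.loc[post, "z_B_m"] - zB_post]
    )
    return SteadyStateEstimates(
        w_star=float(steady["w_m"].mean()),
        z_B_star_left_path=zB_pre,
        z_B_star_right_path=zB_post,
        sd_w=float(steady["w_m"].std(ddof=1)),
        sd_zB=float(dev_zB.std(ddof=1)),
        n_steps=int(len(steady)),
    )


def stepping_errors(
    table: pd.DataFrame, goals: SteadyStateEstimates
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Goal errors per step and their per-index summary.

    The position goal switches at initiation: steps with index <= 0 are
    judged against the pre-transition (left path) goal, steps with
    index >= 1 against the post-transition goal.  The width goal is the
    single pooled ``w*`` throughout.

    Returns ``(per_step, summary)``: the input rows with ``F_zB``/``F_w``
    columns added, and mean/SD of each error per step index.
    """
    out = _derive_step_vars(table, check=False)
    zB_star = np.where(
        out["step_index"] <= 0, goals.z_B_star_left_path, goals.z_B_star_right_path
    )
    out["F_zB"] = out["z_B_m"] - zB_star
    out["F_w"] = out["w_m"] - goals.w_star
    summary = (
        out.groupby("step_index")[["F_zB", "F_w"]]
        .agg(["mean", "std"])
        .rename(columns={"std": "sd"})
    )
    summary.columns = [f"{stat}_{var}" for var, stat in summary.columns]
    return out, summary


def estimate_epsilon(
    table: pd.DataFrame, prep_index: int = 0, recovery_index: int = 2
) -> float:
    """Intermediate offset epsilon from preparatory/recovery foot placements.

    Averages the signed medial foot-placement differences, relative to
    that foot's steady-state placement, of the offset foot at the
    preparatory step (left foot, vs. its pre-transition steady mean) and
    at the recovery step (right foot — placed at the transition — vs.
    its post-transition steady mean).  On aligned left-to-right data
    both differences are medial (toward the other path) in expectation,
    so signed averaging is unbiased under symmetric placement noise; the
    magnitude of the mean is returned.

    With partial error correction (gain k < 1) realized offsets are
    attenuated by about k relative to the scheduled offset.
    """
    table = _derive_step_vars(table, check=False)
    pre, post = _steady_masks(table)
    if not pre.any() or not post.any():
        raise ValueError("steady-state steps required to reference foot placements")
    zL_steady_pre = float(table.loc[pre, "z_L_m"].mean())
    zR_steady_post = float(table.loc[post, "z_R_m"].mean())
    prep = table[table["step_index"] == prep_index]
    recov = table[table["step_index"] == recovery_index]
    if prep.empty or recov.empty:
        raise ValueError(
            f"no rows at preparatory index {prep_index} or recovery index {recovery_index}"
        )
    offsets = np.concatenate(
        [
            (prep["z_L_m"] - zL_steady_pre).to_numpy(),  # medial is +z
            (zR_steady_post - recov["z_R_m"]).to_numpy(),  # medial is -z
        ]
    )
    return float(abs(offsets.mean()))


# ---------------------------------------------------------------------------
# synthetic experiment


def default_lane_change_schedule(
    path_separation: float = 0.6, w_star: float = 0.12, epsilon: float | None = 0.03
) -> ManeuverSchedule:
    """Four-step schedule for the canonical lane change (paths 0.6 m apart)."""
    half = 0.5 * path_separation
    cfg = FourStepConfig(
        initial=StepGoal(-half, w_star), final=StepGoal(half, w_star), epsilon=epsilon
    )
    return four_step_schedule(cfg)


def generate_synthetic_experiment(
    n_participants: int = 20,
    n_maneuvers: int = 4,
    steady_steps_per_side: int = 8,
    schedule: ManeuverSchedule | None = None,
    seed: int = 0,
    reg_zB: RegulatorParams | None = None,
    reg_w: RegulatorParams | None = None,
    participant_goal_sd: float = 0.0,
    n_burnin_steps: int = 30,
    n_crossover: int = 0,
    n_multistep: int = 0,
) -> pd.DataFrame:
    """Model-generated stand-in for the lane-change experiment.

    Per participant x maneuver, one simulated trace spanning step
    indices ``-(5 + steady_steps_per_side) .. 10 + steady_steps_per_side``,
    so each maneuver contributes ``2 * steady_steps_per_side``
    steady-state steps outside the exclusion window (defaults: 20 x 4
    maneuvers x 16 = 1280 pooled steady-state steps).  Each trace is
    preceded by ``n_burnin_steps`` discarded steady-walking steps so the
    pre-maneuver stepping distribution is stationary, as it is for
    participants walking continuously between maneuvers.  Maneuver
    direction alternates (half leftward, mirrored at generation);
    a nominal auditory cue is marked 0-3 steps before initiation
    (bookkeeping only — the generator does not model cue response).
    ``participant_goal_sd`` optionally perturbs each participant's
    position goals (m) to mimic inter-participant heterogeneity.
    Optional hand-constructed crossover / multi-step maneuvers can be
    appended for strategy-classification exercises.
    """
    if schedule is None:
        schedule = default_lane_change_schedule()
    if reg_zB is None:
        reg_zB = default_position_params()
    if reg_w is None:
        reg_w = default_width_params(schedule.entry(schedule.min_index).goal.w_star)

    start = -(5 + steady_steps_per_side)
    stop = 10 + steady_steps_per_side
    root = np.random.SeedSequence(seed)
    tables = []
    for p, p_seq in enumerate(root.spawn(n_participants), start=1):
        pid = f"P{p:02d}"
        p_rng = np.random.default_rng(p_seq)
        goal_shift = participant_goal_sd * p_rng.standard_normal() if participant_goal_sd else 0.0
        for m in range(1, n_maneuvers + 1):
            mid = f"{pid}-M{m}"
            rightward = m % 2 == 1
            sched = schedule if rightward else mirror_schedule(schedule)
            if goal_shift:
                sched = ManeuverSchedule(
                    entries={
                        i: type(e)(
                            goal=StepGoal(e.goal.z_B_star + goal_shift, e.goal.w_star),
                            rho=e.rho,
                            sigma_a_multiplier=e.sigma_a_multiplier,
                        )
                        for i, e in sched.entries.items()
                    },
                    labels=dict(sched.labels),
                    anchor_index=sched.anchor_index,
                    anchor_foot=sched.anchor_foot,
                )
            res = simulate_ensemble(
                sched,
                1,
                reg_zB,
                reg_w,
                rng=p_rng,
                start_index=start - n_burnin_steps,
                stop_index=stop,
            )
            keep = slice(n_burnin_steps, None)
            cue_lag = int(p_rng.integers(0, 4))
            rows = pd.DataFrame(
                {
                    "participant_id": pid,
                    "trial_id": "T1",
                    "maneuver_id": mid,
                    "step_index": res.step_indices[keep],
                    "moving_foot": res.moving_foot[n_burnin_steps:],
                    "z_L_m": res.z_L[0, keep],
                    "z_R_m": res.z_R[0, keep],
                    "path_label": np.where(
                        res.step_indices[keep] <= 0,
                        "left" if rightward else "right",
                        "right" if rightward else "left",
                    ),
                    "cue_flag": res.step_indices[keep] == -cue_lag,
                }
            )
            tables.append(_derive_step_vars(rows, check=False))

    for i in range(n_crossover):
        tables.append(make_crossover_fixture(f"PX-C{i + 1}", start, stop))
    for i in range(n_multistep):
        tables.append(make_multistep_fixture(f"PX-S{i + 1}", start, stop))
    return pd.concat(tables, ignore_index=True)


def _fixture_frame(mid: str, placements: list[tuple[int, str, float, float]]) -> pd.DataFrame:
    rows = pd.DataFrame(
        placements, columns=["step_index", "moving_foot", "z_L_m", "z_R_m"]
    )
    rows.insert(0, "maneuver_id", mid)
    rows.insert(0, "trial_id", "T1")
    rows.insert(0, "participant_id", "PX")
    rows["path_label"] = np.where(rows["step_index"] <= 0, "left", "right")
    rows["cue_flag"] = False
    return _derive_step_vars(rows, check=False)


def _steady_rows(indices, foot_at, z_L, z_R):
    return [(int(i), foot_at(int(i)), z_L, z_R) for i in indices]


def make_crossover_fixture(mid: str, start: int = -13, stop: int = 18) -> pd.DataFrame:
    """Noiseless left-to-right maneuver crossed with the contralateral foot.

    Synthetic construction (not model output): the left foot takes the
    large crossing step onto the new path, landing lateral of the right
    foot (negative step width mid-crossing).
    """

    def foot(i: int) -> str:
        return "right" if i % 2 == 1 else "left"

    placements = _steady_rows(range(start, 1), foot, -0.36, -0.24)
    placements += [
        (1, "right", -0.36, -0.30),  # slight inward right step
        (2, "left", 0.30, -0.30),  # crossover: left foot lands on the new path
        (3, "right", 0.30, 0.36),  # right foot follows (uncrossing)
        (4, "left", 0.24, 0.36),  # normal stance restored
    ]
    placements += _steady_rows(range(5, stop + 1), foot, 0.24, 0.36)
    return _fixture_frame(mid, placements)


def make_multistep_fixture(mid: str, start: int = -13, stop: int = 18) -> pd.DataFrame:
    """Noiseless staircase maneuver needing three steps to reach the new path."""

    def foot(i: int) -> str:
        return "right" if i % 2 == 1 else "left"

    placements = _steady_rows(range(start, 1), foot, -0.36, -0.24)
    placements += [
        (1, "right", -0.36, -0.04),  # first partial step, lands between paths
        (2, "left", -0.16, -0.04),  # second partial step, still between paths
        (3, "right", -0.16, 0.36),  # reaches the new path
        (4, "left", 0.24, 0.36),
    ]
    placements += _steady_rows(range(5, stop + 1), foot, 0.24, 0.36)
    return _fixture_frame(mid, placements)
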