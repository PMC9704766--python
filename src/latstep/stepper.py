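"""Multi-objective stepping engine.

At each step both regulators (body position z_B and step width w) run
independently on the current step variables and predict the values they
would each like realized at the next step.  Because only one foot moves
per step, each prediction implies its own placement for the moving foot
("experts"): with the stance foot fixed, realizing the predicted step
width w_pred puts a moving right foot at ``z_L + w_pred`` (left foot at
``z_R - w_pred``), and realizing the predicted position zB_pred puts it
at ``2 zB_pred - z_stance``.  The realized placement is the
rho-weighted average of the two experts — rho = 1 is pure step-width
control, rho = 0 pure position control.

Per simulated step, four standard-normal draws are consumed in a fixed
order (position regulator v_m, v_a; then width regulator v_m, v_a) so
that trajectories are bit-reproducible under a fixed seed regardless of
noise amplitudes.

:func:`simulate_ensemble` is the vectorized engine (all simulations
advance in lock-step over numpy arrays); :func:`simulate_walk` is the
single-trajectory wrapper emitting :class:`StepRecord` rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .geometry import (
    FootPlacementPair,
    GoalError,
    StepGoal,
    StepVariables,
    feet_to_step_vars,
    goal_errors,
)
from .maneuver import ManeuverSchedule
from .regulator import NoiseDraw, RegulatorParams, control_gain, update

__all__ = [
    "MixtureParams",
    "WalkerState",
    "StepRecord",
    "expert_placements",
    "mix_placement",
    "take_step",
    "simulate_walk",
    "simulate_ensemble",
    "EnsembleResult",
    "initial_state_for",
]

Foot = Literal["left", "right"]


@dataclass(frozen=True)
class MixtureParams:
    """Control proportion rho in [0, 1] weighting the step-width expert."""

    rho: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")


@dataclass(frozen=True)
class WalkerState:
    """Walker configuration between steps; ``moving_foot`` moves next."""

    step_index: int
    z_L: float
    z_R: float
    moving_foot: Foot

    @property
    def step_vars(self) -> StepVariables:
        return feet_to_step_vars(FootPlacementPair(self.z_L, self.z_R))


@dataclass(frozen=True)
class StepRecord:
    """One emitted step: both feet, derived variables, goal and errors."""

    maneuver_id: str
    step_index: int
    moving_foot: Foot
    z_L: float
    z_R: float
    z_B: float
    w: float
    goal: StepGoal
    errors: GoalError


def expert_placements(state: WalkerState, zB_pred: float, w_pred: float) -> tuple[float, float]:
    """Moving-foot placements implied by each regulator's prediction.

    Returns ``(width_expert, position_expert)``.  Both keep the stance
    foot fixed; the width expert realizes ``w_pred`` exactly, the
    position expert realizes ``zB_pred`` exactly.
    """
    if state.moving_foot == "right":
        return state.z_L + w_pred, 2.0 * zB_pred - state.z_L
    return state.z_R - w_pred, 2.0 * zB_pred - state.z_R


def mix_placement(experts: tuple[float, float], mix: MixtureParams) -> float:
    """rho-weighted average: rho * width expert + (1 - rho) * position expert."""
    width_expert, position_expert = experts
    return mix.rho * width_expert + (1.0 - mix.rho) * position_expert


def take_step(
    state: WalkerState,
    goal: StepGoal,
    reg_zB: RegulatorParams,
    reg_w: RegulatorParams,
    mix: MixtureParams,
    noise_zB: NoiseDraw = NoiseDraw(0.0, 0.0),
    noise_w: NoiseDraw = NoiseDraw(0.0, 0.0),
) -> WalkerState:
    """Advance the walker one step toward ``goal``.

    Runs both regulators on the current step variables (their stored
    goals are overridden by ``goal``), mixes the implied placements, and
    moves the moving foot there; the stance foot is unchanged.
    """
    sv = state.step_vars
    zB_pred = update(sv.z_B, reg_zB.with_goal(goal.z_B_star), noise_zB)
    w_pred = update(sv.w, reg_w.with_goal(goal.w_star), noise_w)
    placement = mix_placement(expert_placements(state, zB_pred, w_pred), mix)
    if state.moving_foot == "right":
        z_L, z_R = state.z_L, placement
    else:
        z_L, z_R = placement, state.z_R
    return WalkerState(
        step_index=state.step_index + 1,
        z_L=z_L,
        z_R=z_R,
        moving_foot="left" if state.moving_foot == "right" else "right",
    )


def initial_state_for(schedule: ManeuverSchedule, start_index: int) -> WalkerState:
    """Walker at the goal fixed point of ``schedule`` just before ``start_index``.

    Feet sit at the placement goals of the entry at ``start_index - 1``;
    the moving foot is chosen so that foot alternation matches the
    schedule's anchor (e.g. a right-foot transition step).
    """
    goal = schedule.entry(start_index - 1).goal
    z_L = goal.z_B_star - 0.5 * goal.w_star
    z_R = goal.z_B_star + 0.5 * goal.w_star
    return WalkerState(
        step_index=start_index - 1,
        z_L=z_L,
        z_R=z_R,
        moving_foot=schedule.moving_foot(start_index),
    )


@dataclass
class EnsembleResult:
    """Vectorized simulation output: arrays of shape (n_sims, n_steps)."""

    step_indices: np.ndarray  # (n_steps,)
    z_L: np.ndarray
    z_R: np.ndarray
    moving_foot: list  # per step: "left" | "right"
    schedule: ManeuverSchedule = field(repr=False)

    @property
    def z_B(self) -> np.ndarray:
        return 0.5 * (self.z_L + self.z_R)

    @property
    def w(self) -> np.ndarray:
        return self.z_R - self.z_L

    def errors(self) -> tuple[np.ndarray, np.ndarray]:
        """(F_zB, F_w) relative to the schedule goal at each step index."""
        goals = np.array(
            [
                (self.schedule.entry(int(i)).goal.z_B_star, self.schedule.entry(int(i)).goal.w_star)
                for i in self.step_indices
            ]
        )
        return self.z_B - goals[:, 0], self.w - goals[:, 1]


def simulate_ensemble(
    schedule: ManeuverSchedule,
    n_sims: int,
    reg_zB: RegulatorParams,
    reg_w: RegulatorParams,
    rng: np.random.Generator | int,
    start_index: int | None = None,
    stop_index: int | None = None,
    initial: WalkerState | None = None,
) -> EnsembleResult:
    """Run ``n_sims`` independent walkers over the schedule's index range.

    Steps are taken for indices ``start_index .. stop_index`` inclusive
    (defaulting to the schedule's stored range).  Per step the goal, rho
    and additive-noise multiplier come from the schedule entry at the
    *destination* index; the multiplier scales sigma_a only, not sigma_m.
    """
    if start_index is None:
        start_index = schedule.min_index
    if stop_index is None:
        stop_index = schedule.max_index
    if stop_index < start_index:
        raise ValueError("stop_index must be >= start_index")
    rng = np.random.default_rng(rng)

    if initial is None:
        initial = initial_state_for(schedule, start_index)
    z_L = np.full(n_sims, float(initial.z_L))
    z_R = np.full(n_sims, float(initial.z_R))

    k_zB = control_gain(reg_zB)
    k_w = control_gain(reg_w)

    indices = np.arange(start_index, stop_index + 1)
    out_L = np.empty((n_sims, indices.size))
    out_R = np.empty((n_sims, indices.size))
    feet: list[str] = []

    foot = initial.moving_foot
    for j, idx in enumerate(indices):
        e = schedule.entry(int(idx))
        mult = e.sigma_a_multiplier
        # fixed draw order: position (v_m, v_a) then width (v_m, v_a)
        v = rng.standard_normal((4, n_sims))
        zB = 0.5 * (z_L + z_R)
        w = z_R - z_L
        u_zB = -k_zB * (zB - e.goal.z_B_star)
        u_w = -k_w * (w - e.goal.w_star)
        zB_pred = zB + reg_zB.g * (1.0 + reg_zB.sigma_m * v[0]) * u_zB + mult * reg_zB.sigma_a * v[1]
        w_pred = w + reg_w.g * (1.0 + reg_w.sigma_m * v[2]) * u_w + mult * reg_w.sigma_a * v[3]
        if foot == "right":
            width_expert = z_L + w_pred
            position_expert = 2.0 * zB_pred - z_L
            z_R = e.rho * width_expert + (1.0 - e.rho) * position_expert
        else:
            width_expert = z_R - w_pred
            position_expert = 2.0 * zB_pred - z_R
            z_L = e.rho * width_expert + (1.0 - e.rho) * position_expert
        out_L[:, j] = z_L
        out_R[:, j] = z_R
        feet.append(foot)
        foot = "left" if foot == "right" else "right"

    return EnsembleResult(step_indices=indices, z_L=out_L, z_R=out_R, moving_foot=feet, schedule=schedule)


def simulate_walk(
    initial: WalkerState | None,
    schedule: ManeuverSchedule,
    n_steps: int,
    seed: int | np.random.Generator,
    reg_zB: RegulatorParams | None = None,
    reg_w: RegulatorParams | None = None,
    maneuver_id: str = "sim",
    start_index: int | None = None,
) -> list[StepRecord]:
    """Simulate one walker for ``n_steps`` steps and return its records.

    The first step lands on index ``start_index`` (default: the
    schedule's first stored index, or ``initial.step_index + 1`` when an
    explicit initial state is given).  Regulator parameter defaults are
    the steady-state model constants.
    """
    from .regulator import default_position_params, default_width_params

    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if reg_zB is None:
        reg_zB = default_position_params()
    if reg_w is None:
        reg_w = default_width_params()
    if start_index is None:
        start_index = initial.step_index + 1 if initial is not None else schedule.min_index
    res = simulate_ensemble(
        schedule,
        n_sims=1,
        reg_zB=reg_zB,
        reg_w=reg_w,
        rng=seed,
        start_index=start_index,
        stop_index=start_index + n_steps - 1,
        initial=initial,
    )
    records = []
    for j, idx in enumerate(res.step_indices):
        z_L, z_R = float(res.z_L[0, j]), float(res.z_R[0, j])
        sv = feet_to_step_vars(FootPlacementPair(z_L, z_R))
        goal = schedule.entry(int(idx)).goal
        records.append(
            StepRecord(
                maneuver_id=maneuver_id,
                step_index=int(idx),
                moving_foot=res.moving_foot[j],  # type: ignore[arg-type]
                z_L=z_L,
                z_R=z_R,
                z_B=sv.z_B,
                w=sv.w,
                goal=goal,
                errors=goal_errors(sv, goal),
            )
        )
    return records
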