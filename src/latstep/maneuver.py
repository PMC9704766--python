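"""Maneuver goal algebra and per-step parameter schedules.

A lateral maneuver is a commanded change of the stepping goals
``(z_B*, w*)``.  Because one step moves only one foot, no maneuver with
a nonzero goal change can be completed in a single step: at least one
*intermediate* step is required, whose own stepping goals follow in
closed form from the initial goals and the commanded change
(:func:`intermediate_goals`).

The empirically typical lane change is a four-step strategy —
preparatory, transition, recovery, arrival — idealized here by a single
foot-placement offset ``epsilon``: the preparatory step narrows the
stance by moving the trailing foot medially by ``epsilon``, the
transition step is a large ipsilateral crossing step, and the recovery
step mirrors the preparation on the new path
(:func:`four_step_schedule`).

A :class:`ManeuverSchedule` maps step index -> (goal, rho,
sigma_a multiplier) with constant extension beyond its ends, where
``rho`` is the control proportion mixing step-width (rho) and
body-position (1 - rho) foot-placement experts and the multiplier
scales the additive noise at that step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Mapping

from .geometry import (
    FootPlacementPair,
    StepGoal,
    StepVariables,
    feet_to_step_vars,
    step_vars_to_feet,
)

__all__ = [
    "GoalChange",
    "FourStepConfig",
    "ScheduleEntry",
    "ManeuverSchedule",
    "intermediate_goals",
    "verify_two_step_completion",
    "minimum_steps",
    "four_step_schedule",
    "mirror_schedule",
    "steady_schedule",
]

Foot = Literal["left", "right"]


@dataclass(frozen=True)
class GoalChange:
    """Commanded increments (delta z_B*, delta w*) of the stepping goals."""

    delta_zB_star: float
    delta_w_star: float


@dataclass(frozen=True)
class FourStepConfig:
    """Configuration of the idealized four-step lane-change strategy.

    ``epsilon`` is the medial foot-placement offset (meters) applied at
    the preparatory and recovery steps.  Its default, 0.25 * w_i*, is a
    package choice of plausible magnitude (experimentally it would be
    estimated by averaging preparatory/recovery foot-placement offsets;
    see :func:`latstep.dataio.estimate_epsilon`).
    """

    initial: StepGoal
    final: StepGoal
    epsilon: float | None = None
    direction: Literal["left_to_right", "right_to_left"] = "left_to_right"

    def resolved_epsilon(self) -> float:
        eps = 0.25 * self.initial.w_star if self.epsilon is None else self.epsilon
        if eps < 0:
            raise ValueError("epsilon must be non-negative")
        return eps


@dataclass(frozen=True)
class ScheduleEntry:
    goal: StepGoal
    rho: float
    sigma_a_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if not self.sigma_a_multiplier > 0:
            raise ValueError("sigma_a_multiplier must be > 0")


@dataclass(frozen=True)
class ManeuverSchedule:
    """Per-step-index goals and regulator modulation for one maneuver.

    ``anchor_index``/``anchor_foot`` fix which foot moves at which index
    (feet alternate); labels name the special steps.  Indices outside
    the stored range take the nearest stored entry (constant extension).
    """

    entries: Mapping[int, ScheduleEntry]
    labels: Mapping[str, int] = field(default_factory=dict)
    anchor_index: int = 1
    anchor_foot: Foot = "right"
    warning: str | None = None

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("schedule must contain at least one entry")
        object.__setattr__(self, "entries", dict(sorted(self.entries.items())))
        object.__setattr__(self, "labels", dict(self.labels))

    @property
    def min_index(self) -> int:
        return next(iter(self.entries))

    @property
    def max_index(self) -> int:
        return next(reversed(self.entries))

    def entry(self, index: int) -> ScheduleEntry:
        """Entry at ``index``, clamped to the stored range at the ends."""
        idx = min(max(index, self.min_index), self.max_index)
        if idx in self.entries:
            return self.entries[idx]
        # gap inside the range: hold the previous entry
        prev = max(i for i in self.entries if i <= idx)
        return self.entries[prev]

    def moving_foot(self, index: int) -> Foot:
        """Foot that moves at step ``index`` (feet alternate every step)."""
        same = (index - self.anchor_index) % 2 == 0
        if same:
            return self.anchor_foot
        return "left" if self.anchor_foot == "right" else "right"

    def indices(self) -> Iterator[int]:
        return iter(self.entries)

    def to_dict(self) -> dict:
        """Plain-dict form for YAML/JSON round trips."""
        return {
            "anchor_index": self.anchor_index,
            "anchor_foot": self.anchor_foot,
            "labels": dict(self.labels),
            "warning": self.warning,
            "entries": [
                {
                    "step_index": i,
                    "z_B_star": e.goal.z_B_star,
                    "w_star": e.goal.w_star,
                    "rho": e.rho,
                    "sigma_a_multiplier": e.sigma_a_multiplier,
                }
                for i, e in self.entries.items()
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ManeuverSchedule":
        entries = {
            int(r["step_index"]): ScheduleEntry(
                goal=StepGoal(float(r["z_B_star"]), float(r["w_star"])),
                rho=float(r["rho"]),
                sigma_a_multiplier=float(r.get("sigma_a_multiplier", 1.0)),
            )
            for r in d["entries"]
        }
        return cls(
            entries=entries,
            labels={str(k): int(v) for k, v in dict(d.get("labels", {})).items()},
            anchor_index=int(d.get("anchor_index", 1)),
            anchor_foot=d.get("anchor_foot", "right"),
            warning=d.get("warning"),
        )


def steady_schedule(goal: StepGoal, rho: float = 0.9) -> ManeuverSchedule:
    """Constant schedule for steady-state walking on one path."""
    return ManeuverSchedule(entries={0: ScheduleEntry(goal=goal, rho=rho)}, anchor_index=1)


def intermediate_goals(
    initial: StepGoal, change: GoalChange, intermediate_foot: Foot
) -> StepGoal:
    """Stepping goals of the single intermediate step of a two-step maneuver.

    The intermediate foot lands at its *final* placement goal while the
    stance foot stays at its *initial* placement goal; transforming that
    mixed configuration into task coordinates gives, for a right-foot
    intermediate step,

        z_B*^a = z_Bi* + delta_zB/2 + delta_w/4
        w*^a   = w_i*  + delta_zB   + delta_w/2

    and the left-foot mirror flips the signs of the cross terms.
    """
    dz, dw = change.delta_zB_star, change.delta_w_star
    if intermediate_foot == "right":
        return StepGoal(
            z_B_star=initial.z_B_star + 0.5 * dz + 0.25 * dw,
            w_star=initial.w_star + dz + 0.5 * dw,
        )
    if intermediate_foot == "left":
        return StepGoal(
            z_B_star=initial.z_B_star + 0.5 * dz - 0.25 * dw,
            w_star=initial.w_star - dz + 0.5 * dw,
        )
    raise ValueError(f"intermediate_foot must be 'left' or 'right', got {intermediate_foot!r}")


def verify_two_step_completion(
    initial: StepGoal, change: GoalChange, intermediate_foot: Foot, tol: float = 1e-12
) -> bool:
    """Check, by direct construction in the foot-placement plane, that the
    two-step strategy realizes the maneuver and its closed-form
    intermediate goals.

    Places the intermediate foot at its final placement goal (stance foot
    at its initial placement goal), transforms through the coordinate
    map, and compares with :func:`intermediate_goals`; then moves the
    remaining foot and compares with the final goal.
    """
    final = StepGoal(
        initial.z_B_star + change.delta_zB_star, initial.w_star + change.delta_w_star
    )
    feet_i = step_vars_to_feet(StepVariables(*initial))
    feet_f = step_vars_to_feet(StepVariables(*final))
    if intermediate_foot == "right":
        feet_mid = FootPlacementPair(z_L=feet_i.z_L, z_R=feet_f.z_R)
    else:
        feet_mid = FootPlacementPair(z_L=feet_f.z_L, z_R=feet_i.z_R)
    mid = feet_to_step_vars(feet_mid)
    expected = intermediate_goals(initial, change, intermediate_foot)
    ok_mid = abs(mid.z_B - expected.z_B_star) < tol and abs(mid.w - expected.w_star) < tol
    after = feet_to_step_vars(feet_f)
    ok_final = abs(after.z_B - final.z_B_star) < tol and abs(after.w - final.w_star) < tol
    return ok_mid and ok_final


def minimum_steps(initial: StepGoal, change: GoalChange, tol: float = 1e-12) -> int:
    """Minimum number of steps needed to realize a goal change exactly.

    Counts the feet whose placement goal moves.  Generic changes move
    both feet (2 steps); on the degenerate lines delta_zB = +-delta_w/2
    one foot's goal is unchanged and a single step suffices; the null
    change needs none.
    """
    final = StepGoal(
        initial.z_B_star + change.delta_zB_star, initial.w_star + change.delta_w_star
    )
    feet_i = step_vars_to_feet(StepVariables(*initial))
    feet_f = step_vars_to_feet(StepVariables(*final))
    moved_L = abs(feet_f.z_L - feet_i.z_L) > tol
    moved_R = abs(feet_f.z_R - feet_i.z_R) > tol
    return int(moved_L) + int(moved_R)


def four_step_schedule(
    cfg: FourStepConfig,
    rho_steady: float = 0.9,
    rho_prep: float = 0.7,
    rho_trans: float = 0.5,
    sigma_mult_prep: float = 2.0,
    sigma_mult_trans: float = 2.0,
) -> ManeuverSchedule:
    """Adaptive schedule for the idealized four-step lane change.

    Step indices: 0 = preparatory (trailing foot in by epsilon), 1 =
    transition (large ipsilateral crossing step), 2 = recovery, 3 =
    arrival at the final goals; steady-state entries flank the maneuver.
    Defaults implement the stability-maneuverability trade-off: rho 0.9
    at steady state, 0.7 at preparatory/recovery, 0.5 (equal weighting)
    at the transition; additive noise doubled at the preparatory and
    transition steps.
    """
    if cfg.direction == "right_to_left":
        mirrored_cfg = replace(
            cfg,
            initial=StepGoal(-cfg.initial.z_B_star, cfg.initial.w_star),
            final=StepGoal(-cfg.final.z_B_star, cfg.final.w_star),
            direction="left_to_right",
        )
        return mirror_schedule(
            four_step_schedule(
                mirrored_cfg, rho_steady, rho_prep, rho_trans, sigma_mult_prep, sigma_mult_trans
            )
        )

    eps = cfg.resolved_epsilon()
    if not (cfg.initial.w_star > 0 and cfg.final.w_star > 0):
        raise ValueError("initial and final w* must be positive")

    feet_i = step_vars_to_feet(StepVariables(*cfg.initial))
    feet_f = step_vars_to_feet(StepVariables(*cfg.final))
    # preparatory: left (trailing) foot moves medially by +epsilon
    prep = feet_to_step_vars(FootPlacementPair(feet_i.z_L + eps, feet_i.z_R))
    # recovery: configuration [z_Lf*, z_Rf* - eps] on the new path
    recov = feet_to_step_vars(FootPlacementPair(feet_f.z_L, feet_f.z_R - eps))
    prep_goal = StepGoal(*prep)
    recov_goal = StepGoal(*recov)
    trans_goal = intermediate_goals(
        prep_goal,
        GoalChange(recov_goal.z_B_star - prep_goal.z_B_star, recov_goal.w_star - prep_goal.w_star),
        intermediate_foot="right",
    )

    warning = None
    if prep_goal.w_star <= 0 or recov_goal.w_star <= 0:
        warning = f"epsilon={eps} produces non-positive preparatory/recovery step width"

    entries = {
        -1: ScheduleEntry(cfg.initial, rho=rho_steady),
        0: ScheduleEntry(prep_goal, rho=rho_prep, sigma_a_multiplier=sigma_mult_prep),
        1: ScheduleEntry(trans_goal, rho=rho_trans, sigma_a_multiplier=sigma_mult_trans),
        2: ScheduleEntry(recov_goal, rho=rho_prep),
        3: ScheduleEntry(cfg.final, rho=rho_steady),
    }
    labels = {"preparatory": 0, "transition": 1, "recovery": 2, "arrival": 3}
    return ManeuverSchedule(
        entries=entries, labels=labels, anchor_index=1, anchor_foot="right", warning=warning
    )


def mirror_schedule(s: ManeuverSchedule) -> ManeuverSchedule:
    """Left/right mirror image: z_B* negated, w* kept, feet swapped.

    An involution; rho values and noise multipliers are preserved.
    """
    entries = {
        i: replace(e, goal=StepGoal(-e.goal.z_B_star, e.goal.w_star))
        for i, e in s.entries.items()
    }
    return ManeuverSchedule(
        entries=entries,
        labels=dict(s.labels),
        anchor_index=s.anchor_index,
        anchor_foot="left" if s.anchor_foot == "right" else "right",
        warning=s.warning,
    )
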