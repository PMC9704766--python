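"""Coordinate geometry of lateral stepping.

Lateral stepping is described in two equivalent coordinate frames: the
foot-placement plane ``[z_L, z_R]`` (lateral positions of the left and
right feet, meters, z increasing to the walker's right) and the task
plane ``[z_B, w]`` where ``z_B = (z_L + z_R)/2`` is the lateral body
position (midpoint of the feet, a once-per-step proxy for the lateral
center of mass) and ``w = z_R - z_L`` is the step width.

Goals to hold ``z_B`` or ``w`` constant each define a line in the
``[z_L, z_R]`` plane — a Goal Equivalent Manifold (GEM): every point on
the line satisfies that goal exactly.  The two GEMs are mutually
orthogonal diagonals; their intersection is the unique foot-placement
pair realizing both goals.

All quantities are in meters; the origin is arbitrary and every
operation is translation covariant.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

__all__ = [
    "FootPlacementPair",
    "StepVariables",
    "StepGoal",
    "GoalError",
    "feet_to_step_vars",
    "step_vars_to_feet",
    "goal_errors",
    "gem_directions",
]


class FootPlacementPair(NamedTuple):
    """Lateral positions of the two feet at a step, meters."""

    z_L: float
    z_R: float


class StepVariables(NamedTuple):
    """Task-plane coordinates of a step: body position and step width.

    ``w`` may be negative for crossover configurations (left foot to the
    right of the right foot).
    """

    z_B: float
    w: float


class StepGoal(NamedTuple):
    """Target pair ``(z_B*, w*)`` defining perfect task performance."""

    z_B_star: float
    w_star: float


class GoalError(NamedTuple):
    """Signed goal-function values ``F = actual - goal`` for one step."""

    F_zB: float
    F_w: float


def _require_finite(*values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"non-finite coordinate: {v!r}")


def feet_to_step_vars(feet: FootPlacementPair) -> StepVariables:
    """Map foot placements to step variables: z_B = (z_L+z_R)/2, w = z_R-z_L."""
    z_L, z_R = feet
    _require_finite(z_L, z_R)
    return StepVariables(z_B=0.5 * (z_L + z_R), w=z_R - z_L)


def step_vars_to_feet(sv: StepVariables) -> FootPlacementPair:
    """Exact inverse of :func:`feet_to_step_vars`."""
    z_B, w = sv
    _require_finite(z_B, w)
    return FootPlacementPair(z_L=z_B - 0.5 * w, z_R=z_B + 0.5 * w)


def goal_errors(sv: StepVariables, goal: StepGoal) -> GoalError:
    """Goal-function errors F_zB = z_B - z_B*, F_w = w - w*."""
    _require_finite(*sv, *goal)
    return GoalError(F_zB=sv.z_B - goal.z_B_star, F_w=sv.w - goal.w_star)


def gem_directions() -> tuple[np.ndarray, np.ndarray]:
    """Unit tangents of the two GEMs in the ``[z_L, z_R]`` plane.

    Returns ``(t_w, t_zB)``: the constant-``w*`` GEM tangent
    ``(1, 1)/sqrt(2)`` (moving both feet together changes z_B, not w) and
    the constant-``z_B*`` GEM tangent ``(1, -1)/sqrt(2)``.
    """
    s = 1.0 / math.sqrt(2.0)
    return np.array([s, s]), np.array([s, -s])
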