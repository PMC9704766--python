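"""Single-variable stochastic optimal error regulator.

Each regulated stepping variable ``q`` (lateral body position z_B or
step width w) is driven toward its goal ``q*`` by a lag-1
error-correcting update,

    q_{n+1} = q_n + g (1 + sigma_m v_m) u(q_n) + sigma_a v_a,

where ``v_m, v_a ~ N(0, 1)`` i.i.d., ``sigma_a`` is additive
(perceptual/motor) noise in meters, ``sigma_m`` is dimensionless
multiplicative noise on the control input, and ``g`` is an overall gain.
The control input minimizing the expected one-step quadratic cost

    C = alpha * e_{n+1}^2 + gamma * u^2

(error weight ``alpha``, effort weight ``gamma``) is direct error
feedback,

    u(q) = -k (q - q*),    k = 1 / (1 + sigma_m^2 + gamma/alpha).

Defaults follow the steady-state walking model: gamma/alpha = 0.10,
sigma_m = 0.1 * sigma_a, g = 1.  The default additive noise amplitudes
(0.02 m for step width, 0.01 m for body position) are plausible
steady-state stepping SDs for treadmill walking, not published values,
and should be overridden when experimental SDs are available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

__all__ = [
    "RegulatorParams",
    "NoiseDraw",
    "control_gain",
    "control_input",
    "update",
    "step_cost",
    "default_width_params",
    "default_position_params",
]

#: Default additive noise, meters (step width / body position). Plausible
#: steady-state SDs; config-overridable, not experimentally fitted here.
DEFAULT_SIGMA_A_W = 0.02
DEFAULT_SIGMA_A_ZB = 0.01


class NoiseDraw(NamedTuple):
    """One step's standard-normal draws: multiplicative then additive."""

    v_m: float
    v_a: float


ZERO_NOISE = NoiseDraw(0.0, 0.0)


@dataclass(frozen=True)
class RegulatorParams:
    """Constants of one scalar regulator.

    Parameters
    ----------
    q_star : float
        Goal value of the regulated variable, meters.
    alpha : float
        Error weight in the cost, > 0.
    gamma : float
        Effort weight in the cost, >= 0.
    sigma_a : float
        Additive noise SD, meters, >= 0.
    sigma_m : float
        Multiplicative noise amplitude (dimensionless), >= 0.  Enters
        both the noise term and the optimal gain.
    g : float
        Overall control gain; 1 leaves the optimal gain untouched.
    """

    q_star: float
    alpha: float = 1.0
    gamma: float = 0.1
    sigma_a: float = 0.0
    sigma_m: float = 0.0
    g: float = 1.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.gamma < 0 or self.sigma_a < 0 or self.sigma_m < 0:
            raise ValueError("gamma, sigma_a, sigma_m must be non-negative")

    def with_goal(self, q_star: float) -> "RegulatorParams":
        return replace(self, q_star=q_star)


def default_width_params(w_star: float = 0.12, sigma_a: float = DEFAULT_SIGMA_A_W) -> RegulatorParams:
    """Step-width regulator with steady-state defaults (gamma/alpha = 0.10)."""
    return RegulatorParams(q_star=w_star, sigma_a=sigma_a, sigma_m=0.1 * sigma_a)


def default_position_params(z_B_star: float = 0.0, sigma_a: float = DEFAULT_SIGMA_A_ZB) -> RegulatorParams:
    """Body-position regulator with steady-state defaults."""
    return RegulatorParams(q_star=z_B_star, sigma_a=sigma_a, sigma_m=0.1 * sigma_a)


def control_gain(params: RegulatorParams) -> float:
    """Optimal feedback gain k = 1/(1 + sigma_m^2 + gamma/alpha), in (0, 1]."""
    return 1.0 / (1.0 + params.sigma_m**2 + params.gamma / params.alpha)


def control_input(q: float, params: RegulatorParams) -> float:
    """Direct error feedback u = -k (q - q*)."""
    return -control_gain(params) * (q - params.q_star)


def update(q: float, params: RegulatorParams, noise: NoiseDraw = ZERO_NOISE) -> float:
    """One noisy state update q' = q + g (1 + sigma_m v_m) u(q) + sigma_a v_a."""
    u = control_input(q, params)
    return q + params.g * (1.0 + params.sigma_m * noise.v_m) * u + params.sigma_a * noise.v_a


def step_cost(error_next: float, u: float, params: RegulatorParams) -> float:
    """Quadratic one-step cost C = alpha e^2 + gamma u^2."""
    return params.alpha * error_next**2 + params.gamma * u**2


def stationary_sd(params: RegulatorParams) -> float:
    """Stationary SD of the sigma_m = 0, g = 1 map: sigma_a / sqrt(1-(1-k)^2).

    Closed form for the lag-1 linear map q' = q - k(q - q*) + sigma_a v_a.
    Used as an analytic cross-check of simulated steady-state variability.
    """
    k = control_gain(params)
    import math

    return params.sigma_a / math.sqrt(1.0 - (1.0 - k) ** 2)
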