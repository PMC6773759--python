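"""Discrete-time correlated random walk shared by all agents.

Every cell advances once per simulation minute by a step of random width
(Rayleigh with mean ``v``) in a direction obtained by turning the
previous heading by a random angle.  The turning-angle magnitude is
drawn uniformly from persistence-dependent bounds and applied with a
sign ``s ∈ {−1, +1}`` (−1 = right/clockwise, drawn with probability
``q_R`` unless a chemotactic controller overrides it).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AgentState",
    "WalkParams",
    "draw_step_width",
    "turning_bounds",
    "draw_turn_magnitude",
    "advance",
]

#: Rayleigh scale that yields a mean step width of v: sigma = v * sqrt(2/pi)
RAYLEIGH_SCALE = float(np.sqrt(2.0 / np.pi))


def _wrap_angle(phi: float) -> float:
    return float(np.mod(phi + np.pi, 2.0 * np.pi) - np.pi)


@dataclass(frozen=True)
class AgentState:
    """Position and heading of one cell (immune or target).

    ``position`` is folded into ``[0, L_sys)²``; ``unwrapped_position``
    accumulates the same displacements without folding, for mean squared
    displacement analysis.  ``alive`` is meaningful for targets only.
    """

    position: np.ndarray
    heading: float
    unwrapped_position: np.ndarray
    alive: bool = True

    @classmethod
    def create(cls, position, heading: float, alive: bool = True) -> "AgentState":
        pos = np.asarray(position, dtype=float)
        return cls(
            position=pos.copy(),
            heading=_wrap_angle(heading),
            unwrapped_position=pos.copy(),
            alive=alive,
        )


@dataclass(frozen=True)
class WalkParams:
    """Speed v (μm/min), persistence ε ∈ [−1, 1], right-turn probability q_R."""

    v: float
    eps: float
    q_R: float = 0.5

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("speed v must be non-negative")
        if not -1.0 <= self.eps <= 1.0:
            raise ValueError("persistence eps must lie in [-1, 1]")
        if not 0.0 <= self.q_R <= 1.0:
            raise ValueError("q_R must be a probability")


def draw_step_width(v, rng: np.random.Generator, size=None):
    """Rayleigh step width with mean ``v`` (scale ``v * sqrt(2/pi)``).

    ``v`` may be an array (broadcast against ``size``); ``v = 0`` yields
    zero-width steps.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("speed v must be non-negative")
    return rng.rayleigh(scale=v * RAYLEIGH_SCALE, size=size)


def turning_bounds(eps: float) -> tuple[float, float]:
    """Uniform turning-angle bounds (Δϕ_min, Δϕ_max) for persistence ε.

    ε ≥ 0 gives symmetric bounds ±(1−ε)π (ε = 1 ballistic, ε = 0
    isotropic); ε < 0 gives ((1−|ε|)π, (1+|ε|)π), i.e. turns centered on
    a reversal.
    """
    if not -1.0 <= eps <= 1.0:
        raise ValueError("persistence eps must lie in [-1, 1]")
    if eps >= 0:
        half = (1.0 - eps) * np.pi
        return (-half, half)
    a = abs(eps)
    return ((1.0 - a) * np.pi, (1.0 + a) * np.pi)


def draw_turn_magnitude(eps, rng: np.random.Generator, size=None):
    """|Δϕ| drawn uniformly from the persistence bounds, vectorized over ε.

    Only the magnitude enters the position update; the sign is supplied
    separately.
    """
    eps = np.asarray(eps, dtype=float)
    if np.any(np.abs(eps) > 1.0):
        raise ValueError("persistence eps must lie in [-1, 1]")
    lo = np.where(eps >= 0, -(1.0 - eps) * np.pi, (1.0 - np.abs(eps)) * np.pi)
    hi = np.where(eps >= 0, (1.0 - eps) * np.pi, (1.0 + np.abs(eps)) * np.pi)
    return np.abs(rng.uniform(lo, hi, size=size))


def advance(
    state: AgentState,
    params: WalkParams,
    rng: np.random.Generator,
    L_sys: float,
    sign_override: int | None = None,
) -> AgentState:
    """One walk step: draw width and |turn|, apply the turn sign, move.

    The sign is ``sign_override`` when a chemotactic controller supplies
    it; otherwise −1 (right) with probability ``q_R`` and +1 (left)
    otherwise.  Both the folded and the unwrapped position advance by
    the same displacement; the new heading is returned with the state.
    """
    w = float(draw_step_width(params.v, rng))
    dphi = float(draw_turn_magnitude(params.eps, rng))
    if sign_override is not None:
        s = int(sign_override)
        if s not in (-1, 1):
            raise ValueError("sign_override must be -1 or +1")
    else:
        s = -1 if rng.random() < params.q_R else 1
    phi = state.heading + s * dphi
    disp = w * np.array([np.cos(phi), np.sin(phi)])
    return replace(
        state,
        position=np.mod(state.position + disp, L_sys),
        unwrapped_position=state.unwrapped_position + disp,
        heading=_wrap_angle(phi),
    )
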