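"""Chemotactic sensors and logistic stimulus-response functions.

The immune cell carries a central sensor (temporal gradient sensing:
the difference Δρ^C between the local attractant density now and one
step ago) and two lateral sensors on its left and right border (spatial
gradient sensing: the right-minus-left difference Δρ^LR).  Two logistic
response functions map these signals to behavior, fresh at every step:

* mode choice — approach mode with probability
  ``logistic(c_A0 + c_A1 · Δρ^C)``, otherwise normal mode; each mode has
  its own speed and persistence;
* turn sign — right turn (s = −1) with probability
  ``logistic(c_R1 · Δρ^LR)``.

Positive sensitivities are attractive: rising concentration favors the
approach mode, and a denser right side favors a right turn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attractant import FieldContext, field_at

__all__ = [
    "StrategyParams",
    "SensorState",
    "logistic",
    "temporal_difference",
    "lateral_sensor_positions",
    "spatial_difference",
    "choose_mode",
    "choose_turn_sign",
]


@dataclass(frozen=True)
class StrategyParams:
    """The 7 tunable immune-cell parameters.

    v_N, ε_N and v_A, ε_A are the speed (μm/min) and persistence of the
    normal and approach migration modes; c_A0 is the mode bias, c_A1 the
    temporal and c_R1 the spatial sensitivity.  Speeds are restricted to
    [0, 6] μm/min and persistences to [0, 1]; the sensitivities are
    dimensionless per density unit.  c_A0 is nominally in [−5, 5] but an
    out-of-range value such as 500 is accepted as an "always approach"
    override.
    """

    v_N: float
    eps_N: float
    v_A: float
    eps_A: float
    c_A0: float
    c_A1: float
    c_R1: float

    def __post_init__(self) -> None:
        for name, v in (("v_N", self.v_N), ("v_A", self.v_A)):
            if not 0.0 <= v <= 6.0:
                raise ValueError(f"{name} must lie in [0, 6] μm/min, got {v}")
        for name, e in (("eps_N", self.eps_N), ("eps_A", self.eps_A)):
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {e}")

    def as_dict(self) -> dict[str, float]:
        return {
            "v_N": self.v_N,
            "eps_N": self.eps_N,
            "v_A": self.v_A,
            "eps_A": self.eps_A,
            "c_A0": self.c_A0,
            "c_A1": self.c_A1,
            "c_R1": self.c_R1,
        }


@dataclass
class SensorState:
    """Memory of the central sensor: the previous density reading.

    Before the first reading the temporal difference is defined as 0, so
    the initial mode prior is ``logistic(c_A0)``.
    """

    rho_prev: float = 0.0
    initialized: bool = False


def logistic(x):
    """1 / (1 + exp(−x)), numerically stable for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def temporal_difference(sensor: SensorState, rho_now: float) -> float:
    """Δρ^C = ρ_now − ρ_prev; 0 on the first call.  Updates the memory."""
    if rho_now < 0:
        raise ValueError("density must be non-negative")
    if sensor.initialized:
        delta = rho_now - sensor.rho_prev
    else:
        delta = 0.0
        sensor.initialized = True
    sensor.rho_prev = rho_now
    return delta


def lateral_sensor_positions(center, heading: float, r_imm: float):
    """Left and right sensor points on the cell border, perpendicular to
    the heading of the previous step."""
    if r_imm <= 0:
        raise ValueError("r_imm must be positive")
    center = np.asarray(center, dtype=float)
    left = center + r_imm * np.array(
        [np.cos(heading + np.pi / 2), np.sin(heading + np.pi / 2)]
    )
    right = center + r_imm * np.array(
        [np.cos(heading - np.pi / 2), np.sin(heading - np.pi / 2)]
    )
    return left, right


def spatial_difference(ctx: FieldContext, left, right) -> float:
    """Δρ^LR = ρ^R − ρ^L: total density at the right sensor minus left."""
    return field_at(ctx, right) - field_at(ctx, left)


def choose_mode(params: StrategyParams, delta_rho_c: float, rng: np.random.Generator) -> str:
    """Draw the migration mode for this step: 'A' with probability
    ``logistic(c_A0 + c_A1 Δρ^C)``, else 'N'.  Memoryless across steps."""
    q_A = logistic(params.c_A0 + params.c_A1 * delta_rho_c)
    return "A" if rng.random() < q_A else "N"


def choose_turn_sign(params: StrategyParams, delta_rho_lr: float, rng: np.random.Generator) -> int:
    """Draw the turn sign: −1 (right) with probability
    ``logistic(c_R1 Δρ^LR)``, else +1 (left)."""
    q_R = logistic(params.c_R1 * delta_rho_lr)
    return -1 if rng.random() < q_R else 1
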