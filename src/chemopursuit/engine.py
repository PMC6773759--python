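"""Pursuit simulation: one immune cell hunting emitting targets.

A run places a single immune cell and ``N_tar`` target cells uniformly
on the periodic ``L_sys`` × ``L_sys`` plane and advances everything for
``T_sim`` one-minute steps.  Per step, in order:

1. all live targets take an unbiased correlated-random-walk step;
2. the immune cell reads its central sensor (on the post-move field),
   forms the temporal difference and draws its migration mode, then
   reads the lateral sensors with the heading of the previous step and
   draws its turn sign;
3. the immune cell advances with the chosen mode's speed/persistence
   and the chosen sign;
4. any live target whose center comes within ``r_imm + r_tar`` of the
   immune center is contacted and immediately removed — its attractant
   cloud vanishes with it (fast-diffusion limit).

The eliminated-target count of run ``k`` is ``Q_k``; averaging it over
many runs gives the search efficiency Q.

Two equivalent engines are provided: :func:`run_simulation` is a
readable per-agent loop that records full trajectories, and
:func:`run_batch` advances thousands of independent runs in lock-step
numpy arrays and returns only the ``Q_k`` counts.  A statistical
equivalence test ties the two together.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .attractant import AttractantKernel, FieldContext, field_at, min_image_distance, solve_kernel
from .response import (
    SensorState,
    StrategyParams,
    choose_mode,
    choose_turn_sign,
    lateral_sensor_positions,
    logistic,
    spatial_difference,
    temporal_difference,
)
from .walk import RAYLEIGH_SCALE, AgentState, WalkParams, advance

__all__ = [
    "ScenarioConfig",
    "RunResult",
    "PlacementError",
    "initialize_run",
    "detect_contacts",
    "run_simulation",
    "run_batch",
    "trajectory_frame",
]

_STANDARD_STRATEGY = StrategyParams(
    v_N=3, eps_N=0.5, v_A=3, eps_A=0.5, c_A0=-5, c_A1=0, c_R1=0
)


class PlacementError(RuntimeError):
    """Raised when non-overlapping initial placement cannot be found."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one simulation scenario.

    Defaults are the standard parameters: a 1000 μm periodic box, 1 min
    steps for 100 min, 10 emitting targets of radius 10 μm (density
    1e-5 μm⁻²), attractant diffusivity 6000 μm²/min and decay 0.6/min
    (diffusion length 100 μm), and a blind immune cell with medium
    migration parameters.

    ``ensemble`` selects the target population: ``"mixed"`` draws each
    target's speed ~ U[0, 6] and persistence ~ U[0, 1] independently per
    run (the optimization condition), ``"pure"`` gives every target the
    same ``(v_tar, eps_tar)``, and ``"static"`` pins immobile targets at
    ``static_positions``.

    ``eliminate_on_contact`` distinguishes the two observation
    protocols.  With the default ``True`` (the efficiency protocol) a
    contacted target is removed together with its attractant cloud.
    With ``False`` targets persist after contact — the protocol for
    trajectory diagnostics, where a guided cell can stay bound to a
    target and the localization signatures (reduced large-lag MSD,
    exponential-like nearest-target distances) become observable.
    ``Q_k`` counts distinct contacted targets in both protocols.
    """

    L_sys: float = 1000.0
    dt_sim: float = 1.0
    T_sim: float = 100.0
    N_tar: int = 10
    r_tar: float = 10.0
    r_imm: float = 10.0
    D: float = 6000.0
    k: float = 0.6
    strategy: StrategyParams = _STANDARD_STRATEGY
    ensemble: Literal["mixed", "pure", "static"] = "mixed"
    v_tar: float = 1.0
    eps_tar: float = 0.0
    static_positions: Optional[tuple[tuple[float, float], ...]] = None
    eliminate_on_contact: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L_sys <= 0 or self.dt_sim <= 0 or self.T_sim <= 0:
            raise ValueError("L_sys, dt_sim and T_sim must be positive")
        if self.N_tar < 0:
            raise ValueError("N_tar must be non-negative")
        if self.r_tar <= 0 or self.r_imm <= 0:
            raise ValueError("cell radii must be positive")
        if self.D <= 0 or self.k <= 0:
            raise ValueError("D and k must be positive")
        if self.ensemble not in ("mixed", "pure", "static"):
            raise ValueError(f"unknown ensemble {self.ensemble!r}")
        if self.ensemble == "static" and self.static_positions is None:
            raise ValueError("static ensemble requires static_positions")

    @property
    def n_steps(self) -> int:
        return int(round(self.T_sim / self.dt_sim))

    @property
    def contact_distance(self) -> float:
        return self.r_imm + self.r_tar

    def kernel(self) -> AttractantKernel:
        return solve_kernel(self.D, self.k, self.r_tar)


@dataclass
class RunResult:
    """Full record of one run: trajectories, contacts, and Q_k."""

    Q_k: int
    contact_events: list[tuple[int, int, tuple[float, float]]]
    immune_folded: np.ndarray  # (T+1, 2)
    immune_unwrapped: np.ndarray  # (T+1, 2)
    immune_mode: np.ndarray  # (T,) of 'N'/'A'
    target_folded: np.ndarray  # (T+1, N, 2)
    target_unwrapped: np.ndarray  # (T+1, N, 2)
    target_alive: np.ndarray  # (T+1, N) bool
    config: ScenarioConfig = field(repr=False, default=None)


def _uniform_positions(rng: np.random.Generator, n: int, L: float) -> np.ndarray:
    return rng.uniform(0.0, L, size=(n, 2))


def initialize_run(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> tuple[AgentState, list[AgentState], list[WalkParams]]:
    """Random initial configuration: uniform positions and headings.

    Mixed-ensemble target parameters are drawn fresh; any mobile target
    initially within contact range of the immune cell is re-placed (a
    zero-effort elimination at step 0 would not measure search).
    """
    imm_pos = rng.uniform(0.0, cfg.L_sys, size=2)
    immune = AgentState.create(imm_pos, rng.uniform(0.0, 2.0 * np.pi))

    n = cfg.N_tar
    if cfg.ensemble == "static":
        pos = np.asarray(cfg.static_positions, dtype=float).reshape(-1, 2)
        if len(pos) != n:
            n = len(pos)
        params = [WalkParams(v=0.0, eps=0.0) for _ in range(n)]
    else:
        pos = _uniform_positions(rng, n, cfg.L_sys)
        for _ in range(100):
            d = min_image_distance(pos, imm_pos, cfg.L_sys)
            bad = d <= cfg.contact_distance
            if not np.any(bad):
                break
            pos[bad] = _uniform_positions(rng, int(bad.sum()), cfg.L_sys)
        else:
            raise PlacementError("could not place targets clear of the immune cell")
        if cfg.ensemble == "mixed":
            v = rng.uniform(0.0, 6.0, size=n)
            e = rng.uniform(0.0, 1.0, size=n)
        else:
            v = np.full(n, cfg.v_tar)
            e = np.full(n, cfg.eps_tar)
        params = [WalkParams(v=float(vi), eps=float(ei)) for vi, ei in zip(v, e)]

    headings = rng.uniform(0.0, 2.0 * np.pi, size=n)
    targets = [AgentState.create(pos[i], headings[i]) for i in range(n)]
    return immune, targets, params


def detect_contacts(
    immune: AgentState,
    targets: list[AgentState],
    r_imm: float,
    r_tar: float,
    L_sys: float,
) -> list[int]:
    """Indices of live targets whose center is within ``r_imm + r_tar``
    (inclusive) of the immune center, minimum-image."""
    hits = []
    for i, t in enumerate(targets):
        if not t.alive:
            continue
        if min_image_distance(immune.position, t.position, L_sys) <= r_imm + r_tar:
            hits.append(i)
    return hits


def run_simulation(cfg: ScenarioConfig, rng: np.random.Generator | int | None = None) -> RunResult:
    """Run one complete seeded simulation and record everything."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    kernel = cfg.kernel()
    immune, targets, tar_params = initialize_run(cfg, rng)
    n = len(targets)
    T = cfg.n_steps
    dt = cfg.dt_sim
    strat = cfg.strategy
    sensor = SensorState()

    imm_folded = np.empty((T + 1, 2))
    imm_unwrapped = np.empty((T + 1, 2))
    imm_mode = np.empty(T, dtype="U1")
    tar_folded = np.empty((T + 1, n, 2))
    tar_unwrapped = np.empty((T + 1, n, 2))
    tar_alive = np.empty((T + 1, n), dtype=bool)

    imm_folded[0] = immune.position
    imm_unwrapped[0] = immune.unwrapped_position
    for i, t in enumerate(targets):
        tar_folded[0, i] = t.position
        tar_unwrapped[0, i] = t.unwrapped_position
        tar_alive[0, i] = t.alive

    # mean step width per step is v * dt
    step_params = [replace(p, v=p.v * dt) for p in tar_params]
    mode_params = {
        "N": WalkParams(v=strat.v_N * dt, eps=strat.eps_N),
        "A": WalkParams(v=strat.v_A * dt, eps=strat.eps_A),
    }

    contact_events: list[tuple[int, int, tuple[float, float]]] = []
    contacted: set[int] = set()
    Q = 0
    for step in range(1, T + 1):
        for i, t in enumerate(targets):
            if t.alive:
                targets[i] = advance(t, step_params[i], rng, cfg.L_sys)

        ctx = FieldContext(
            np.array([t.position for t in targets if t.alive]).reshape(-1, 2),
            kernel,
            cfg.L_sys,
        )
        rho_c = field_at(ctx, immune.position)
        delta_c = temporal_difference(sensor, rho_c)
        mode = choose_mode(strat, delta_c, rng)
        left, right = lateral_sensor_positions(immune.position, immune.heading, cfg.r_imm)
        delta_lr = spatial_difference(ctx, left, right)
        sign = choose_turn_sign(strat, delta_lr, rng)

        immune = advance(immune, mode_params[mode], rng, cfg.L_sys, sign_override=sign)

        for i in detect_contacts(immune, targets, cfg.r_imm, cfg.r_tar, cfg.L_sys):
            if i in contacted:
                continue
            contacted.add(i)
            contact_events.append((step, i, tuple(targets[i].position)))
            Q += 1
            if cfg.eliminate_on_contact:
                targets[i] = replace(targets[i], alive=False)

        imm_folded[step] = immune.position
        imm_unwrapped[step] = immune.unwrapped_position
        imm_mode[step - 1] = mode
        for i, t in enumerate(targets):
            tar_folded[step, i] = t.position
            tar_unwrapped[step, i] = t.unwrapped_position
            tar_alive[step, i] = t.alive

    return RunResult(
        Q_k=Q,
        contact_events=contact_events,
        immune_folded=imm_folded,
        immune_unwrapped=imm_unwrapped,
        immune_mode=imm_mode,
        target_folded=tar_folded,
        target_unwrapped=tar_unwrapped,
        target_alive=tar_alive,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# vectorized batch engine


def _fold_delta(delta: np.ndarray, L: float) -> np.ndarray:
    return delta - L * np.round(delta / L)


def _batch_kernel_values(kernel: AttractantKernel, r: np.ndarray) -> np.ndarray:
    f = np.exp(np.interp(r.ravel(), kernel.r_grid, kernel._log_f)).reshape(r.shape)
    f = np.where(r < kernel.r_tar, 1.0, f)
    return np.where(r > kernel.r_max, 0.0, f)


def _batch_field(points, tar_pos, alive_f, kernel, L):
    """Field at ``points`` (R, 2) from targets (R, N, 2); ``alive_f`` is a
    float 0/1 mask (R, N)."""
    d = _fold_delta(points[:, None, :] - tar_pos, L)
    r = np.sqrt(np.einsum("rnk,rnk->rn", d, d))
    return np.einsum("rn,rn->r", _batch_kernel_values(kernel, r), alive_f)


def run_batch(cfg: ScenarioConfig, n_runs: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Advance ``n_runs`` independent runs in lock-step; return Q_k (int array).

    Statistically identical to looping :func:`run_simulation`, but all
    per-step draws are batched across runs.  Field evaluations are
    skipped entirely for channels with zero sensitivity (blind
    strategies cost no kernel interpolation).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    R = int(n_runs)
    N = cfg.N_tar
    L = cfg.L_sys
    dt = cfg.dt_sim
    strat = cfg.strategy
    kernel = cfg.kernel()
    need_center = strat.c_A1 != 0.0
    need_lateral = strat.c_R1 != 0.0

    imm_pos = rng.uniform(0.0, L, size=(R, 2))
    imm_head = rng.uniform(0.0, 2.0 * np.pi, size=R)

    if cfg.ensemble == "static":
        base = np.asarray(cfg.static_positions, dtype=float).reshape(-1, 2)
        N = len(base)
        tar_pos = np.broadcast_to(base, (R, N, 2)).copy()
        tar_v = np.zeros((R, N))
        tar_e = np.zeros((R, N))
    else:
        tar_pos = rng.uniform(0.0, L, size=(R, N, 2))
        for _ in range(100):
            d = _fold_delta(tar_pos - imm_pos[:, None, :], L)
            bad = np.sqrt((d * d).sum(-1)) <= cfg.contact_distance
            if not bad.any():
                break
            tar_pos[bad] = rng.uniform(0.0, L, size=(int(bad.sum()), 2))
        else:
            raise PlacementError("could not place targets clear of the immune cell")
        if cfg.ensemble == "mixed":
            tar_v = rng.uniform(0.0, 6.0, size=(R, N))
            tar_e = rng.uniform(0.0, 1.0, size=(R, N))
        else:
            tar_v = np.full((R, N), cfg.v_tar)
            tar_e = np.full((R, N), cfg.eps_tar)
    tar_head = rng.uniform(0.0, 2.0 * np.pi, size=(R, N))
    alive = np.ones((R, N), dtype=bool)
    contacted_mask = np.zeros((R, N), dtype=bool)

    tar_scale = tar_v * dt * RAYLEIGH_SCALE
    tar_halfwidth = (1.0 - tar_e) * np.pi  # eps in [0, 1]
    q_A_const = logistic(strat.c_A0)
    Q = np.zeros(R, dtype=np.int64)
    rho_prev = np.zeros(R)
    contact_sq = cfg.contact_distance**2

    for step in range(cfg.n_steps):
        if N:
            w = rng.rayleigh(scale=np.maximum(tar_scale, 1e-300), size=(R, N))
            w[tar_scale == 0.0] = 0.0
            dphi = np.abs(rng.uniform(-tar_halfwidth, tar_halfwidth))
            s = np.where(rng.random((R, N)) < 0.5, -1.0, 1.0)
            tar_head = tar_head + s * dphi
            tar_pos[..., 0] += w * np.cos(tar_head)
            tar_pos[..., 1] += w * np.sin(tar_head)
            np.mod(tar_pos, L, out=tar_pos)
        alive_f = alive.astype(float)

        if need_center and N:
            rho = _batch_field(imm_pos, tar_pos, alive_f, kernel, L)
            delta_c = rho - rho_prev if step > 0 else np.zeros(R)
            rho_prev = rho
            q_A = logistic(strat.c_A0 + strat.c_A1 * delta_c)
        else:
            q_A = q_A_const
        in_A = rng.random(R) < q_A
        v = np.where(in_A, strat.v_A, strat.v_N)
        eps = np.where(in_A, strat.eps_A, strat.eps_N)

        if need_lateral and N:
            offs = cfg.r_imm * np.stack(
                [np.cos(imm_head + np.pi / 2), np.sin(imm_head + np.pi / 2)], axis=-1
            )
            pts = np.concatenate([imm_pos - offs, imm_pos + offs])  # right, left
            f = _batch_field(
                pts,
                np.concatenate([tar_pos, tar_pos]),
                np.concatenate([alive_f, alive_f]),
                kernel,
                L,
            )
            delta_lr = f[:R] - f[R:]
            q_R = logistic(strat.c_R1 * delta_lr)
        else:
            q_R = 0.5
        s_imm = np.where(rng.random(R) < q_R, -1.0, 1.0)

        scale = v * dt * RAYLEIGH_SCALE
        w_imm = rng.rayleigh(scale=np.maximum(scale, 1e-300), size=R)
        w_imm[scale == 0.0] = 0.0
        half = (1.0 - eps) * np.pi
        dphi_imm = np.abs(rng.uniform(-half, half))
        imm_head = imm_head + s_imm * dphi_imm
        imm_pos[:, 0] += w_imm * np.cos(imm_head)
        imm_pos[:, 1] += w_imm * np.sin(imm_head)
        np.mod(imm_pos, L, out=imm_pos)

        if N:
            d = _fold_delta(tar_pos - imm_pos[:, None, :], L)
            hit = ~contacted_mask & (np.einsum("rnk,rnk->rn", d, d) <= contact_sq)
            if hit.any():
                Q += hit.sum(axis=1)
                contacted_mask |= hit
                if cfg.eliminate_on_contact:
                    alive &= ~hit
    return Q


def trajectory_frame(result: RunResult, run_id: int = 0) -> pd.DataFrame:
    """Tidy per-step trajectory table (one row per agent per step)."""
    T = len(result.immune_folded) - 1
    n = result.target_folded.shape[1]
    frames = []
    steps = np.arange(T + 1)
    frames.append(
        pd.DataFrame(
            {
                "run_id": run_id,
                "step": steps,
                "agent_id": 0,
                "role": "immune",
                "x": result.immune_folded[:, 0],
                "y": result.immune_folded[:, 1],
                "x_unwrapped": result.immune_unwrapped[:, 0],
                "y_unwrapped": result.immune_unwrapped[:, 1],
                "mode": np.concatenate([[""], result.immune_mode]),
                "alive": True,
            }
        )
    )
    for i in range(n):
        frames.append(
            pd.DataFrame(
                {
                    "run_id": run_id,
                    "step": steps,
                    "agent_id": i + 1,
                    "role": "target",
                    "x": result.target_folded[:, i, 0],
                    "y": result.target_folded[:, i, 1],
                    "x_unwrapped": result.target_unwrapped[:, i, 0],
                    "y_unwrapped": result.target_unwrapped[:, i, 1],
                    "mode": "",
                    "alive": result.target_alive[:, i],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
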