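"""Grid-based cyclic coordinate descent (CCD) on a noisy objective.

The search efficiency Q(π) of a strategy is maximized over the free
subset of the 7 immune-cell parameters.  Each sweep scans the free
parameters one at a time over their full grids, greedily updating the
incumbent to the scan argmax; iteration stops when a full sweep leaves
every parameter unchanged (the same optimum found in two subsequent
loops) or a sweep cap is hit.

Because Q is estimated by Monte Carlo, all evaluations share common
random numbers (one evaluation seed derived from the master seed):
the objective is then a fixed deterministic function of the parameter
vector, scan argmaxes are reproducible, and incumbent values are
non-decreasing across sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .efficiency import estimate_Q
from .engine import ScenarioConfig
from .response import StrategyParams

__all__ = [
    "ParameterGrid",
    "OptimizationTrace",
    "optimize",
    "make_Q_objective",
    "default_grids",
]

#: Default per-parameter scan grids.  Speeds step by 1 μm/min,
#: persistences by 0.1, the mode bias by 1; the sensitivities use a
#: sign-symmetric coarse ladder since the response saturates long
#: before |c| = 500.
def default_grids() -> dict[str, np.ndarray]:
    ladder = np.array([0.0, 5.0, 50.0, 500.0])
    return {
        "v_N": np.arange(0.0, 6.5, 1.0),
        "eps_N": np.round(np.arange(0.0, 1.05, 0.1), 10),
        "v_A": np.arange(0.0, 6.5, 1.0),
        "eps_A": np.round(np.arange(0.0, 1.05, 0.1), 10),
        "c_A0": np.arange(-5.0, 5.5, 1.0),
        "c_A1": np.concatenate([-ladder[:0:-1], ladder]),
        "c_R1": np.concatenate([-ladder[:0:-1], ladder]),
    }


@dataclass(frozen=True)
class ParameterGrid:
    """Scan grids for the free parameters plus frozen values for the rest."""

    free: Mapping[str, np.ndarray]
    frozen: StrategyParams

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("at least one free parameter is required")
        bounds = {
            "v_N": (0, 6),
            "v_A": (0, 6),
            "eps_N": (0, 1),
            "eps_A": (0, 1),
            "c_A0": (-5, 5),
            "c_A1": (-500, 500),
            "c_R1": (-500, 500),
        }
        for name, grid in self.free.items():
            lo, hi = bounds[name]
            g = np.asarray(grid, dtype=float)
            if g.min() < lo or g.max() > hi:
                raise ValueError(f"grid for {name} exceeds its range [{lo}, {hi}]")

    @classmethod
    def for_family(
        cls, free_names: Sequence[str], frozen: StrategyParams, grids=None
    ) -> "ParameterGrid":
        all_grids = default_grids()
        if grids:
            all_grids.update(grids)
        return cls(free={n: np.asarray(all_grids[n], float) for n in free_names}, frozen=frozen)


@dataclass
class OptimizationTrace:
    """Per-sweep incumbents of a CCD run."""

    sweeps: list[dict] = field(default_factory=list)  # {"params": dict, "Q": float}
    converged: bool = False

    @property
    def best_params(self) -> dict[str, float]:
        return self.sweeps[-1]["params"]

    @property
    def best_Q(self) -> float:
        return self.sweeps[-1]["Q"]


def make_Q_objective(
    cfg: ScenarioConfig, N_runs_per_eval: int
) -> Callable[[StrategyParams, int], float]:
    """Objective evaluating the search efficiency of a strategy with a
    fixed run budget and a caller-supplied seed (common random numbers)."""

    def objective(params: StrategyParams, seed: int) -> float:
        return estimate_Q(replace(cfg, strategy=params), N_runs_per_eval, seed).Q

    return objective


def optimize(
    grid: ParameterGrid,
    objective: Callable[[StrategyParams, int], float],
    master_seed: int = 0,
    max_sweeps: int = 20,
) -> OptimizationTrace:
    """Cyclic coordinate descent over the free-parameter grids.

    Ties within a scan keep the incumbent if it is among the maximizers,
    else take the lowest grid index.  The returned trace flags whether
    the stopping rule (an unchanged sweep) was reached before the cap.
    """
    eval_seed = int(
        np.random.SeedSequence(master_seed).generate_state(1)[0] % (2**31)
    )
    incumbent = {name: float(np.asarray(g)[0]) for name, g in grid.free.items()}
    # start each free parameter from its frozen/preset value when on-grid
    frozen_dict = grid.frozen.as_dict()
    for name, g in grid.free.items():
        g = np.asarray(g, float)
        if np.any(np.isclose(g, frozen_dict[name])):
            incumbent[name] = float(g[np.argmin(np.abs(g - frozen_dict[name]))])

    cache: dict[tuple, float] = {}

    def evaluate(values: dict[str, float]) -> float:
        key = tuple(sorted(values.items()))
        if key not in cache:
            params = StrategyParams(**{**frozen_dict, **values})
            cache[key] = float(objective(params, eval_seed))
        return cache[key]

    trace = OptimizationTrace()
    for _ in range(max_sweeps):
        changed = False
        for name, g in grid.free.items():
            g = np.asarray(g, float)
            scores = np.array(
                [evaluate({**incumbent, name: float(val)}) for val in g]
            )
            best = scores.max()
            maximizers = np.flatnonzero(scores == best)
            current_idx = np.flatnonzero(np.isclose(g, incumbent[name]))
            if current_idx.size and current_idx[0] in maximizers:
                choice = int(current_idx[0])
            else:
                choice = int(maximizers[0])
            if not np.isclose(g[choice], incumbent[name]):
                changed = True
            incumbent[name] = float(g[choice])
        trace.sweeps.append(
            {"params": dict(incumbent), "Q": evaluate(dict(incumbent))}
        )
        if not changed:
            trace.converged = True
            break
    return trace
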