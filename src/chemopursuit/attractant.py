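"""Stationary chemoattractant field around emitting target cells.

Each target cell releases a chemoattractant at its center at a constant
rate.  The substance diffuses (diffusivity ``D``) and decays (rate ``k``),
so in the fast-diffusion limit every emitter carries a static,
rotationally symmetric concentration cloud of spatial extent
``L_dif = sqrt(D / k)``.  Outside the emitter radius the stationary
radial profile ``f(r)`` obeys the modified Helmholtz equation

    f'' + f'/r = (k / D) f,

solved here by a shooting method: the profile is normalized to
``f(r_tar) = 1`` at the cell border and the initial slope is bisected
until the solution decays to (numerically) zero instead of diverging.
The total field of all live targets is the linear superposition of their
kernels, with distances measured by the minimum-image convention on the
periodic simulation plane.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "AttractantKernel",
    "FieldContext",
    "KernelConvergenceError",
    "solve_kernel",
    "kernel_value",
    "min_image_distance",
    "field_at",
]


class KernelConvergenceError(RuntimeError):
    """Raised when the shooting iteration fails to bracket the decaying profile."""


@dataclass(frozen=True)
class AttractantKernel:
    """Tabulated stationary radial profile of one emitter.

    Attributes
    ----------
    r_grid : ndarray
        Radial distances in μm, strictly increasing, ``r_grid[0] == r_tar``.
    f_values : ndarray
        Dimensionless density, normalized to ``f_values[0] == 1`` and
        strictly decreasing.
    L_dif : float
        Diffusion length ``sqrt(D / k)`` in μm.
    r_tar : float
        Emitter (target cell) radius in μm.
    r_max : float
        Truncation radius in μm; the kernel is defined as exactly 0 beyond.
    D, k : float
        Diffusivity (μm²/min) and decay rate (1/min), kept for provenance.
    """

    r_grid: np.ndarray
    f_values: np.ndarray
    L_dif: float
    r_tar: float
    r_max: float
    D: float
    k: float
    _log_f: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_log_f", np.log(self.f_values))

    def __call__(self, r):
        return kernel_value(self, r)

    def to_csv(self) -> str:
        """Serialize as two-column CSV with a JSON header comment."""
        meta = {
            "D": self.D,
            "k": self.k,
            "r_tar": self.r_tar,
            "r_max": self.r_max,
            "L_dif": self.L_dif,
        }
        buf = io.StringIO()
        buf.write("# " + json.dumps(meta) + "\n")
        buf.write("r,f\n")
        for r, f in zip(self.r_grid, self.f_values):
            buf.write(f"{r:.10g},{f:.12e}\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "AttractantKernel":
        lines = text.splitlines()
        meta = json.loads(lines[0].lstrip("# "))
        data = np.loadtxt(io.StringIO("\n".join(lines[2:])), delimiter=",")
        return cls(
            r_grid=data[:, 0],
            f_values=data[:, 1],
            L_dif=meta["L_dif"],
            r_tar=meta["r_tar"],
            r_max=meta["r_max"],
            D=meta["D"],
            k=meta["k"],
        )


_KERNEL_CACHE: dict[tuple, AttractantKernel] = {}


def solve_kernel(
    D: float,
    k: float,
    r_tar: float,
    r_max: float | None = None,
    n_grid: int = 2000,
    max_iter: int = 200,
) -> AttractantKernel:
    """Solve the stationary radial profile by shooting.

    Parameters
    ----------
    D : float
        Chemoattractant diffusivity in μm²/min.
    k : float
        Decay rate in 1/min.
    r_tar : float
        Emitter radius in μm; the profile is normalized to 1 there.
    r_max : float, optional
        Truncation radius; defaults to ``10 * L_dif``, where the profile
        has decayed below ~1e-5 so that truncation error is negligible.
    n_grid : int
        Number of nodes of the geometric radial grid (denser near
        ``r_tar`` where the curvature is largest).

    The initial slope ``f'(r_tar)`` is bisected inside ``[-10, 0]``:
    a too-steep trial crosses zero before ``r_max``, a too-shallow one
    diverges; iteration stops once the tail value at ``r_max`` lies in
    ``[0, 1e-8]`` with the profile positive throughout.
    """
    if D <= 0 or k <= 0 or r_tar <= 0:
        raise ValueError("D, k and r_tar must be positive")
    L_dif = float(np.sqrt(D / k))
    if r_max is None:
        r_max = 10.0 * L_dif
    if r_max < 10.0 * L_dif:
        raise ValueError(f"r_max must be at least 10 * L_dif = {10 * L_dif:g} μm")
    key = (float(D), float(k), float(r_tar), float(r_max), int(n_grid))
    if key in _KERNEL_CACHE:
        return _KERNEL_CACHE[key]

    # Dimensionless radius x = r / L_dif turns the equation into
    # f'' + f'/x = f, integrated from x0 = r_tar/L_dif to x1 = r_max/L_dif.
    x0 = r_tar / L_dif
    x1 = r_max / L_dif
    tail_tol = 1e-8

    def rhs(x, y):
        f, fp = y
        return [fp, f - fp / x]

    def crossed_zero(x, y):
        return y[0]

    crossed_zero.terminal = True
    crossed_zero.direction = -1

    def diverged(x, y):
        return y[0] - 2.0

    diverged.terminal = True
    diverged.direction = 1

    def shoot(slope_per_um: float):
        sol = solve_ivp(
            rhs,
            (x0, x1),
            [1.0, slope_per_um * L_dif],
            method="RK45",
            rtol=1e-10,
            atol=1e-12,
            dense_output=True,
            events=(crossed_zero, diverged),
        )
        if sol.t_events[0].size:  # hit zero before r_max: slope too steep
            return "steep", sol
        if sol.t_events[1].size or sol.y[0, -1] > tail_tol:
            return "shallow", sol
        return "ok", sol

    lo, hi = -10.0, 0.0  # f'(r_tar) in 1/μm; decaying solution lies between
    status, sol_lo = shoot(lo)
    if status != "steep":
        raise KernelConvergenceError("lower slope bound does not cross zero")
    status, sol_hi = shoot(hi)
    if status != "shallow":
        raise KernelConvergenceError("upper slope bound does not diverge")

    sol = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        status, trial = shoot(mid)
        if status == "ok":
            sol = trial
            break
        if status == "steep":
            lo = mid
        else:
            hi = mid
    if sol is None:
        raise KernelConvergenceError(
            f"slope bisection did not reach a tail in [0, {tail_tol:g}] "
            f"within {max_iter} iterations"
        )

    x_grid = np.geomspace(x0, x1, n_grid)
    f_values = sol.sol(x_grid)[0]
    f_values[0] = 1.0
    kernel = AttractantKernel(
        r_grid=x_grid * L_dif,
        f_values=f_values,
        L_dif=L_dif,
        r_tar=float(r_tar),
        r_max=float(r_max),
        D=float(D),
        k=float(k),
    )
    _KERNEL_CACHE[key] = kernel
    return kernel


def kernel_value(kernel: AttractantKernel, r):
    """Evaluate the kernel at radius ``r`` (scalar or array, μm).

    Distances below ``r_tar`` clamp to the border value 1 (the sensing
    cell's center can never be closer to the emission point than the
    emitter radius); beyond ``r_max`` the kernel is exactly 0.  In
    between, interpolation is log-linear in ``f``, which is nearly exact
    given the exponential tail.
    """
    r_arr = np.asarray(r, dtype=float)
    out = np.exp(np.interp(r_arr, kernel.r_grid, kernel._log_f))
    out = np.where(r_arr < kernel.r_tar, 1.0, out)
    out = np.where(r_arr > kernel.r_max, 0.0, out)
    if np.isscalar(r) or r_arr.ndim == 0:
        return float(out)
    return out


def min_image_distance(a, b, L_sys: float):
    """Euclidean distance on the ``L_sys`` × ``L_sys`` torus.

    Works on single points or arrays whose last axis has length 2;
    broadcasting applies to the leading axes.
    """
    delta = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    delta -= L_sys * np.round(delta / L_sys)
    return np.sqrt(np.sum(delta * delta, axis=-1))


@dataclass
class FieldContext:
    """Live-target positions plus the kernel and system size.

    Positions are folded into ``[0, L_sys)²``; the list shrinks as
    targets are eliminated, and with them their attractant clouds
    (fast-diffusion limit).
    """

    live_target_positions: np.ndarray  # (N, 2), μm
    kernel: AttractantKernel
    L_sys: float

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.live_target_positions, dtype=float))
        if pos.size == 0:
            pos = pos.reshape(0, 2)
        self.live_target_positions = np.mod(pos, self.L_sys)


def field_at(ctx: FieldContext, p) -> float:
    """Total chemoattractant density at point ``p``: the sum of the
    kernels of all live targets at their minimum-image distances."""
    pos = ctx.live_target_positions
    if len(pos) == 0:
        return 0.0
    d = min_image_distance(pos, np.asarray(p, dtype=float), ctx.L_sys)
    return float(np.sum(kernel_value(ctx.kernel, d)))
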