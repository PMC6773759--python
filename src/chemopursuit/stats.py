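"""Trajectory diagnostics: covered area, MSD, nearest-target distances.

These three statistics expose the indirect signatures of goal-directed
search: guided strategies barely change the covered area but reduce the
large-lag mean squared displacement and shift the nearest-target
distance distribution from the Rayleigh shape of an uncorrelated
searcher toward an exponential-like pile-up at contact range.
"""

from __future__ import annotations

import numpy as np

from .attractant import min_image_distance

__all__ = [
    "covered_area",
    "msd",
    "nearest_target_distances",
    "rayleigh_nn_density",
]


def covered_area(folded_trajectory, delta_L: float = 10.0, L_sys: float = 1000.0) -> np.ndarray:
    """Covered area A(t) = n_vis(t) · δL² from a folded trajectory.

    The plane is partitioned into square patches of side ``delta_L``
    (default 10 μm, the cell radius); per step the patch containing the
    cell center counts as visited.  Returns one value per trajectory
    point; A is non-decreasing and bounded by ``L_sys²``.
    """
    traj = np.asarray(folded_trajectory, dtype=float)
    n_side = int(round(L_sys / delta_L))
    ix = np.clip((traj[:, 0] // delta_L).astype(int), 0, n_side - 1)
    iy = np.clip((traj[:, 1] // delta_L).astype(int), 0, n_side - 1)
    patch = ix * n_side + iy
    _, first = np.unique(patch, return_index=True)
    new_visit = np.zeros(len(traj), dtype=bool)
    new_visit[first] = True
    return np.cumsum(new_visit) * delta_L**2


def msd(unwrapped_trajectory) -> np.ndarray:
    """Time-averaged mean squared displacement R²(Δt) for lags 1..T−1.

    Computed on unwrapped coordinates (no periodic folding), averaging
    over all overlapping time origins.
    """
    traj = np.asarray(unwrapped_trajectory, dtype=float)
    T = len(traj)
    if T < 2:
        raise ValueError("trajectory must contain at least 2 points")
    out = np.empty(T - 1)
    for lag in range(1, T):
        d = traj[lag:] - traj[:-lag]
        out[lag - 1] = np.mean(np.sum(d * d, axis=1))
    return out


def nearest_target_distances(
    immune_folded, target_folded, target_alive, L_sys: float
) -> np.ndarray:
    """Per-step minimum-image distance from the immune cell to its
    nearest live target.

    ``immune_folded`` is (T, 2), ``target_folded`` (T, N, 2) and
    ``target_alive`` (T, N); steps with no live target are skipped.
    """
    imm = np.asarray(immune_folded, dtype=float)
    tar = np.asarray(target_folded, dtype=float)
    alive = np.asarray(target_alive, dtype=bool)
    d = min_image_distance(tar, imm[:, None, :], L_sys)
    d = np.where(alive, d, np.inf)
    nn = d.min(axis=1)
    return nn[np.isfinite(nn)]


def rayleigh_nn_density(rho_tar: float, d) -> np.ndarray:
    """Nearest-neighbor distance density for an uncorrelated searcher in
    a spatial Poisson field of intensity ``rho_tar``:

        p(d) = 2π ρ d · exp(−π ρ d²),

    with mean ``1 / (2 √ρ)`` and mode ``1 / √(2πρ)``.
    """
    if rho_tar <= 0:
        raise ValueError("rho_tar must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return 2.0 * np.pi * rho_tar * d * np.exp(-np.pi * rho_tar * d * d)
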