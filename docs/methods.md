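# Methods

## Model overview and assumptions

The simulator studies a pursuit problem: one chemotactically sensing
searcher ("immune cell") and `N_tar` independently migrating emitters
("target cells") on an `L_sys × L_sys` plane with periodic boundary
conditions. The model makes four structural assumptions:

1. **Correlated random walks.** Every cell moves in discrete 1-min
   steps with Rayleigh-distributed step widths (mean = the cell's
   speed parameter `v`, so `v` is the average contour speed) and
   turning-angle magnitudes drawn uniformly from bounds set by a
   persistence parameter ε: `±(1−ε)π` for ε ≥ 0, a reversal-centered
   band for ε < 0. Only the magnitude enters the position update; the
   sign of the turn is a separate Bernoulli variable, which is exactly
   the hook the spatial-sensing channel uses. Headings are stored
   explicitly rather than recomputed from displacements, which is
   mathematically identical and avoids the zero-step-width degeneracy.
2. **Fast-diffusion limit.** The chemoattractant (diffusivity
   D = 6000 μm²/min, decay k = 0.6/min) relaxes on a time scale
   T_dif = 1/k ≈ 1.7 min and a length scale L_dif = √(D/k) = 100 μm,
   giving a critical emitter speed L_dif/T_dif ≈ 60 μm/min. Targets
   move at ≤ 6 μm/min, so each carries a fully developed stationary
   cloud; the field is a static kernel translated with the emitter, and
   the time-dependent reaction–diffusion equation is never solved.
   A cloud disappears instantly with its emitter for the same reason.
3. **Linear superposition.** Emitters contribute independently; the
   total field is the sum of kernels at minimum-image distances.
4. **Ideal sensing.** The searcher reads arbitrarily small
   concentrations and concentration differences; no receptor noise or
   detection floor is modeled.

## Stationary kernel

Outside the emitter radius the stationary profile obeys
`f″ + f′/r = (k/D) f`, the modified Bessel equation of order zero, so
`f(r) = K₀(r/L_dif)/K₀(r_tar/L_dif)` after normalizing `f(r_tar) = 1`.
The solver deliberately does not use this closed form: it integrates
the ODE with an explicit Runge–Kutta scheme (`scipy.solve_ivp`, RK45,
rtol 1e-10) and bisects the initial slope `f′(r_tar) ∈ [−10, 0] μm⁻¹`,
classifying trials as "crossed zero" (too steep) or "diverged" (too
shallow), until the tail at the truncation radius lies in `[0, 1e-8]`.
The Bessel form then serves as an independent oracle in the tests
(agreement to < 1e-4 relative over r ∈ [10, 500] μm).

Numerical choices:

- **Truncation** at `r_max = 10·L_dif`, where the true profile is
  ~7e-6 of the border value; beyond it the kernel is defined as exactly
  zero. The truncation error is far below Monte-Carlo noise.
- **Grid** of 2000 geometrically spaced nodes (denser near `r_tar`,
  where curvature is largest); evaluation interpolates log-linearly in
  `f`, nearly exact for the exponential tail.
- **Clamping:** distances below `r_tar` return 1 (a searcher center can
  never be closer to an emission point than the emitter radius).
- The tail forced into `[0, 1e-8]` sits slightly below the true profile
  near `r_max`; the contamination by the growing Bessel mode is ~5e-5
  relative at r = 500 μm and only matters in the last ~15% of the grid,
  which is 5+ decades below the border value.
- The emission rate g is not represented: with `f(r_tar) = 1` it only
  scales the field, and the response channels are optimized jointly
  with the sensitivities, so it is absorbed into `c_A1`, `c_R1`.

## Response channels and sign conventions

P(approach mode) = logistic(c_A0 + c_A1·Δρ^C) with Δρ^C the one-step
temporal difference at the cell center; P(right turn, s = −1) =
logistic(c_R1·Δρ^LR) with Δρ^LR the right-minus-left difference across
the two border sensors, placed perpendicular to the *previous* heading.
Positive sensitivities attract: rising concentration favors the
approach mode, and a denser right side favors a right turn (turning
right decreases the heading angle, i.e. toward the denser side). Both
draws are memoryless across steps; the only state is the previous
center reading, and the first temporal difference of a run is defined
as 0 so that the initial mode prior is logistic(c_A0).

The bias range is nominally c_A0 ∈ [−5, 5]; the spatial-sensing preset
uses c_A0 = 500 as an "always approach" override, which the parameter
container accepts (speeds and persistences stay strictly validated).

## Simulation protocol

Per step: (1) all live targets advance (q_R = 1/2); (2) the searcher
senses on the post-target-move field and draws its mode and turn sign;
(3) the searcher advances; (4) contacts (center distance ≤
r_imm + r_tar = 20 μm, evaluated at step endpoints) are recorded and
contacted targets removed. Initial positions and headings are uniform;
targets initially inside contact range are re-placed so that Q never
counts zero-effort eliminations. Segment-crossing misses between
endpoints are rare (P(w > 20 μm) < 2e-4 at v = 6) and below
Monte-Carlo noise.

Two engines implement this process: a per-agent reference loop that
records full trajectories, and a vectorized engine that advances
thousands of runs in lock-step and returns only the elimination counts.
Blind channels cost nothing in the vectorized engine (no field
evaluation when a sensitivity is zero). A statistical-equivalence test
ties the two engines together on a guided scenario.

**Seeding.** A master seed spawns child `SeedSequence`s per fixed-size
2000-run chunk (vectorized path) or per run (scalar path); estimates
are exactly reproducible given (seed, N_runs), and chunks are
order-independent.

**Elimination protocols.** Search-efficiency runs remove a contacted
target together with its cloud (the definition of Q). Trajectory
diagnostics instead use a persistent-target protocol
(`eliminate_on_contact=False`, Q then counts *distinct* contacted
targets): with instant removal a searcher can never dwell near a
target, so the localization signatures of guided search — reduced
large-lag MSD, exponential-like nearest-target distances — are not
observable; with persistent targets a guided cell stays bound to a
cloud and both signatures appear decisively. With elimination enabled,
guided steering actually *straightens* trajectories between kills and
raises the large-lag MSD above the blinded control; this protocol
dependence is a genuine property of the model worth knowing when
comparing against trajectory data.

## Efficiency estimation and optimization

Q is the mean of Q_k over N_runs = 10⁴ independent runs (default; the
standard error, sample std/√N_runs, is always reported). The mixed
target ensemble redraws each target's (v, ε) uniformly from
[0, 6] × [0, 1] per run; pure ensembles fix both, and the 7×6 grid
(v ∈ {0..6}, ε ∈ {0, 0.2, …, 1}) used for Q(v_tar, ε_tar) maps give
per-node standard errors of ~0.01–0.03 at 2000 runs per node.

The optimizer is grid-based cyclic coordinate descent: scan one free
parameter's full grid with the others held at their incumbents, adopt
the argmax, cycle until a sweep changes nothing (cap 20 sweeps).
Because the objective is noisy, all evaluations share one evaluation
seed derived from the master seed (common random numbers): the
objective becomes a deterministic function, scans are reproducible,
incumbent values are non-decreasing, and evaluations are memoized.
Ties keep the incumbent, else the lowest grid index. Default grids:
speeds in steps of 1, persistences in steps of 0.1, bias in steps of 1,
sensitivities on a sign-symmetric ladder {0, ±5, ±50, ±500} — the
response saturates long before |c| = 500, so finer resolution there
adds nothing.

## Problem sizes used in tests

The shipped suite estimates the headline efficiencies at the full
10⁴-run budget, heat-map trends at 2000 runs per node on the 7×6 grid,
and optimizer recovery (blind family, free v_N and ε_N) at 2000 runs
per evaluation; trajectory-statistics comparisons use 12 paired seeds
of 300-min runs. These sizes give Monte-Carlo standard errors one
order of magnitude below the effects being checked.

## What the generator emulates — and what it does not

The synthetic scenarios reproduce the statistical structure of the
model: cell-scale geometry (10 μm radii), realistic attractant
parameters (anaphylatoxin-like diffusivity and decay), uniform random
initial configurations, and target behavior spanning immobile to fast
persistent migration. They do not emulate receptor/ligand noise, finite
diffusion speed (no wake behind fast emitters), cell–cell volume
exclusion, target evasion, multiple searchers, or heterogeneity of the
searcher's own parameters over time beyond the two-mode switching.
Passing tests therefore validate the model's internal consistency and
its published phenomenology, not agreement with any particular
experimental system.

## Known limitations

- 2D only; no 3D geometry.
- Contacts are endpoint checks, not continuous segment sweeps.
- Covered-area marks only the patch of the cell center per step (patch
  size δL = 10 μm equals the cell radius, so footprint effects are
  sub-dominant).
- MSD standard errors use all overlapping origins without blocking
  corrections — a diagnostic, not an inferential tool.
- The CCD optimizer inherits the usual greedy-coordinate caveat: on
  non-separable objectives it can stop at coordinate-wise optima; with
  common random numbers it optimizes one noise realization of Q.
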