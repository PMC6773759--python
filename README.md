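# chemopursuit

Agent-based simulation of **chemotactic pursuit**: a single immune-like
searcher hunting multiple chemoattractant-emitting target cells on a
periodic two-dimensional plane. The package is built for quantitative
questions about search strategy — how efficient is unguided ("blind")
migration, how much do temporal or spatial gradient sensing add, and
which stimulus-response parameters maximize the kill rate against
targets with unknown migration behavior. Intended users are
computational biophysicists and quantitative cell-biology groups who
want a reproducible reference implementation of this model class for
strategy comparison, parameter optimization, or generating synthetic
trajectories for trajectory-analysis methods.

## Model

All cells perform discrete-time correlated random walks (time step
Δt = 1 min). A step of cell *c* is

r⃗_{c,n} = r⃗_{c,n−1} + w_{c,n} · (cos(ϕ_{c,n−1} + s_{c,n}|Δϕ_{c,n}|),
sin(ϕ_{c,n−1} + s_{c,n}|Δϕ_{c,n}|)),

with Rayleigh step widths *w* of mean *v*, turning magnitudes |Δϕ|
uniform on persistence-dependent bounds (ε = 1 ballistic, ε = 0
isotropic), and a turn sign *s* = −1 (right) with probability q_R.

Each target emits a chemoattractant that diffuses (D = 6000 μm²/min)
and decays (k = 0.6/min). In the fast-diffusion limit each emitter
carries a stationary radial cloud f(r) solving f″ + f′/r = (k/D) f with
f(r_tar) = 1, equal to K₀(r/L_dif)/K₀(r_tar/L_dif) with diffusion
length L_dif = √(D/k) = 100 μm; clouds of live targets superpose
linearly on the torus (minimum-image distances).

The searcher has two migration modes — normal (v_N, ε_N) and approach
(v_A, ε_A) — and two logistic response channels, evaluated fresh each
step:

- mode choice: P(approach) = logistic(c_A0 + c_A1 Δρ^C), where Δρ^C is
  the one-step change of the concentration at the cell center
  (temporal gradient sensing);
- turn sign: P(right) = logistic(c_R1 Δρ^LR), where Δρ^LR is the
  right-minus-left concentration difference across the cell body
  (spatial gradient sensing).

A target whose center comes within r_imm + r_tar = 20 μm is contacted
and removed. The **search efficiency Q** is the mean number of targets
eliminated in a 100-min run with 10 targets in a 1000 μm box, averaged
over 10⁴ seeded runs whose target speeds and persistences are drawn
uniformly from [0, 6] μm/min × [0, 1] (the "mixed ensemble"). The free
strategy parameters π = (v_N, ε_N, v_A, ε_A, c_A0, c_A1, c_R1) are
optimized by grid-based cyclic coordinate descent on Q.

Five named strategies ship as presets: `bls` (blind search), `rms`
(random mode switching), `tgs` (temporal gradient sensing, a
run-and-tumble strategy), `sgs` (spatial gradient sensing) and `cgs`
(combined sensing).

## Worked example

```python
import numpy as np
from chemopursuit import ScenarioConfig, estimate_Q, solve_kernel
from chemopursuit.presets import PRESETS

kernel = solve_kernel(D=6000, k=0.6, r_tar=10)
print(f"L_dif = {kernel.L_dif:.0f} μm")

for name in ("bls", "tgs", "sgs"):
    cfg = ScenarioConfig(strategy=PRESETS[name].params, ensemble="mixed")
    rep = estimate_Q(cfg, N_runs=10_000, master_seed=1)
    print(f"{name}: Q = {rep.Q:.3f} ± {rep.se:.3f}")
```

Output:

```
L_dif = 100 μm
bls: Q = 0.261 ± 0.005
tgs: Q = 1.127 ± 0.008
sgs: Q = 2.619 ± 0.009
```

The blind searcher at its optimum (maximum speed, full persistence)
eliminates about a quarter of a target per run; temporal gradient
sensing quadruples this, and spatial gradient sensing is nearly ten
times more efficient than blind search — the strategy hierarchy
Q_BLS < Q_TGS < Q_SGS. Equivalent runs from the shell:

```bash
chemopursuit efficiency --preset sgs --runs 10000 --seed 1 --out sgs.csv
chemopursuit heatmap --preset tgs --runs 2000 --seed 1 --out tgs_heatmap.csv
chemopursuit optimize --strategy bls --runs 2000 --seed 1
chemopursuit simulate --preset cgs --seed 3 --out run/
```

## Layout

- `chemopursuit.attractant` — stationary kernel (shooting solver), periodic field
- `chemopursuit.walk` — correlated-random-walk primitives
- `chemopursuit.response` — sensors and logistic stimulus-response functions
- `chemopursuit.engine` — scalar and vectorized simulation engines
- `chemopursuit.efficiency` — Monte-Carlo Q estimation and target-grid scans
- `chemopursuit.optimize` — grid-based cyclic coordinate descent
- `chemopursuit.stats` — covered area, MSD, nearest-target distances
- `chemopursuit.presets` / `config` / `cli` — named strategies, YAML configs, CLI

See `docs/methods.md` for the modeling assumptions, numerical choices
and known limitations.
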