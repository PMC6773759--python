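"""Trajectory diagnostics: covered area, MSD, nearest-target distances."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gmean, kstest

from chemopursuit import (
    ScenarioConfig,
    covered_area,
    msd,
    nearest_target_distances,
    rayleigh_nn_density,
    run_simulation,
)
from chemopursuit.presets import PRESETS

RHO = 1e-5  # standard target density, 1/μm²


class TestCoveredArea:
    def test_stationary_agent_one_patch(self):
        traj = np.tile([123.0, 456.0], (50, 1))
        assert np.all(covered_area(traj) == 100.0)

    def test_revisits_counted_once(self):
        traj = np.array([[5.0, 5.0], [15.0, 5.0], [5.0, 5.0], [25.0, 5.0]])
        assert covered_area(traj).tolist() == [100.0, 200.0, 200.0, 300.0]

    def test_ballistic_growth_linear(self):
        """A fast fully persistent walker covers new patches at a steady
        rate: A(t) grows ~linearly before wrap-around."""
        cfg = ScenarioConfig(
            strategy=PRESETS["bls"].params, N_tar=0, T_sim=100
        )
        res = run_simulation(cfg, 2)
        A = covered_area(res.immune_folded, 10.0, cfg.L_sys)
        assert A[-1] >= 0.5 * A.size * 100.0 * 0.5  # at least half a patch per 2 steps
        assert np.all(np.diff(A) >= 0)
        corr = np.corrcoef(np.arange(A.size), A)[0, 1]
        assert corr > 0.99

    def test_bounded_by_system_area(self):
        traj = np.random.default_rng(0).uniform(0, 1000, size=(5000, 2))
        assert covered_area(traj)[-1] <= 1000.0**2


class TestMSD:
    def test_ballistic_closed_form(self):
        """A straight unit-speed trajectory has R²(Δt) = Δt² exactly."""
        t = np.arange(60.0)
        traj = np.stack([t * np.cos(0.4), t * np.sin(0.4)], axis=1)
        lags = np.arange(1, 60.0)
        assert np.allclose(msd(traj), lags**2, rtol=1e-12)

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            msd(np.zeros((1, 2)))

    def test_diffusive_large_lag_exponent(self):
        """Non-persistent walks are diffusive: the log-log slope of
        R²(Δt) at large lag is ≈ 1."""
        from chemopursuit import AgentState, WalkParams, advance

        rng = np.random.default_rng(1)
        curves = []
        for _ in range(40):
            state = AgentState.create((0.0, 0.0), rng.uniform(0, 2 * np.pi))
            traj = [state.unwrapped_position]
            for _ in range(300):
                state = advance(state, WalkParams(v=3.0, eps=0.0), rng, L_sys=1e9)
                traj.append(state.unwrapped_position)
            curves.append(msd(np.array(traj)))
        mean_msd = np.mean(curves, axis=0)
        lags = np.arange(1, 301)
        m = (lags >= 30) & (lags <= 150)
        slope = np.polyfit(np.log(lags[m]), np.log(mean_msd[m]), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_persistent_walk_ballistic_at_all_lags(self):
        """With ε = 1 and Rayleigh widths, R²(Δt)/Δt² approaches the
        squared mean step width at large lag."""
        from chemopursuit import AgentState, WalkParams, advance

        rng = np.random.default_rng(2)
        ratios = []
        for _ in range(30):
            state = AgentState.create((0.0, 0.0), rng.uniform(0, 2 * np.pi))
            traj = [state.unwrapped_position]
            for _ in range(200):
                state = advance(state, WalkParams(v=3.0, eps=1.0), rng, L_sys=1e9)
                traj.append(state.unwrapped_position)
            r2 = msd(np.array(traj))
            ratios.append(r2[149] / 150.0**2)
        assert np.mean(ratios) == pytest.approx(9.0, rel=0.05)


class TestNearestTargetDistances:
    def test_static_pair_constant(self):
        T = 10
        imm = np.tile([100.0, 100.0], (T, 1))
        tar = np.tile([100.0, 160.0], (T, 1, 1))
        alive = np.ones((T, 1), dtype=bool)
        d = nearest_target_distances(imm, tar, alive, 1000.0)
        assert np.allclose(d, 60.0)

    def test_dead_steps_skipped(self):
        imm = np.zeros((4, 2))
        tar = np.tile([50.0, 0.0], (4, 1, 1))
        alive = np.array([[True], [False], [False], [True]])
        assert len(nearest_target_distances(imm, tar, alive, 1000.0)) == 2

    def test_uncorrelated_placements_follow_rayleigh(self):
        """Independent uniform placements at the standard density follow
        the nearest-neighbor law.  With exactly 10 targets in the box
        the survival function is (1 − πd²/A)^10 (mean 152.5 μm by
        quadrature), which converges to the Rayleigh form
        exp(−πρd²) (mean 158 μm) in the Poisson limit."""
        rng = np.random.default_rng(3)
        n_cfg = 20000
        imm = rng.uniform(0, 1000, size=(n_cfg, 2))
        tar = rng.uniform(0, 1000, size=(n_cfg, 10, 2))
        alive = np.ones((n_cfg, 10), dtype=bool)
        d = nearest_target_distances(imm, tar, alive, 1000.0)
        assert d.mean() == pytest.approx(152.478, rel=0.01)
        assert d.mean() == pytest.approx(1 / (2 * np.sqrt(RHO)), rel=0.05)
        exact_cdf = lambda x: 1 - np.clip(1 - np.pi * x**2 / 1e6, 0, None) ** 10
        assert kstest(d, exact_cdf).statistic < 0.01
        # the sup-distance between the exact finite-N CDF and the
        # Poisson-limit Rayleigh CDF is 0.028 analytically
        rayleigh_cdf = lambda x: 1 - np.exp(-np.pi * RHO * x**2)
        assert kstest(d, rayleigh_cdf).statistic < 0.028 + 0.015


class TestRayleighDensity:
    def test_normalization(self):
        total, _ = quad(lambda d: rayleigh_nn_density(RHO, d), 0, 2000)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_mean_at_standard_density(self):
        mean, _ = quad(lambda d: d * rayleigh_nn_density(RHO, d), 0, 5000)
        assert mean == pytest.approx(1 / (2 * np.sqrt(RHO)), rel=1e-6)
        assert mean == pytest.approx(158.1, abs=0.1)

    def test_mode_location(self):
        mode = 1 / np.sqrt(2 * np.pi * RHO)
        d = np.linspace(1.0, 1000.0, 5000)
        p = rayleigh_nn_density(RHO, d)
        assert d[np.argmax(p)] == pytest.approx(mode, rel=1e-2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rayleigh_nn_density(0.0, 10.0)
        with pytest.raises(ValueError):
            rayleigh_nn_density(RHO, -1.0)


@pytest.fixture(scope="module")
def paired_runs():
    out = {}
    for name, blind_off in (("tgs", "c_A1"), ("sgs", "c_R1")):
        guided = PRESETS[name].params
        blinded = replace(guided, **{blind_off: 0})
        pairs = []
        for seed in range(12):
            rg = run_simulation(
                ScenarioConfig(strategy=guided, T_sim=300, eliminate_on_contact=False),
                9000 + seed,
            )
            rb = run_simulation(
                ScenarioConfig(strategy=blinded, T_sim=300, eliminate_on_contact=False),
                9000 + seed,
            )
            pairs.append((rg, rb))
        out[name] = pairs
    return out


class TestGuidedVersusBlinded:
    """Localization signatures of goal-directed search, measured under
    the persistent-target observation protocol (targets keep emitting
    after contact, so a guided cell can stay bound to them)."""

    @pytest.mark.parametrize("name", ["tgs", "sgs"])
    def test_guided_msd_reduced_at_large_lag(self, paired_runs, name):
        g = [msd(rg.immune_unwrapped)[99:200].mean() for rg, _ in paired_runs[name]]
        b = [msd(rb.immune_unwrapped)[99:200].mean() for _, rb in paired_runs[name]]
        assert gmean(g) < gmean(b)

    @pytest.mark.parametrize("name", ["tgs", "sgs"])
    def test_guided_nn_mass_shifted_to_zero(self, paired_runs, name):
        """Guided search piles nearest-target distances near zero
        (exponential-like) compared with the Rayleigh-like blinded
        reference: far more mass below 50 μm."""
        def mass(res):
            d = nearest_target_distances(
                res.immune_folded, res.target_folded, res.target_alive, 1000.0
            )
            return np.mean(d <= 50.0)

        g = np.mean([mass(rg) for rg, _ in paired_runs[name]])
        b = np.mean([mass(rb) for _, rb in paired_runs[name]])
        assert g > 2 * b
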