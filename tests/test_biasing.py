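import numpy as np
import pytest

from pathmetad.biasing import (
    BiasState,
    CVWall,
    RatchetState,
    WellTemperedConfig,
    convergence_monitor,
    deposit_hill,
    evaluate_bias,
    free_energy_estimate,
    ratchet_bias,
    run_metadynamics,
    wt_hill_height,
)
from pathmetad.constants import KB_KCAL
from pathmetad.errors import ConfigError, InputError
from pathmetad.toy_systems import make_double_well


def cfg_1d(w=0.4, tau=0.5, sigma=0.12, delta_t=3000.0):
    return WellTemperedConfig(w=w, tau=tau, temperature=300.0, delta_t=delta_t,
                              sigma=(sigma,), cv_names=("x",))


class TestRatchet:
    def test_never_fires_while_improving(self):
        state = RatchetState.initialize(chi0_value=2.0, chi_target=0.0, k=10.0)
        for chi in [1.8, 1.5, 1.0, 0.4, 0.1]:
            energy, dedchi, state = ratchet_bias(chi, state)
            assert energy == 0.0 and dedchi == 0.0
        assert state.running_best == pytest.approx(0.1)

    def test_hand_computed_penalty(self):
        state = RatchetState(chi_target=0.0, k=10.0, running_best=0.2)
        energy, dedchi, new_state = ratchet_bias(0.5, state)
        assert energy == pytest.approx(0.5 * 10.0 * 0.3**2)  # 0.45
        assert dedchi == pytest.approx(10.0 * 0.3)
        assert new_state.running_best == pytest.approx(0.2)  # unchanged

    def test_running_best_is_prefix_minimum(self, rng):
        series = rng.normal(loc=1.0, scale=0.5, size=200)
        state = RatchetState.initialize(series[0], chi_target=0.0, k=10.0)
        bests = []
        for chi in series:
            _, _, state = ratchet_bias(chi, state)
            bests.append(state.running_best)
        np.testing.assert_array_equal(bests, np.minimum.accumulate(series))

    def test_negative_elastic_constant_rejected(self):
        with pytest.raises(ConfigError):
            RatchetState.initialize(1.0, 0.0, k=-1.0)


class TestHillHeight:
    def test_initial_height_is_w(self):
        assert wt_hill_height(0.0, cfg_1d()) == pytest.approx(0.4)

    def test_unit_exponent(self):
        cfg = cfg_1d()
        assert wt_hill_height(KB_KCAL * cfg.delta_t, cfg) == pytest.approx(0.4 * np.exp(-1))

    def test_standard_metadynamics_limit(self):
        cfg = cfg_1d(delta_t=1e14)
        assert wt_hill_height(5.0, cfg) == pytest.approx(0.4, rel=1e-9)

    def test_strictly_decreasing(self):
        cfg = cfg_1d()
        heights = [wt_hill_height(v, cfg) for v in np.linspace(0, 5, 20)]
        assert np.all(np.diff(heights) < 0)


class TestDeposition:
    def test_first_hill_height(self):
        state = BiasState(cfg_1d())
        rec = state.deposit(np.array([0.0]), 0.5)
        assert rec.height == pytest.approx(0.4)

    def test_second_hill_same_point_damped(self):
        cfg = cfg_1d()
        state = BiasState(cfg)
        deposit_hill(state, [0.0], 0.5)
        rec = state.deposit(np.array([0.0]), 1.0)
        assert rec.height == pytest.approx(0.4 * np.exp(-0.4 / (KB_KCAL * cfg.delta_t)))

    def test_distant_hills_keep_full_height(self):
        state = BiasState(cfg_1d())
        for i in range(5):
            state.deposit(np.array([i * 8 * 0.12]), i + 1.0)
        np.testing.assert_allclose(state.heights(), 0.4, atol=1e-9)

    def test_non_finite_cv_rejected(self):
        state = BiasState(cfg_1d())
        with pytest.raises(InputError):
            state.deposit(np.array([np.nan]), 1.0)

    def test_heights_non_increasing_at_revisited_point(self):
        state = BiasState(cfg_1d())
        for t in range(20):
            state.deposit(np.array([0.0]), float(t + 1))
        assert np.all(np.diff(state.heights()) < 0)


class TestEvaluation:
    def test_empty_state_is_zero(self):
        state = BiasState(cfg_1d())
        assert evaluate_bias(state, [0.3]) == 0.0

    def test_hill_center_and_one_sigma(self):
        state = BiasState(cfg_1d())
        state.deposit(np.array([0.0]), 0.5)
        assert evaluate_bias(state, [0.0]) == pytest.approx(0.4)
        assert evaluate_bias(state, [0.12]) == pytest.approx(0.4 * np.exp(-0.5))

    def test_grid_matches_exact_summation(self, rng):
        cfg = cfg_1d()
        state = BiasState(cfg)
        for t in range(200):
            state.deposit(np.array([rng.uniform(-1, 1)]), float(t + 1))
        for x in np.linspace(-1, 1, 41):
            exact = state.evaluate(np.array([x]))
            gridded = state.evaluate_grid(np.array([x]))
            assert gridded == pytest.approx(exact, abs=1e-3 * cfg.w)

    def test_gradient_matches_finite_difference(self, rng):
        state = BiasState(WellTemperedConfig(sigma=(0.12, 0.4), cv_names=("a", "b")))
        for t in range(30):
            state.deposit(rng.uniform(-1, 1, size=2), float(t + 1))
        pt = np.array([0.1, -0.2])
        g = state.gradient(pt, exact=True)
        eps = 1e-7
        for i in range(2):
            dp = pt.copy()
            dp[i] += eps
            num = (state.evaluate(dp) - state.evaluate(pt)) / eps
            assert g[i] == pytest.approx(num, rel=1e-5, abs=1e-8)


class TestFreeEnergyEstimate:
    def test_prefactor_is_minus_1p1_v(self):
        # ΔT = 10 T makes the estimator exactly -1.1 V (before min-shift)
        state = BiasState(cfg_1d())
        state.deposit(np.array([0.0]), 0.5)
        state.deposit(np.array([0.3]), 1.0)
        surf = free_energy_estimate(state)
        v = state.evaluate(surf.axes[0].centers[:, None])
        expected = -1.1 * v
        expected -= expected.min()
        np.testing.assert_allclose(surf.values, expected, atol=1e-12)

    def test_single_hill_minimum_at_center(self):
        state = BiasState(cfg_1d())
        state.deposit(np.array([0.25]), 0.5)
        surf = free_energy_estimate(state)
        x_min = surf.axes[0].centers[np.argmin(surf.values)]
        assert x_min == pytest.approx(0.25, abs=0.01)

    def test_no_hills_rejected(self):
        with pytest.raises(InputError):
            free_energy_estimate(BiasState(cfg_1d()))


class TestRunMetadynamics:
    def test_zero_height_reproduces_unbiased(self):
        pot = make_double_well(2.0)
        t1, _ = run_metadynamics(pot, cfg_1d(w=0.0), steps=2000, dt=0.002, seed=42)
        t2, s2 = run_metadynamics(pot, cfg_1d(w=0.0), steps=2000, dt=0.002, seed=42)
        np.testing.assert_array_equal(t1.cvs, t2.cvs)
        assert s2.n_hills == 0

    def test_hill_times_are_multiples_of_tau(self):
        pot = make_double_well(2.0)
        _, state = run_metadynamics(pot, cfg_1d(tau=0.1), steps=2000, dt=0.002, seed=0)
        expected = np.arange(1, state.n_hills + 1) * 0.1
        np.testing.assert_allclose(state.times, expected, atol=1e-12)

    def test_zero_steps(self):
        pot = make_double_well(2.0)
        traj, state = run_metadynamics(pot, cfg_1d(), steps=0, dt=0.002, seed=0)
        assert traj.n_frames == 1 and state.n_hills == 0

    def test_same_seed_bit_identical(self):
        pot = make_double_well(2.0)
        t1, s1 = run_metadynamics(pot, cfg_1d(), steps=3000, dt=0.002, seed=7)
        t2, s2 = run_metadynamics(pot, cfg_1d(), steps=3000, dt=0.002, seed=7)
        np.testing.assert_array_equal(t1.cvs, t2.cvs)
        np.testing.assert_array_equal(s1.heights(), s2.heights())

    def test_biased_runs_escape_where_unbiased_do_not(self):
        # 5 kcal/mol barrier: thermal escape takes ~1 ns, far beyond the
        # 120 ps window, while the bias fills the well within ~30 ps
        pot = make_double_well(5.0)
        n_biased = n_unbiased = 0
        for seed in (3, 4, 5):
            biased, _ = run_metadynamics(pot, cfg_1d(), steps=60_000, dt=0.002, seed=seed)
            unbiased, _ = run_metadynamics(pot, cfg_1d(w=0.0), steps=60_000, dt=0.002, seed=seed)
            n_biased += biased.cvs[:, 0].max() > 0.5
            n_unbiased += unbiased.cvs[:, 0].max() > 0.5
        assert n_biased == 3
        assert n_unbiased <= 1

    def test_wall_confines_cv(self):
        pot = make_double_well(0.5)
        walls = [CVWall(0, lower=-1.5, upper=1.5, k=500.0)]
        traj, _ = run_metadynamics(pot, cfg_1d(), steps=40_000, dt=0.002, seed=5,
                                   walls=walls)
        assert traj.cvs[:, 0].max() < 2.0
        assert traj.cvs[:, 0].min() > -2.0


class TestConvergenceMonitor:
    def test_symmetric_well_difference_vanishes(self):
        pot = make_double_well(1.5)
        _, state = run_metadynamics(pot, cfg_1d(tau=0.25), steps=150_000, dt=0.002, seed=11)
        res = convergence_monitor(
            state,
            checkpoints=np.linspace(20.0, state.times[-1], 8),
            region_a=lambda p: p[:, 0] < 0.0,
            region_b=lambda p: p[:, 0] > 0.0,
        )
        assert abs(res["delta_f"][-1]) < 0.5
        assert np.isfinite(res["trailing_fluctuation"])

    def test_asymmetric_offset_recovered(self):
        pot = make_double_well(1.5, asymmetry=1.0)
        _, state = run_metadynamics(pot, cfg_1d(tau=0.25), steps=150_000, dt=0.002, seed=12)
        res = convergence_monitor(
            state,
            checkpoints=np.linspace(20.0, state.times[-1], 8),
            region_a=lambda p: p[:, 0] < 0.0,
            region_b=lambda p: p[:, 0] > 0.0,
        )
        assert res["delta_f"][-1] == pytest.approx(pot.minima_energy_difference, abs=0.5)

    def test_empty_region_rejected(self):
        state = BiasState(cfg_1d())
        state.deposit(np.array([0.0]), 0.5)
        with pytest.raises(InputError):
            convergence_monitor(state, [0.5, 1.0],
                                region_a=lambda p: p[:, 0] > 1e9,
                                region_b=lambda p: p[:, 0] < 1e9)
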