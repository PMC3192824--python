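import numpy as np
import pytest

from pathmetad.constants import KB_KCAL
from pathmetad.errors import InputError
from pathmetad.toy_systems import (
    TwoStateNetworkSystem,
    baoab_step,
    interpolated_trajectory,
    make_double_well,
    make_double_well_2d,
    make_harmonic,
    make_mini_receptor,
    make_two_state_chain,
    overdamped_step,
)

KBT = KB_KCAL * 300.0


class TestDoubleWell:
    def test_symmetric_minima_and_barrier(self):
        pot = make_double_well(3.0)
        locs = sorted(m[0][0] for m in pot.minima)
        assert locs == pytest.approx([-1.0, 1.0])
        assert pot.minima[0][1] == pytest.approx(pot.minima[1][1])
        assert pot.barrier == pytest.approx(3.0)

    def test_tilted_minima_split_by_asymmetry(self):
        pot = make_double_well(3.0, asymmetry=1.0)
        # first-order perturbation: ΔU ≈ a; exact value from root-finding
        assert pot.minima_energy_difference == pytest.approx(1.0, abs=0.05)
        # stationarity of the stored minima
        for loc, _ in pot.minima:
            assert abs(pot.gradient(loc)[0]) < 1e-9

    @pytest.mark.parametrize("factory", [
        lambda: make_double_well(2.0, asymmetry=0.7),
        lambda: make_double_well_2d(2.0, asymmetry=0.7, k_perp=3.0),
        lambda: make_harmonic(4.0, center=0.3),
    ])
    def test_gradient_matches_finite_difference(self, factory, rng):
        pot = factory()
        for _ in range(10):
            x = rng.uniform(-1.5, 1.5, size=pot.dimension)
            g = pot.gradient(x)
            eps = 1e-6
            for i in range(pot.dimension):
                dx = x.copy()
                dx[i] += eps
                num = (pot.energy(dx) - pot.energy(x)) / eps
                assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_invalid_barrier_rejected(self):
        with pytest.raises(InputError):
            make_double_well(-1.0)


class TestLangevin:
    def test_gradient_descent_limit(self):
        # T = 0 with strong friction: inertial dynamics relaxes into the
        # nearest minimum (no thermal noise at zero temperature)
        pot = make_double_well(2.0)
        rng = np.random.default_rng(0)
        x = np.array([0.4])
        v = np.zeros(1)
        f = pot.force(x)
        for _ in range(20000):
            x, v, f = baoab_step(x, v, f, pot.force, 0.002, 50.0, 0.0, 12.0, rng)
        assert x[0] == pytest.approx(1.0, abs=1e-4)  # nearest minimum

    def test_harmonic_equipartition_overdamped(self):
        k = 5.0
        pot = make_harmonic(k)
        rng = np.random.default_rng(1)
        x = np.array([0.0])
        f = pot.force(x)
        samples = []
        for i in range(400_000):
            x, f = overdamped_step(x, pot.force, 0.005, 1.0, 300.0, rng, f=f)
            if i % 5 == 0:
                samples.append(x[0])
        var = np.var(samples)
        assert var == pytest.approx(KBT / k, rel=0.02)

    def test_harmonic_equipartition_baoab(self):
        k = 5.0
        pot = make_harmonic(k)
        rng = np.random.default_rng(2)
        x = np.array([0.0])
        v = np.zeros(1)
        f = pot.force(x)
        samples = []
        for i in range(400_000):
            x, v, f = baoab_step(x, v, f, pot.force, 0.005, 2.0, 300.0, 12.0, rng)
            if i % 5 == 0:
                samples.append(x[0])
        assert np.var(samples) == pytest.approx(KBT / k, rel=0.02)

    def test_same_seed_bit_identical(self):
        pot = make_double_well(2.0)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            x = np.array([-1.0])
            f = pot.force(x)
            xs = []
            for _ in range(1000):
                x, f = overdamped_step(x, pot.force, 0.002, 1.0, 300.0, rng, f=f)
                xs.append(x[0])
            out.append(np.array(xs))
        np.testing.assert_array_equal(out[0], out[1])

    def test_boltzmann_density_recovered(self):
        """Long unbiased sampling reproduces exp(-U/kBT) (L1 < 0.05)."""
        pot = make_double_well(0.5)
        rng = np.random.default_rng(3)
        x = np.array([-1.0])
        f = pot.force(x)
        samples = np.empty(250_000)
        for i in range(1_000_000):
            x, f = overdamped_step(x, pot.force, 0.002, 1.0, 300.0, rng, f=f)
            if i % 4 == 0:
                samples[i // 4] = x[0]
        edges = np.linspace(-1.8, 1.8, 41)
        hist, _ = np.histogram(samples, bins=edges, density=False)
        hist = hist / hist.sum()
        centers = 0.5 * (edges[1:] + edges[:-1])
        boltz = np.exp(-np.array([pot.energy(np.array([c])) for c in centers]) / KBT)
        boltz /= boltz.sum()
        assert np.abs(hist - boltz).sum() < 0.05


class TestMiniReceptor:
    def test_inactive_descriptor_targets(self, mini_receptor):
        from pathmetad.descriptors import compute_descriptors

        vals = compute_descriptors(mini_receptor.inactive, mini_receptor.inactive,
                                   mini_receptor.residue_map, mini_receptor.align_mask)
        assert vals.d_il == pytest.approx(3.0, abs=0.1)
        assert vals.chi_ts == pytest.approx(163.0, abs=1.0)
        assert vals.delta_d_tm6 == pytest.approx(0.0, abs=0.1)

    def test_active_descriptor_targets(self, mini_receptor):
        from pathmetad.descriptors import compute_descriptors

        vals = compute_descriptors(mini_receptor.active, mini_receptor.inactive,
                                   mini_receptor.residue_map, mini_receptor.align_mask)
        assert vals.d_il == pytest.approx(12.0, abs=0.1)
        assert vals.chi_ts == pytest.approx(55.0, abs=1.0)
        assert vals.delta_d_tm6 == pytest.approx(5.9, abs=0.1)

    def test_deterministic_construction(self):
        a = make_mini_receptor(seed=5)
        b = make_mini_receptor(seed=5)
        np.testing.assert_array_equal(a.inactive.coords, b.inactive.coords)
        np.testing.assert_array_equal(a.active.coords, b.active.coords)

    def test_end_states_are_local_minima_of_network_energy(self, mini_receptor):
        system = mini_receptor.system()
        rng = np.random.default_rng(0)
        for x_state, q_star in zip((system.x_in, system.x_ac),
                                   [q for q, _ in system.minima_q]):
            # the nearby tilted minimum along the mode
            x_min = system.x_in + q_star * system.disp
            e0 = system.energy(x_min)
            for _ in range(20):
                pert = rng.normal(size=x_min.shape)
                pert /= np.linalg.norm(pert)
                assert system.energy(x_min + 0.05 * pert) > e0

    def test_collective_mode_ground_truth(self, mini_receptor):
        system = mini_receptor.system(barrier=2.0, asymmetry=1.0)
        (q_lo, e_lo), (q_hi, e_hi) = sorted(system.minima_q)
        assert q_lo == pytest.approx(0.0, abs=0.05)
        assert q_hi == pytest.approx(1.0, abs=0.05)
        assert e_hi - e_lo == pytest.approx(1.0, abs=0.05)
        q_sad, e_sad = system.saddle_q
        assert 0.4 < q_sad < 0.6
        assert e_sad - e_lo == pytest.approx(2.5, abs=0.1)

    def test_network_force_matches_finite_difference(self, mini_receptor):
        system = mini_receptor.system()
        rng = np.random.default_rng(4)
        x = system.x_in + 0.3 * rng.normal(size=system.n_dof)
        f = system.force(x)
        eps = 1e-6
        for i in rng.choice(system.n_dof, size=10, replace=False):
            dx = x.copy()
            dx[i] += eps
            num = -(system.energy(dx) - system.energy(x)) / eps
            assert f[i] == pytest.approx(num, abs=1e-4)


class TestTwoStateChain:
    def test_end_states_differ_by_roughly_requested_rmsd(self):
        from pathmetad.geometry import rmsd

        inactive, active = make_two_state_chain(6, 5.0, seed=0)
        assert 3.0 < rmsd(inactive, active) < 5.5

    def test_mismatched_states_rejected(self, mini_receptor):
        inactive, _ = make_two_state_chain(6, 5.0)
        with pytest.raises(InputError):
            TwoStateNetworkSystem(inactive, mini_receptor.active, barrier=1.0)


class TestInterpolatedTrajectory:
    def test_midpoint_is_coordinate_average(self, mini_receptor):
        frames = interpolated_trajectory(mini_receptor, 3, noise_sigma=0.0)
        expected = 0.5 * (mini_receptor.inactive.coords + mini_receptor.active.coords)
        np.testing.assert_allclose(frames[1].coords, expected)

    def test_endpoints_noise_free(self, mini_receptor):
        frames = interpolated_trajectory(mini_receptor, 5, noise_sigma=0.5, seed=1)
        np.testing.assert_array_equal(frames[0].coords, mini_receptor.inactive.coords)
        np.testing.assert_array_equal(frames[-1].coords, mini_receptor.active.coords)

    def test_rmsd_to_inactive_increases(self, mini_receptor):
        from pathmetad.geometry import rmsd

        frames = interpolated_trajectory(mini_receptor, 8, noise_sigma=0.0)
        dists = [rmsd(f, mini_receptor.inactive, mask=mini_receptor.ca_mask)
                 for f in frames]
        assert np.all(np.diff(dists) > 0)

    def test_too_few_frames_rejected(self, mini_receptor):
        with pytest.raises(InputError):
            interpolated_trajectory(mini_receptor, 1)
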