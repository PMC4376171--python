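import numpy as np
import pytest

from oxypath.errors import ParameterError, SimulationError
from oxypath.les import (
    CagePotential,
    LESConfig,
    ToySystem,
    default_toy_system,
    first_passage_stats,
    les_forces,
    plain_forces,
    simulate_langevin,
    simulate_les,
    total_energy,
)


def _bare_system(n_copies=1, **kw):
    pot = kw.pop("potential", CagePotential(portals=()))
    return ToySystem(copy_pos=np.zeros((n_copies, 3)),
                     env_pos=np.zeros((0, 3)), potential=pot, **kw)


class TestLESForces:
    def test_n1_equals_unscaled(self, rng):
        sys = default_toy_system(n_copies=1, seed=4)
        sys.copy_pos = rng.normal(size=(1, 3)) * 3
        cfg = LESConfig(n_copies=1)
        f_les = les_forces(sys, cfg)
        f_plain = plain_forces(sys)
        assert np.array_equal(f_les[0], f_plain[0])
        assert np.array_equal(f_les[1], f_plain[1])

    def test_two_coincident_copies_linearity(self, rng):
        """Two copies at the same point with N=2 exert the same force on the
        environment as one unscaled copy there."""
        p = rng.normal(size=3) * 2
        sys2 = default_toy_system(n_copies=2, seed=0)
        sys2.copy_pos = np.stack([p, p])
        sys1 = default_toy_system(n_copies=1, seed=0)
        sys1.copy_pos = p[None, :]
        _, f_env2 = les_forces(sys2, LESConfig(n_copies=2))
        _, f_env1 = plain_forces(sys1)
        assert np.allclose(f_env2, f_env1, rtol=1e-12, atol=1e-12)

    def test_copy_copy_force_is_zero(self, rng):
        """Moving other copies around never changes a copy's force."""
        sys = default_toy_system(n_copies=3, seed=1)
        cfg = LESConfig(n_copies=3)
        f0 = les_forces(sys, cfg)[0][0].copy()
        sys.copy_pos[1:] += rng.normal(size=(2, 3)) * 5
        f1 = les_forces(sys, cfg)[0][0]
        assert np.array_equal(f0, f1)

    def test_matches_bruteforce(self, rng):
        """Oracle: explicit python loops over scaled pair sums."""
        for _ in range(10):
            n, m = 14, 5
            sys = default_toy_system(n_copies=n, n_env=m, seed=0)
            sys.copy_pos = rng.normal(size=(n, 3)) * 4
            sys.env_pos = rng.normal(size=(m, 3)) * 4
            cfg = LESConfig(n_copies=n)
            f_c, f_e = les_forces(sys, cfg)

            s = 1.0 / n
            exp_c = np.zeros((n, 3))
            exp_e = np.zeros((m, 3))
            for i in range(n):
                exp_c[i] += s * sys.potential.force(sys.copy_pos[i][None, :])[0]
                for j in range(m):
                    d = sys.copy_pos[i] - sys.env_pos[j]
                    pref = (sys.pair_eps / sys.pair_sigma**2) * np.exp(
                        -(d @ d) / (2 * sys.pair_sigma**2))
                    exp_c[i] += s * pref * d
                    exp_e[j] -= s * pref * d
            for j in range(m):
                exp_e[j] += -sys.tether_k * (sys.env_pos[j] - sys.env_home[j])
            assert np.allclose(f_c, exp_c, rtol=1e-9, atol=1e-12)
            assert np.allclose(f_e, exp_e, rtol=1e-9, atol=1e-12)

    def test_force_is_minus_gradient(self, rng):
        pot = CagePotential(portals=(((1.0, 0.0, 0.0), 0.7, 2.0),),
                            tilt=np.array([0.1, -0.2, 0.05]))
        x = rng.normal(size=(6, 3)) * 5
        f = pot.force(x)
        eps = 1e-6
        for d in range(3):
            dx = np.zeros(3)
            dx[d] = eps
            num = (pot.energy(x + dx) - pot.energy(x - dx)) / (2 * eps)
            assert np.allclose(f[:, d], -num, atol=1e-5)

    def test_scaling_is_exactly_one_over_n(self):
        for n in (1, 2, 14):
            assert LESConfig(n_copies=n).scaling == 1.0 / n

    def test_nonfinite_force_reported(self):
        sys = _bare_system()
        sys.potential.tilt = np.array([np.inf, 0.0, 0.0])  # corrupt after init
        with pytest.raises(SimulationError, match="non-finite"):
            les_forces(sys, LESConfig(n_copies=1))


class TestSimulate:
    def test_stationary_at_minimum(self):
        sys = _bare_system()  # portal-free cage: origin is a critical point
        cfg = LESConfig(n_copies=1, temperature=0.0, friction=1.0, n_steps=200)
        res = simulate_les(sys, cfg)
        assert np.abs(res.copy_traj).max() == 0.0

    def test_same_seed_identical(self):
        sys = default_toy_system(n_copies=4, seed=2)
        cfg = LESConfig(n_copies=4, n_steps=300, seed=42)
        a = simulate_les(sys.clone(), cfg)
        b = simulate_les(sys.clone(), cfg)
        assert np.array_equal(a.copy_traj, b.copy_traj)
        assert np.array_equal(a.env_traj, b.env_traj)

    def test_n1_les_bit_identical_to_plain_langevin(self):
        sys = default_toy_system(n_copies=1, seed=3)
        cfg = LESConfig(n_copies=1, n_steps=400, temperature=0.8,
                        friction=2.0, seed=9)
        a = simulate_les(sys.clone(), cfg)
        b = simulate_langevin(sys.clone(), cfg)
        assert np.array_equal(a.copy_traj, b.copy_traj)
        assert np.array_equal(a.env_traj, b.env_traj)

    def test_equipartition(self):
        sys = default_toy_system(n_copies=14, seed=3)
        cfg = LESConfig(n_copies=14, n_steps=20000, temperature=1.3,
                        friction=2.0, timestep=0.01, seed=1, stride=10)
        res = simulate_les(sys, cfg)
        tail = res.kinetic_temperature[len(res.kinetic_temperature) // 5:]
        assert tail.mean() == pytest.approx(1.3, rel=0.05)

    def test_energy_drift_bounded(self):
        """Symplectic-style check: gamma = T = 0, small timestep."""
        sys = _bare_system()
        sys.copy_pos[0] = [2.0, 0.5, -0.5]
        cfg = LESConfig(n_copies=1, temperature=0.0, friction=0.0,
                        timestep=0.002, n_steps=2000, stride=2000)
        res = simulate_les(sys.clone(), cfg)
        e0 = total_energy(sys, cfg)
        e1 = total_energy(sys, cfg, copy_pos=res.copy_traj[-1],
                          env_pos=res.env_traj[-1],
                          copy_vel=res.final_copy_vel, env_vel=res.final_env_vel)
        assert abs(e1 - e0) < 1e-3 * max(abs(e0), 1.0)

    def test_divergence_raises(self):
        pot = CagePotential(well_depth=0.0, barrier_height=0.0,
                            tilt=np.array([50.0, 0.0, 0.0]))
        sys = _bare_system(potential=pot, box_bound=10.0)
        cfg = LESConfig(n_copies=1, temperature=0.0, friction=0.0,
                        timestep=0.05, n_steps=5000)
        with pytest.raises(SimulationError, match="diverged"):
            simulate_les(sys, cfg)

    def test_copy_count_mismatch(self):
        sys = default_toy_system(n_copies=2, seed=0)
        with pytest.raises(ParameterError):
            simulate_les(sys, LESConfig(n_copies=3, n_steps=1))

    def test_config_validation(self):
        with pytest.raises(ParameterError):
            LESConfig(n_copies=0)
        with pytest.raises(ParameterError):
            LESConfig(timestep=0.0)
        with pytest.raises(ParameterError):
            LESConfig(friction=-1.0)


class TestFirstPassage:
    def test_zero_barrier_immediate(self):
        pot = CagePotential(well_depth=0.0, barrier_height=0.0)
        sys = ToySystem(copy_pos=np.zeros((4, 3)), env_pos=np.zeros((0, 3)),
                        potential=pot)
        cfg = LESConfig(n_copies=4, temperature=2.0, friction=1.0,
                        timestep=0.05, n_steps=2000)
        fp = first_passage_stats(sys, cfg, r_escape=1.0, n_replicas=10, seed=1)
        assert not fp.censored.any()
        assert fp.median < 300

    def test_ballistic_passage_analytic(self):
        """Constant tilt, T = gamma = 0: velocity Verlet reproduces the
        x(t) = g t^2 / 2 parabola exactly, so the first-passage step must
        match the closed-form ceil(sqrt(2 d / g) / dt)."""
        g, d, dt = 0.5, 8.0, 0.01
        pot = CagePotential(well_depth=0.0, barrier_height=0.0,
                            tilt=np.array([g, 0.0, 0.0]))
        sys = ToySystem(copy_pos=np.zeros((1, 3)), env_pos=np.zeros((0, 3)),
                        potential=pot, box_bound=1e6)
        cfg = LESConfig(n_copies=1, temperature=0.0, friction=0.0,
                        timestep=dt, n_steps=10000)
        fp = first_passage_stats(sys, cfg, r_escape=d, n_replicas=1, seed=0)
        t_star = np.sqrt(2 * d / g)
        assert abs(fp.steps[0] - np.ceil(t_star / dt)) <= 1

    def test_censoring_flagged(self):
        sys = default_toy_system(n_copies=1, seed=0)
        cfg = LESConfig(n_copies=1, temperature=0.05, friction=1.0,
                        timestep=0.01, n_steps=50)
        fp = first_passage_stats(sys, cfg, r_escape=12.0, n_replicas=3, seed=2)
        assert fp.censored.all()
        assert np.isinf(fp.steps).all()
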