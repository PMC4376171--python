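"""Toy locally-enhanced-sampling (LES) Langevin dynamics.

The contract being modelled: N ligand copies that (i) do not interact with
each other and (ii) interact with the rest of the system at a scaling
factor of exactly 1/N.  Everything else (potential shape, integrator) is a
deliberately minimal stand-in: point-particle copies inside a spherically
capped cage whose barrier carries Gaussian portal depressions, plus a few
harmonically tethered environment particles.

Integrator: BAOAB Langevin splitting; with friction = 0 it reduces to
velocity Verlet.  Reduced units with kB = 1.  All particles (copies and
environment) share one uniform thermostat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, SimulationError

__all__ = [
    "LESConfig",
    "CagePotential",
    "ToySystem",
    "default_toy_system",
    "les_forces",
    "plain_forces",
    "simulate_les",
    "simulate_langevin",
    "first_passage_stats",
    "total_energy",
]


@dataclass
class LESConfig:
    """LES run parameters; the copy-scaling factor is pinned to 1/N."""

    n_copies: int = 14
    timestep: float = 0.01
    temperature: float = 1.0
    friction: float = 1.0
    n_steps: int = 1000
    seed: int = 0
    stride: int = 1

    def __post_init__(self):
        if self.n_copies < 1:
            raise ParameterError(f"n_copies must be >= 1, got {self.n_copies}")
        if self.timestep <= 0 or self.n_steps < 0 or self.stride < 1:
            raise ParameterError("timestep > 0, n_steps >= 0, stride >= 1 required")
        if self.friction < 0 or self.temperature < 0:
            raise ParameterError("friction and temperature must be >= 0")

    @property
    def scaling(self) -> float:
        """Copy-environment interaction scaling, exactly 1/N."""
        return 1.0 / self.n_copies


@dataclass
class CagePotential:
    """Radial well + barrier shell, with Gaussian depressions at portals.

    U(x) = -D exp(-r^2 / 2 s_w^2) + B exp(-(r - r_b)^2 / 2 w^2)
           - sum_p a_p B exp(-|x - r_b u_p|^2 / 2 s_p^2) - tilt . x
    """

    well_depth: float = 4.0
    well_width: float = 3.0
    barrier_height: float = 6.0
    barrier_radius: float = 7.0
    barrier_width: float = 1.5
    portals: tuple = ()          # (unit direction (3,), depth fraction, width)
    tilt: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def _portal_centers(self):
        return [(self.barrier_radius * np.asarray(u, dtype=float), a, s)
                for u, a, s in self.portals]

    def energy(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        r = np.linalg.norm(x, axis=1)
        u = -self.well_depth * np.exp(-r**2 / (2 * self.well_width**2))
        u += self.barrier_height * np.exp(-(r - self.barrier_radius)**2
                                          / (2 * self.barrier_width**2))
        for c, a, s in self._portal_centers():
            d2 = np.sum((x - c)**2, axis=1)
            u -= a * self.barrier_height * np.exp(-d2 / (2 * s**2))
        u -= x @ np.asarray(self.tilt, dtype=float)
        return u

    def force(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        r = np.linalg.norm(x, axis=1)
        safe_r = np.where(r > 1e-12, r, 1.0)
        g = np.exp(-r**2 / (2 * self.well_width**2))
        f = -(self.well_depth / self.well_width**2) * g[:, None] * x
        h = np.exp(-(r - self.barrier_radius)**2 / (2 * self.barrier_width**2))
        radial = (self.barrier_height * (r - self.barrier_radius)
                  / self.barrier_width**2) * h
        f += np.where(r[:, None] > 1e-12, radial[:, None] * x / safe_r[:, None], 0.0)
        for c, a, s in self._portal_centers():
            d = x - c
            e = np.exp(-np.sum(d**2, axis=1) / (2 * s**2))
            f -= (a * self.barrier_height / s**2) * e[:, None] * d
        f += np.asarray(self.tilt, dtype=float)
        return f


@dataclass
class ToySystem:
    """Copies + tethered environment particles inside a cage potential."""

    copy_pos: np.ndarray                   # (N, 3)
    env_pos: np.ndarray                    # (M, 3)
    potential: CagePotential
    env_home: np.ndarray | None = None     # (M, 3) tether anchors
    copy_vel: np.ndarray | None = None
    env_vel: np.ndarray | None = None
    copy_mass: float = 1.0
    env_mass: float = 1.0
    tether_k: float = 10.0
    pair_eps: float = 1.0                  # copy-env Gaussian repulsion strength
    pair_sigma: float = 1.5
    box_bound: float = 60.0                # |x| beyond this -> integration error

    def __post_init__(self):
        self.copy_pos = np.atleast_2d(np.asarray(self.copy_pos, dtype=float)).copy()
        self.env_pos = (np.zeros((0, 3)) if self.env_pos is None or len(self.env_pos) == 0
                        else np.atleast_2d(np.asarray(self.env_pos, dtype=float)).copy())
        if self.env_home is None:
            self.env_home = self.env_pos.copy()
        if self.copy_vel is None:
            self.copy_vel = np.zeros_like(self.copy_pos)
        if self.env_vel is None:
            self.env_vel = np.zeros_like(self.env_pos)
        e = self.potential.energy(self.copy_pos)
        if not np.all(np.isfinite(e)):
            raise SimulationError("non-finite energy at the initial state")

    @property
    def n_copies(self) -> int:
        return len(self.copy_pos)

    def clone(self) -> "ToySystem":
        return ToySystem(
            copy_pos=self.copy_pos.copy(), env_pos=self.env_pos.copy(),
            potential=self.potential, env_home=self.env_home.copy(),
            copy_vel=self.copy_vel.copy(), env_vel=self.env_vel.copy(),
            copy_mass=self.copy_mass, env_mass=self.env_mass,
            tether_k=self.tether_k, pair_eps=self.pair_eps,
            pair_sigma=self.pair_sigma, box_bound=self.box_bound,
        )


def default_toy_system(n_copies: int = 14, n_env: int = 6,
                       portal_dirs: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
                       portal_depth: float = 0.7, seed: int = 0) -> ToySystem:
    """A small cage with two portals, copies started near the well bottom."""
    rng = np.random.default_rng(seed)
    pot = CagePotential(portals=tuple(
        (np.asarray(u) / np.linalg.norm(u), portal_depth, 2.0) for u in portal_dirs
    ))
    copy_pos = rng.normal(scale=0.5, size=(n_copies, 3))
    ang = np.linspace(0, 2 * np.pi, n_env, endpoint=False)
    env_pos = np.column_stack([4.0 * np.cos(ang), 4.0 * np.sin(ang), np.zeros(n_env)])
    return ToySystem(copy_pos=copy_pos, env_pos=env_pos, potential=pot)


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def _pair_forces(copy_pos: np.ndarray, env_pos: np.ndarray, eps: float, sigma: float):
    """Gaussian repulsion between every copy-environment pair.

    Returns (force on copies (N,3), force on env (M,3)), unscaled.
    """
    if len(env_pos) == 0:
        return np.zeros_like(copy_pos), np.zeros((0, 3))
    d = copy_pos[:, None, :] - env_pos[None, :, :]       # (N, M, 3)
    e = np.exp(-np.sum(d**2, axis=-1) / (2 * sigma**2))  # (N, M)
    f_pair = (eps / sigma**2) * e[:, :, None] * d        # force on copy from env
    return f_pair.sum(axis=1), -f_pair.sum(axis=0)


def _check_finite(f: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(f)):
        bad = int(np.argwhere(~np.isfinite(f))[0, 0])
        raise SimulationError(f"non-finite force on {what} particle {bad}")


def les_forces(system: ToySystem, config: LESConfig):
    """LES forces: copy-copy force is identically zero; every copy feels the
    environment (cage field + env particles) at the 1/N scaling, and each
    environment particle feels the 1/N-scaled sum over copies."""
    s = config.scaling
    f_field = system.potential.force(system.copy_pos)
    f_ce, f_ec = _pair_forces(system.copy_pos, system.env_pos,
                              system.pair_eps, system.pair_sigma)
    f_copies = s * (f_field + f_ce)
    f_env = s * f_ec
    if len(system.env_pos):
        f_env = f_env - system.tether_k * (system.env_pos - system.env_home)
    _check_finite(f_copies, "copy")
    _check_finite(f_env, "environment")
    return f_copies, f_env


def plain_forces(system: ToySystem):
    """Unscaled forces of the ordinary (non-LES) system."""
    f_field = system.potential.force(system.copy_pos)
    f_ce, f_ec = _pair_forces(system.copy_pos, system.env_pos,
                              system.pair_eps, system.pair_sigma)
    f_copies = f_field + f_ce
    f_env = f_ec
    if len(system.env_pos):
        f_env = f_env - system.tether_k * (system.env_pos - system.env_home)
    _check_finite(f_copies, "copy")
    _check_finite(f_env, "environment")
    return f_copies, f_env


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@dataclass
class LESResult:
    copy_traj: np.ndarray    # (n_saved, N, 3)
    env_traj: np.ndarray     # (n_saved, M, 3)
    times: np.ndarray        # (n_saved,)
    kinetic_temperature: np.ndarray  # (n_saved,) instantaneous, all particles
    config: LESConfig
    final_copy_vel: np.ndarray | None = None
    final_env_vel: np.ndarray | None = None


def _integrate(system: ToySystem, config: LESConfig, force_fn,
               stop_fn=None) -> tuple[LESResult, int | None]:
    dt, gamma, T = config.timestep, config.friction, config.temperature
    rng = np.random.default_rng(config.seed)
    x_c, x_e = system.copy_pos.copy(), system.env_pos.copy()
    v_c, v_e = system.copy_vel.copy(), system.env_vel.copy()
    m_c, m_e = system.copy_mass, system.env_mass
    n_c, n_e = len(x_c), len(x_e)
    ndof = 3 * (n_c + n_e)

    c1 = np.exp(-gamma * dt)
    s_c = np.sqrt(T * (1.0 - c1 * c1) / m_c)
    s_e = np.sqrt(T * (1.0 - c1 * c1) / m_e)

    sys_view = system.clone()

    def forces():
        sys_view.copy_pos, sys_view.env_pos = x_c, x_e
        return force_fn(sys_view)

    def kinetic_T():
        ke = 0.5 * m_c * np.sum(v_c**2) + 0.5 * m_e * np.sum(v_e**2)
        return 2.0 * ke / ndof

    saved_c, saved_e, times, temps = [x_c.copy()], [x_e.copy()], [0.0], [kinetic_T()]
    f_c, f_e = forces()
    hit = None
    for step in range(1, config.n_steps + 1):
        v_c += 0.5 * dt * f_c / m_c
        v_e += 0.5 * dt * f_e / m_e
        x_c += 0.5 * dt * v_c
        x_e += 0.5 * dt * v_e
        noise = rng.standard_normal((n_c + n_e, 3))
        v_c = c1 * v_c + s_c * noise[:n_c]
        v_e = c1 * v_e + s_e * noise[n_c:]
        x_c += 0.5 * dt * v_c
        x_e += 0.5 * dt * v_e
        f_c, f_e = forces()
        v_c += 0.5 * dt * f_c / m_c
        v_e += 0.5 * dt * f_e / m_e
        if np.any(np.abs(x_c) > system.box_bound) or \
           (n_e and np.any(np.abs(x_e) > system.box_bound)):
            raise SimulationError(f"trajectory diverged beyond |x| = "
                                  f"{system.box_bound} at step {step}")
        if step % config.stride == 0:
            saved_c.append(x_c.copy())
            saved_e.append(x_e.copy())
            times.append(step * dt)
            temps.append(kinetic_T())
        if stop_fn is not None and stop_fn(x_c):
            hit = step
            break
    result = LESResult(
        copy_traj=np.asarray(saved_c), env_traj=np.asarray(saved_e),
        times=np.asarray(times), kinetic_temperature=np.asarray(temps),
        config=config, final_copy_vel=v_c.copy(), final_env_vel=v_e.copy(),
    )
    return result, hit


def simulate_les(system: ToySystem, config: LESConfig) -> LESResult:
    """Seed-reproducible LES trajectory of all particles."""
    if config.n_copies != system.n_copies:
        raise ParameterError(
            f"config.n_copies ({config.n_copies}) != system copies ({system.n_copies})"
        )
    result, _ = _integrate(system, config, lambda s: les_forces(s, config))
    return result


def simulate_langevin(system: ToySystem, config: LESConfig) -> LESResult:
    """Plain (unscaled) Langevin dynamics with the identical integrator and
    noise stream; the N=1 LES trajectory must be bit-identical to this."""
    result, _ = _integrate(system, config, plain_forces)
    return result


def total_energy(system: ToySystem, config: LESConfig,
                 copy_pos=None, env_pos=None, copy_vel=None, env_vel=None) -> float:
    """Scaled potential + kinetic energy (for drift checks at gamma = T = 0)."""
    s = config.scaling
    x_c = system.copy_pos if copy_pos is None else np.asarray(copy_pos)
    x_e = system.env_pos if env_pos is None else np.asarray(env_pos)
    v_c = system.copy_vel if copy_vel is None else np.asarray(copy_vel)
    v_e = system.env_vel if env_vel is None else np.asarray(env_vel)
    u = s * float(np.sum(system.potential.energy(x_c)))
    if len(x_e):
        d2 = np.sum((x_c[:, None, :] - x_e[None, :, :])**2, axis=-1)
        u += s * system.pair_eps * float(np.sum(np.exp(-d2 / (2 * system.pair_sigma**2))))
        u += 0.5 * system.tether_k * float(np.sum((x_e - system.env_home)**2))
    ke = 0.5 * system.copy_mass * float(np.sum(v_c**2))
    ke += 0.5 * system.env_mass * float(np.sum(v_e**2))
    return u + ke


# ---------------------------------------------------------------------------
# first-passage demonstration
# ---------------------------------------------------------------------------

@dataclass
class FirstPassageResult:
    steps: np.ndarray        # (replicas,) float; np.inf = censored
    censored: np.ndarray     # (replicas,) bool
    config: LESConfig

    @property
    def median(self) -> float:
        return float(np.median(self.steps))

    @property
    def mean(self) -> float:
        ok = ~self.censored
        return float(np.mean(self.steps[ok])) if ok.any() else float("inf")


def first_passage_stats(system: ToySystem, config: LESConfig, r_escape: float,
                        n_replicas: int = 100, seed: int = 0) -> FirstPassageResult:
    """Per-replica first step at which *any* copy crosses ``r_escape``.

    Replicas that never escape within the step budget are censored
    (recorded as +inf) and flagged.
    """
    if n_replicas < 1:
        raise ParameterError("n_replicas must be >= 1")
    steps = np.full(n_replicas, np.inf)
    censored = np.ones(n_replicas, dtype=bool)
    for rep in range(n_replicas):
        rep_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0])
        cfg = replace(config, seed=rep_seed)
        def escaped(x_c):
            return bool(np.any(np.linalg.norm(x_c, axis=1) > r_escape))
        _, hit = _integrate(system.clone(), cfg,
                            lambda s: les_forces(s, cfg), stop_fn=escaped)
        if hit is not None:
            steps[rep] = hit
            censored[rep] = False
    return FirstPassageResult(steps=steps, censored=censored, config=config)
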