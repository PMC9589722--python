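"""Langevin dynamics with optional restraints.

The integrator is the BAOAB splitting of underdamped Langevin dynamics
(kick / drift / Ornstein-Uhlenbeck / drift / kick), which is symplectic in
the gamma -> 0 limit (reduces to velocity Verlet) and gives accurate
configurational sampling at large time steps.  Beads carry a uniform mass
(:data:`cgbind.units.BEAD_MASS`); the time unit tau follows from mass,
Angstrom and kcal/mol.

Restraint objects expose ``energy_forces(coords) -> (E, F)`` and are summed
with the force-field forces every step:

* :class:`FlatBottomDistanceRestraint` - half-harmonic wall on a
  centre-of-mass distance (keeps a substrate inside the binding area);
* :class:`RmsdRestraint` - harmonic restraint on the best-fit RMSD to a
  reference (targeted-MD style);
* :class:`PositionRestraint` - positional fix of selected beads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .reaction_coords import rmsd_gradient
from .units import BEAD_MASS, KB


def flat_bottom_restraint(r, K, r0):
    """Half-harmonic wall (K/2)(r-r0)^2 H(r-r0); zero and C^1 at r = r0."""
    if K < 0:
        raise ValueError("K must be non-negative")
    r = np.asarray(r, dtype=float)
    out = np.where(r > r0, 0.5 * K * (r - r0) ** 2, 0.0)
    return out.item() if out.ndim == 0 else out


class FlatBottomDistanceRestraint:
    """Half-harmonic wall on the distance between two bead-group centroids."""

    def __init__(self, idx_a, idx_b, K: float, r0: float):
        self.idx_a = np.asarray(idx_a, dtype=np.int64)
        self.idx_b = np.asarray(idx_b, dtype=np.int64)
        if K < 0:
            raise ValueError("K must be non-negative")
        self.K = float(K)
        self.r0 = float(r0)

    def distance(self, coords) -> float:
        ca = coords[self.idx_a].mean(axis=0)
        cb = coords[self.idx_b].mean(axis=0)
        return float(np.linalg.norm(ca - cb))

    def energy_forces(self, coords):
        ca = coords[self.idx_a].mean(axis=0)
        cb = coords[self.idx_b].mean(axis=0)
        d = ca - cb
        r = float(np.linalg.norm(d))
        F = np.zeros_like(coords)
        if r <= self.r0 or r < 1e-12:
            return 0.0, F
        e = 0.5 * self.K * (r - self.r0) ** 2
        g = self.K * (r - self.r0) * d / r  # dE/d(ca)
        F[self.idx_a] -= g / len(self.idx_a)
        F[self.idx_b] += g / len(self.idx_b)
        return e, F


class RmsdRestraint:
    """Harmonic restraint (k/2) RMSD^2 toward a reference structure.

    The RMSD is computed after optimal superposition over ``subset``; the
    gradient passes through the superposition via the envelope theorem.
    """

    def __init__(self, reference, subset=None, k: float = 0.0):
        self.reference = np.asarray(reference, dtype=float)
        self.subset = None if subset is None else np.asarray(subset, np.int64)
        self.k = float(k)

    def energy_forces(self, coords):
        rmsd, grad = rmsd_gradient(coords, self.reference, self.subset)
        e = 0.5 * self.k * rmsd ** 2
        F = -self.k * rmsd * grad
        return e, F


class PositionRestraint:
    """Harmonic positional fix of selected beads to reference positions."""

    def __init__(self, indices, reference, k: float):
        self.indices = np.asarray(indices, dtype=np.int64)
        self.reference = np.asarray(reference, dtype=float)
        self.k = float(k)

    def energy_forces(self, coords):
        d = coords[self.indices] - self.reference
        e = 0.5 * self.k * float((d ** 2).sum())
        F = np.zeros_like(coords)
        F[self.indices] = -self.k * d
        return e, F


class HarmonicBias:
    """Harmonic bias (k/2)(cv - center)^2 on a differentiable observable.

    ``cv_grad(coords)`` must return (value, gradient).  Used for umbrella
    windows along xi.
    """

    def __init__(self, cv_grad: Callable, center: float, k: float):
        self.cv_grad = cv_grad
        self.center = float(center)
        self.k = float(k)
        self.last_value = np.nan

    def energy_forces(self, coords):
        v, g = self.cv_grad(coords)
        self.last_value = v
        e = 0.5 * self.k * (v - self.center) ** 2
        F = -self.k * (v - self.center) * g
        return e, F


# ---------------------------------------------------------------------------
# State and trajectories
# ---------------------------------------------------------------------------

@dataclass
class SimulationState:
    """Coordinates, velocities and the RNG stream position of one system."""

    coords: np.ndarray
    velocities: np.ndarray
    time: float = 0.0
    step_index: int = 0
    rng: np.random.Generator = None

    def __post_init__(self):
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        if self.rng is None:
            self.rng = np.random.default_rng(0)

    def copy(self) -> "SimulationState":
        return SimulationState(self.coords.copy(), self.velocities.copy(),
                               self.time, self.step_index,
                               np.random.default_rng(self._rng_state()))

    def _rng_state(self):
        bg = np.random.PCG64()
        bg.state = self.rng.bit_generator.state
        return bg

    def serialize(self) -> dict:
        return {
            "coords": self.coords.tolist(),
            "velocities": self.velocities.tolist(),
            "time": self.time,
            "step_index": self.step_index,
            "rng_state": self.rng.bit_generator.state,
        }

    @classmethod
    def deserialize(cls, data: dict) -> "SimulationState":
        bg = np.random.PCG64()
        bg.state = data["rng_state"]
        return cls(np.array(data["coords"]), np.array(data["velocities"]),
                   data["time"], data["step_index"], np.random.Generator(bg))


def initial_state(coords, temperature: float, seed: int,
                  mass: float = BEAD_MASS) -> SimulationState:
    """Maxwell-Boltzmann velocities at ``temperature``, seeded RNG stream."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    sigma = np.sqrt(KB * temperature / mass)
    v = rng.normal(0.0, sigma, size=coords.shape)
    return SimulationState(coords.copy(), v, rng=rng)


@dataclass
class Trajectory:
    """Frames and observable time series recorded at a fixed stride."""

    times: np.ndarray
    frames: np.ndarray | None
    observables: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    final_state: SimulationState | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def to_tsv(self, path):
        df = self.observables.copy()
        df.insert(0, "time", self.times)
        df.to_csv(path, sep="\t", index=False)


class LangevinIntegrator:
    """BAOAB Langevin integrator bound to one force field."""

    def __init__(self, ff, temperature: float | None = None,
                 gamma: float | None = None, dt: float | None = None,
                 mass: float = BEAD_MASS):
        self.ff = ff
        p = ff.params
        self.temperature = p.temperature if temperature is None else temperature
        self.gamma = p.gamma if gamma is None else gamma
        self.dt = p.dt if dt is None else dt
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.gamma * self.dt >= 1.0:
            raise ValueError("dt*gamma must be < 1 for a stable thermostat")
        self.mass = mass
        self._c1 = np.exp(-self.gamma * self.dt)
        self._c2 = np.sqrt(KB * self.temperature / mass * (1.0 - self._c1 ** 2))

    def _total_force(self, coords, restraints):
        e, F, comps = self.ff.energy_forces(coords)
        for r in restraints:
            er, Fr = r.energy_forces(coords)
            e += er
            F += Fr
        if not np.all(np.isfinite(F)):
            bad = np.nonzero(~np.isfinite(F).all(axis=1))[0]
            raise FloatingPointError(
                f"non-finite force on beads {bad.tolist()[:5]} "
                f"(energy {e:.3g})")
        return e, F, comps

    def step(self, state: SimulationState, restraints=(),
             force=None) -> np.ndarray:
        """Advance one BAOAB step in place; returns the force at the new coords."""
        dt, m = self.dt, self.mass
        if force is None:
            _, force, _ = self._total_force(state.coords, restraints)
        v = state.velocities
        x = state.coords
        v += 0.5 * dt * force / m
        x += 0.5 * dt * v
        if self.gamma > 0:
            noise = state.rng.standard_normal(x.shape)
            v *= self._c1
            v += self._c2 * noise
        x += 0.5 * dt * v
        _, force, _ = self._total_force(x, restraints)
        v += 0.5 * dt * force / m
        state.time += dt
        state.step_index += 1
        return force

    def run(self, state: SimulationState, n_steps: int, restraints=(),
            observables: dict[str, Callable] | None = None,
            stride: int = 100, store_frames: bool = True,
            energy_components: bool = False) -> Trajectory:
        """Propagate ``n_steps`` steps, recording every ``stride`` steps.

        Frame 0 is the input state, so the trajectory holds
        floor(n_steps/stride) + 1 frames.  Observables are callables of the
        coordinates; a failing observable aborts with the frame index.
        """
        observables = observables or {}
        times, frames, rows = [], [], []

        def record(step):
            times.append(state.time)
            if store_frames:
                frames.append(state.coords.copy())
            row = {}
            for name, fn in observables.items():
                try:
                    row[name] = fn(state.coords)
                except Exception as exc:
                    raise RuntimeError(
                        f"observable {name!r} failed at step {step}: {exc}"
                    ) from exc
            if energy_components:
                _, _, comps = self.ff.energy_forces(state.coords)
                for k, v in comps.items():
                    row[f"E_{k}"] = v
            rows.append(row)

        record(0)
        force = None
        for s in range(1, n_steps + 1):
            force = self.step(state, restraints, force=force)
            if s % stride == 0:
                record(s)

        meta = {
            "n_steps": n_steps,
            "stride": stride,
            "dt": self.dt,
            "gamma": self.gamma,
            "temperature": self.temperature,
            "mass": self.mass,
        }
        return Trajectory(
            times=np.array(times),
            frames=np.array(frames) if store_frames else None,
            observables=pd.DataFrame(rows),
            metadata=meta,
            final_state=state,
        )


def run_trajectory(initial: SimulationState, ff, n_steps: int,
                   observables: dict | None = None, restraints=(),
                   seed: int | None = None, stride: int = 100,
                   store_frames: bool = True, **kw) -> Trajectory:
    """Convenience driver: optionally reseed, then integrate ``n_steps``.

    The returned trajectory's metadata records every integrator parameter
    and the seed used.
    """
    state = initial.copy()
    if seed is not None:
        state.rng = np.random.default_rng(seed)
    integ = LangevinIntegrator(ff, **kw)
    traj = integ.run(state, n_steps, restraints=restraints,
                     observables=observables, stride=stride,
                     store_frames=store_frames)
    traj.metadata["seed"] = seed
    return traj


def kinetic_energy(state: SimulationState, mass: float = BEAD_MASS) -> float:
    return 0.5 * mass * float((state.velocities ** 2).sum())
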