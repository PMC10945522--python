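"""NVT dynamics: Langevin (BAOAB) and Nosé-Hoover integration with rigid bodies.

Rigid groups (e.g. the histone core plus the inner DNA layer) move as single
bodies: net forces translate the center of mass and torques rotate the body
through an exact Rodrigues rotation, so intra-group distances are preserved
to machine precision.  Free beads follow the thermostatted point-particle
update.  Identical seeds give identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .geometry import rotation_matrix
from .units import KB, MVSQ2E

__all__ = ["SimulationState", "IntegratorSettings", "Trajectory", "run_nvt",
           "Integrator", "kinetic_temperature"]

_FORCE_BLOWUP = 1.0e5   # kcal/mol/A


@dataclass
class SimulationState:
    positions: np.ndarray            # (n, 3) A
    velocities: np.ndarray           # (n, 3) A/ps
    box: Optional[float] = None      # cubic edge, A; None = open boundaries
    time: float = 0.0                # ps

    def copy(self) -> "SimulationState":
        return SimulationState(self.positions.copy(), self.velocities.copy(),
                               self.box, self.time)


@dataclass
class IntegratorSettings:
    timestep: float = 0.01           # ps (10 fs)
    temperature: float = 300.0       # K
    damping: float = 1.0             # ps
    thermostat: Optional[str] = "langevin"   # 'langevin' | 'nose-hoover' | None
    seed: int = 0
    #: scale factor on rigid-body mass/inertia; equilibrium averages are
    #: mass-independent, lighter bodies just diffuse and reorient faster
    rigid_mass_scale: float = 1.0
    #: per-bead force-magnitude cap (kcal/mol/A); None disables capping.
    #: Used only for clash-resolving pre-equilibration, never production.
    force_cap: Optional[float] = None


@dataclass
class Trajectory:
    times: List[float] = field(default_factory=list)
    frames: List[np.ndarray] = field(default_factory=list)
    energies: List[float] = field(default_factory=list)
    temperatures: List[float] = field(default_factory=list)
    box: Optional[float] = None

    def append(self, state: SimulationState, energy: float, temperature: float):
        self.times.append(state.time)
        self.frames.append(state.positions.copy())
        self.energies.append(energy)
        self.temperatures.append(temperature)

    def positions_array(self) -> np.ndarray:
        return np.array(self.frames)

    def write_xyz(self, path, species: Sequence[str]):
        with open(path, "w") as fh:
            for t, frame in zip(self.times, self.frames):
                fh.write(f"{len(frame)}\ntime_ps={t:.6f}\n")
                for s, (x, y, z) in zip(species, frame):
                    fh.write(f"{s} {x:.5f} {y:.5f} {z:.5f}\n")

    @staticmethod
    def read_xyz(path):
        times, frames, species = [], [], None
        with open(path) as fh:
            lines = fh.read().splitlines()
        k = 0
        while k < len(lines):
            n = int(lines[k])
            times.append(float(lines[k + 1].split("=")[1]))
            rows = [ln.split() for ln in lines[k + 2:k + 2 + n]]
            if species is None:
                species = [r[0] for r in rows]
            frames.append(np.array([[float(v) for v in r[1:4]] for r in rows]))
            k += 2 + n
        traj = Trajectory(times=times, frames=frames,
                          energies=[np.nan] * len(times),
                          temperatures=[np.nan] * len(times))
        return traj, species


class _RigidBody:
    """State of one rigid group: pose plus body-frame coordinates."""

    def __init__(self, indices, positions, masses, mass_scale: float = 1.0):
        self.idx = np.asarray(indices, int)
        m = masses[self.idx] * mass_scale
        self.mass = float(m.sum())                    # amu
        self.com = (positions[self.idx] * m[:, None]).sum(axis=0) / self.mass
        body = positions[self.idx] - self.com
        # principal-axis body frame
        inertia = np.zeros((3, 3))
        for mi, ri in zip(m, body):
            inertia += mi * (np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri))
        w, V = np.linalg.eigh(inertia * MVSQ2E)       # energy-consistent units
        self.I_body = np.maximum(w, 1e-12)            # principal moments
        if np.linalg.det(V) < 0:
            V[:, 0] = -V[:, 0]
        self.R = V                                    # body->world
        self.body_coords = body @ V                   # coordinates in body frame
        self.vel = np.zeros(3)                        # COM velocity, A/ps
        self.L = np.zeros(3)                          # angular momentum (world)
        self.m_eff = self.mass * MVSQ2E

    def world_positions(self):
        return self.com + self.body_coords @ self.R.T

    def omega(self):
        return self.R @ ((self.R.T @ self.L) / self.I_body)

    def rotate(self, dt):
        w = self.omega()
        wn = np.linalg.norm(w)
        if wn > 1e-14:
            self.R = rotation_matrix(w / wn, wn * dt) @ self.R

    def kinetic_energy(self):
        trans = 0.5 * self.m_eff * float(self.vel @ self.vel)
        Lb = self.R.T @ self.L
        rot = 0.5 * float(np.sum(Lb * Lb / self.I_body))
        return trans + rot


class Integrator:
    """BAOAB Langevin / Nosé-Hoover / NVE integrator with rigid-body support."""

    def __init__(self, topology, forcefield, settings: IntegratorSettings,
                 restraints: Sequence = ()):
        self.top = topology
        self.ff = forcefield
        self.set = settings
        self.restraints = list(restraints)
        self.rng = np.random.default_rng(settings.seed)
        rigid = set(i for g in topology.rigid_groups for i in g)
        self.free = np.array([i for i in range(topology.n_beads) if i not in rigid], int)
        self.m_eff = topology.masses * MVSQ2E
        self.bodies: List[_RigidBody] = []
        self._nh_xi = 0.0
        self._positions_cache = None

    # -- setup --------------------------------------------------------------

    def initialize(self, state: SimulationState):
        self.bodies = [_RigidBody(g, state.positions, self.top.masses,
                                  self.set.rigid_mass_scale)
                       for g in self.top.rigid_groups]
        self._state = state
        self._recompute_forces()

    def draw_velocities(self, state: SimulationState):
        """Maxwell-Boltzmann velocities at the target temperature."""
        kT = KB * self.set.temperature
        n = self.top.n_beads
        state.velocities = (self.rng.standard_normal((n, 3))
                            * np.sqrt(kT / self.m_eff)[:, None])
        for b in self.bodies:
            b.vel = self.rng.standard_normal(3) * np.sqrt(kT / b.m_eff)
            Lb = self.rng.standard_normal(3) * np.sqrt(kT * b.I_body)
            b.L = b.R @ Lb

    # -- force bookkeeping --------------------------------------------------

    def _recompute_forces(self):
        x = self._state.positions
        e, F = self.ff.energy_forces(x)
        for r in self.restraints:
            er, Fr = r.energy_forces(x)
            e += er
            F += Fr
        if self.set.force_cap is not None:
            norms = np.linalg.norm(F, axis=1)
            over = norms > self.set.force_cap
            if np.any(over):
                F[over] *= (self.set.force_cap / norms[over])[:, None]
        else:
            worst = float(np.abs(F).max()) if len(F) else 0.0
            if worst > _FORCE_BLOWUP:
                i = int(np.unravel_index(np.argmax(np.abs(F)), F.shape)[0])
                raise FloatingPointError(
                    f"force blow-up: |F|={worst:.3e} kcal/mol/A on bead {i} "
                    f"({self.top.species[i]}) at t={self._state.time:.3f} ps")
        self.potential_energy = e
        self.forces = F

    # -- thermo -------------------------------------------------------------

    @property
    def n_dof(self) -> int:
        return 3 * len(self.free) + 6 * len(self.bodies)

    def kinetic_energy(self) -> float:
        v = self._state.velocities[self.free]
        ke = 0.5 * float(np.sum(self.m_eff[self.free][:, None] * v * v))
        ke += sum(b.kinetic_energy() for b in self.bodies)
        return ke

    def temperature(self) -> float:
        if self.n_dof == 0:
            return 0.0
        return 2.0 * self.kinetic_energy() / (self.n_dof * KB)

    # -- stepping -----------------------------------------------------------

    def _kick(self, dt):
        fr = self.free
        self._state.velocities[fr] += dt * self.forces[fr] / self.m_eff[fr][:, None]
        for b in self.bodies:
            fnet = self.forces[b.idx].sum(axis=0)
            arm = self._state.positions[b.idx] - b.com
            tau = np.sum(np.cross(arm, self.forces[b.idx]), axis=0)
            b.vel += dt * fnet / b.m_eff
            b.L += dt * tau

    def _drift(self, dt):
        fr = self.free
        self._state.positions[fr] += dt * self._state.velocities[fr]
        for b in self.bodies:
            b.com += dt * b.vel
            b.rotate(dt)
            self._state.positions[b.idx] = b.world_positions()

    def _ou(self, dt):
        """Ornstein-Uhlenbeck (thermostat) part of BAOAB."""
        kT = KB * self.set.temperature
        c1 = np.exp(-dt / self.set.damping)
        c2 = np.sqrt(1.0 - c1 * c1)
        fr = self.free
        sig = np.sqrt(kT / self.m_eff[fr])
        self._state.velocities[fr] = (c1 * self._state.velocities[fr]
                                      + c2 * sig[:, None]
                                      * self.rng.standard_normal((len(fr), 3)))
        for b in self.bodies:
            b.vel = c1 * b.vel + c2 * np.sqrt(kT / b.m_eff) * self.rng.standard_normal(3)
            noise = self.rng.standard_normal(3)
            b.L = c1 * b.L + c2 * b.R @ (np.sqrt(kT * b.I_body) * noise)

    def _nose_hoover(self, dt):
        kT = KB * self.set.temperature
        Q = self.n_dof * kT * self.set.damping ** 2
        ke = self.kinetic_energy()
        self._nh_xi += dt * (2.0 * ke - self.n_dof * kT) / Q
        scale = np.exp(-self._nh_xi * dt)
        self._state.velocities[self.free] *= scale
        for b in self.bodies:
            b.vel *= scale
            b.L *= scale

    def step(self):
        dt = self.set.timestep
        self._kick(dt / 2.0)
        self._drift(dt / 2.0)
        if self.set.thermostat == "langevin":
            self._ou(dt)
        elif self.set.thermostat == "nose-hoover":
            self._nose_hoover(dt)
        self._drift(dt / 2.0)
        self._recompute_forces()
        self._kick(dt / 2.0)
        self._state.time += dt


def kinetic_temperature(integrator: Integrator) -> float:
    return integrator.temperature()


def run_nvt(state: SimulationState, topology, forcefield,
            settings: IntegratorSettings, biases: Sequence = (),
            n_steps: int = 1000, report_every: int = 100,
            initialize_velocities: bool = True) -> Trajectory:
    """Run NVT dynamics and return the trajectory at the reporting stride.

    ``biases`` are restraint objects (``energy_forces(positions)``); the
    reported energy is the potential energy including biases.
    """
    integ = Integrator(topology, forcefield, settings, restraints=biases)
    integ.initialize(state)
    if initialize_velocities:
        integ.draw_velocities(state)
    traj = Trajectory(box=state.box)
    traj.append(state, integ.potential_energy, integ.temperature())
    for s in range(1, n_steps + 1):
        integ.step()
        if s % report_every == 0:
            traj.append(state, integ.potential_energy, integ.temperature())
    return traj
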