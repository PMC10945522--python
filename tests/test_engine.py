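"""Dynamics: thermostat accuracy, conservation, rigid bodies, determinism."""

import numpy as np
import pytest

from chromion.engine import (Integrator, IntegratorSettings, SimulationState,
                             Trajectory, run_nvt)
from chromion.fixtures import make_fixture
from chromion.potentials import ForceField
from chromion.topology import CGTopology


def neutral_fluid(n=64, edge=50.0, seed=1):
    """Charge-free short-range fluid (ion beads with charges zeroed)."""
    top, state, _ = make_fixture("ion_box", {"n_na": n // 2, "n_cl": n // 2,
                                             "edge": edge}, seed=seed)
    top.charges[:] = 0.0
    return top, state


class TestThermostats:
    def test_langevin_temperature_matches_target(self):
        top, state, _ = make_fixture("ion_box", {"n_na": 32, "n_cl": 32,
                                                 "edge": 55.0}, seed=7)
        ff = ForceField(top, box=55.0)
        traj = run_nvt(state, top, ff, IntegratorSettings(seed=3),
                       n_steps=3000, report_every=20)
        temps = np.array(traj.temperatures[50:])
        sem = temps.std() / np.sqrt(len(temps))
        assert abs(temps.mean() - 300.0) < max(3 * sem, 0.03 * 300.0)

    def test_nose_hoover_temperature(self):
        top, state = neutral_fluid()
        ff = ForceField(top, box=50.0)
        traj = run_nvt(state, top, ff,
                       IntegratorSettings(seed=4, thermostat="nose-hoover"),
                       n_steps=3000, report_every=20)
        temps = np.array(traj.temperatures[50:])
        assert abs(temps.mean() - 300.0) < 0.05 * 300.0

    def test_overdamped_zero_temperature_relaxes_downhill(self):
        top, state = neutral_fluid(n=32, edge=30.0)
        ff = ForceField(top, box=30.0)
        settings = IntegratorSettings(seed=5, temperature=1e-6, damping=0.1)
        traj = run_nvt(state, top, ff, settings, n_steps=500, report_every=50,
                       initialize_velocities=False)
        assert traj.energies[-1] <= traj.energies[0]
        assert min(np.diff(traj.energies)) > -np.inf  # finite throughout


class TestConservation:
    def test_nve_energy_drift_is_tiny(self):
        top, state = neutral_fluid()
        ff = ForceField(top, box=50.0)
        run_nvt(state, top, ff, IntegratorSettings(seed=5, temperature=150.0),
                n_steps=1500, report_every=1500)   # thermalize
        integ = Integrator(top, ff, IntegratorSettings(thermostat=None, seed=5))
        integ.initialize(state)
        e0 = integ.potential_energy + integ.kinetic_energy()
        for _ in range(1500):
            integ.step()
        e1 = integ.potential_energy + integ.kinetic_energy()
        assert abs(e1 - e0) / 1500 < 1e-4

    def test_momentum_conserved_without_thermostat(self):
        top, state = neutral_fluid(n=32, edge=40.0)
        ff = ForceField(top, box=40.0)
        integ = Integrator(top, ff, IntegratorSettings(thermostat=None, seed=6))
        integ.initialize(state)
        integ.draw_velocities(state)
        state.velocities -= state.velocities.mean(axis=0)
        p0 = (top.masses[:, None] * state.velocities).sum(axis=0)
        for _ in range(200):
            integ.step()
        p1 = (top.masses[:, None] * state.velocities).sum(axis=0)
        assert np.abs(p1 - p0).max() < 1e-8


class TestDeterminism:
    def test_identical_seed_identical_trajectory(self):
        top, state, _ = make_fixture("ion_box", {"n_na": 16, "n_cl": 16}, seed=2)
        ff = ForceField(top, box=60.0)
        t1 = run_nvt(state.copy(), top, ff, IntegratorSettings(seed=9),
                     n_steps=300, report_every=100)
        t2 = run_nvt(state.copy(), top, ff, IntegratorSettings(seed=9),
                     n_steps=300, report_every=100)
        assert np.array_equal(t1.frames[-1], t2.frames[-1])

    def test_different_seed_diverges(self):
        top, state, _ = make_fixture("ion_box", {"n_na": 16, "n_cl": 16}, seed=2)
        ff = ForceField(top, box=60.0)
        t1 = run_nvt(state.copy(), top, ff, IntegratorSettings(seed=9),
                     n_steps=300, report_every=100)
        t2 = run_nvt(state.copy(), top, ff, IntegratorSettings(seed=10),
                     n_steps=300, report_every=100)
        assert not np.array_equal(t1.frames[-1], t2.frames[-1])


class _ConstantForce:
    """Test restraint applying a fixed per-bead force field."""

    def __init__(self, forces):
        self.forces = forces

    def energy_forces(self, positions):
        return 0.0, self.forces


def dumbbell():
    top = CGTopology()
    top.add_chain("D", "protein", ["GLY", "GLY"],
                  np.array([[-2.0, 0, 0], [2.0, 0, 0]]), [1, 2])
    top.bonds.append((0, 1, 4.0))
    top.rigid_groups = [[0, 1]]
    return top


class TestRigidBodies:
    def test_symmetric_forces_translate_without_rotation(self):
        top = dumbbell()
        ff = ForceField(top)
        f = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
        integ = Integrator(top, ff, IntegratorSettings(thermostat=None),
                           restraints=[_ConstantForce(f)])
        state = SimulationState(top.positions.copy(),
                                np.zeros_like(top.positions))
        integ.initialize(state)
        for _ in range(100):
            integ.step()
        d = state.positions - top.positions
        assert d[0] == pytest.approx(d[1], abs=1e-10)   # pure translation
        assert d[0][1] > 0

    def test_opposite_tangential_forces_rotate_about_com(self):
        top = dumbbell()
        ff = ForceField(top)
        f = np.array([[0.0, 1.0, 0.0], [0.0, -1.0, 0.0]])
        integ = Integrator(top, ff, IntegratorSettings(thermostat=None),
                           restraints=[_ConstantForce(f)])
        state = SimulationState(top.positions.copy(),
                                np.zeros_like(top.positions))
        integ.initialize(state)
        for _ in range(100):
            integ.step()
        com = state.positions.mean(axis=0)
        assert np.abs(com - top.positions.mean(axis=0)).max() < 1e-10
        # beads moved (rotated) while staying 4 A apart
        assert np.linalg.norm(state.positions[0] - top.positions[0]) > 0.01
        assert np.linalg.norm(state.positions[0]
                              - state.positions[1]) == pytest.approx(4.0, abs=1e-10)

    def test_intragroup_distances_constant_over_long_run(self, toy_dinucleosome):
        top, state, extras = toy_dinucleosome
        ff = ForceField(top)
        group = np.asarray(top.rigid_groups[0], int)
        ref = state.positions[group]
        d0 = np.linalg.norm(ref[0] - ref[len(group) // 2])
        st = state.copy()
        run_nvt(st, top, ff, IntegratorSettings(seed=11), n_steps=2000,
                report_every=2000)
        d1 = np.linalg.norm(st.positions[group[0]]
                            - st.positions[group[len(group) // 2]])
        assert abs(d1 - d0) / d0 < 1e-8


class TestTrajectoryIO:
    def test_xyz_roundtrip(self, tmp_path):
        top, state, _ = make_fixture("ion_box", {"n_na": 4, "n_cl": 4}, seed=1)
        ff = ForceField(top, box=60.0)
        traj = run_nvt(state, top, ff, IntegratorSettings(seed=1), n_steps=20,
                       report_every=10)
        path = tmp_path / "t.xyz"
        traj.write_xyz(path, top.species)
        back, species = Trajectory.read_xyz(path)
        assert species == top.species
        assert len(back.frames) == len(traj.frames)
        assert np.allclose(back.frames[-1], traj.frames[-1], atol=1e-5)


def test_force_blowup_aborts_with_diagnostic():
    top, state, _ = make_fixture("ion_box", {"n_na": 2, "n_cl": 2, "edge": 40.0},
                                 seed=1)
    ff = ForceField(top, box=40.0)
    state.positions[1] = state.positions[0] + 1e-4
    with pytest.raises(FloatingPointError):
        run_nvt(state, top, ff, IntegratorSettings(seed=1), n_steps=10,
                report_every=10)
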