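"""Constrained velocity Verlet: constraint fidelity, NVE conservation, SVR."""

import numpy as np
import pytest

from ionscreen.constants import BOLTZMANN_KJ_MOL_K, COULOMB_CONSTANT
from ionscreen.forces import LJCoulomb
from ionscreen.integrators import (
    ConstrainedVerlet,
    ConstraintSpec,
    ThermostatSpec,
    rattle_constrained_step,
    svr_scale_factor,
)
from ionscreen.species import SpeciesParams, SpeciesTable
from ionscreen.system import (
    SimulationBox,
    SystemState,
    build_initial_state,
    maxwell_boltzmann_velocities,
    per_particle_arrays,
)
from ionscreen.windows import EnergyModel


def vacuum_pair(r, charge=1.0):
    table = SpeciesTable([SpeciesParams("Na", 22.99, charge, 0.0, 2.35, 0.0)])
    st = SystemState(
        np.array([[0.0, 0, 0], [r, 0, 0]]), np.zeros((2, 3)), [0, 0], ["Na"],
        SimulationBox(200.0, periodic=False),
    )
    return st, table


class TestConstraint:
    def test_quiescent_neutral_pair_stays_at_target(self):
        st, table = vacuum_pair(5.0, charge=0.0)
        model = EnergyModel(st, table, scheme="none")
        integ = ConstrainedVerlet(
            model, np.array([22.99, 22.99]), dt=2.0,
            constraint=ConstraintSpec((0, 1), 5.0),
        )
        for _ in range(1000):
            integ.step(st)
        d = np.linalg.norm(st.positions[0] - st.positions[1])
        assert d == pytest.approx(5.0, rel=1e-8)

    def test_vacuum_coulomb_constraint_force(self):
        """Two +1e ions held at 10 Å feel exactly the k_C/r² repulsion."""
        st, table = vacuum_pair(10.0)
        model = EnergyModel(st, table, scheme="none")
        integ = ConstrainedVerlet(
            model, np.array([22.99, 22.99]), dt=2.0,
            constraint=ConstraintSpec((0, 1), 10.0),
        )
        forces = [integ.step(st).constraint_force for _ in range(200)]
        assert np.mean(forces) == pytest.approx(COULOMB_CONSTANT / 100.0, rel=1e-6)

    def test_constraint_preserved_with_solvent(self, argon_table):
        state = build_initial_state(32, "Na", 4.5, 21.228, seed=5, table=argon_table)
        masses, _, _, _, _ = per_particle_arrays(state, argon_table)
        model = EnergyModel(state, argon_table, scheme="none", scf_tolerance=1e-8)
        integ = ConstrainedVerlet(
            model, masses, dt=2.0,
            constraint=ConstraintSpec((0, 1), 4.5, tolerance=1e-6),
            thermostat=ThermostatSpec(300.0, 100.0),
            rng=np.random.default_rng(9),
        )
        for _ in range(300):
            res = integ.step(state)
            assert abs(res.distance - 4.5) / 4.5 < 1e-6

    def test_wrapper_returns_constraint_force(self):
        st, table = vacuum_pair(10.0)
        ff = LJCoulomb(st.species_index, st.species_names, table, st.box, "none")
        _, g = rattle_constrained_step(
            st, ConstraintSpec((0, 1), 10.0), 2.0, ff.evaluate, np.array([22.99, 22.99])
        )
        assert g == pytest.approx(COULOMB_CONSTANT / 100.0, rel=1e-6)

    def test_degenerate_constraint_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ConstraintSpec((1, 1), 5.0)


def test_nve_energy_conservation():
    """Thermostat off, constraint on, no polarizability: total-energy drift
    below 0.01 kJ/mol per particle over 10 ps at dt = 2 fs."""
    table = SpeciesTable(
        [
            SpeciesParams("Ar", 39.948, 0.0, 0.0, 3.401, 0.9786),
            SpeciesParams("Na", 22.99, 0.0, 0.0, 2.35, 0.544),
        ]
    )
    state = build_initial_state(32, "Na", 4.5, 21.228, seed=8, table=table)
    masses, _, _, _, _ = per_particle_arrays(state, table)
    model = EnergyModel(state, table, scheme="none")
    integ = ConstrainedVerlet(
        model, masses, dt=2.0, constraint=ConstraintSpec((0, 1), 4.5)
    )
    energies = []
    for k in range(5000):
        res = integ.step(state)
        energies.append(res.potential_energy + res.kinetic_energy)
    energies = np.asarray(energies)
    # compare late-run average against early-run average (drift, not noise)
    drift = abs(energies[-500:].mean() - energies[:500].mean())
    assert drift / state.n_particles < 0.01


class TestThermostat:
    def test_mean_temperature_on_target(self, neutral_argon_table):
        rng = np.random.default_rng(12)
        rho = 21.228
        side = 10.0 * (64 / rho) ** (1 / 3)
        m = 4
        grid = (np.arange(m) + 0.5) * side / m
        pos = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), -1).reshape(-1, 3)
        pos += rng.uniform(-0.2, 0.2, pos.shape)
        masses = np.full(64, 39.948)
        state = SystemState(
            pos, maxwell_boltzmann_velocities(masses, 240.0, rng),
            np.zeros(64, int), ["Ar"], SimulationBox(side),
        )
        model = EnergyModel(state, neutral_argon_table, scheme="none")
        integ = ConstrainedVerlet(
            model, masses, dt=2.0, thermostat=ThermostatSpec(300.0, 200.0), rng=rng
        )
        n_dof = integ.n_dof
        temps = []
        for k in range(2500):
            res = integ.step(state)
            if k >= 500:
                temps.append(2 * res.kinetic_energy / (n_dof * BOLTZMANN_KJ_MOL_K))
        temps = np.asarray(temps)
        # ~2000 correlated samples; block the series for the standard error
        blocks = temps[: 2000].reshape(10, 200).mean(axis=1)
        se = blocks.std(ddof=1) / np.sqrt(len(blocks))
        assert abs(temps.mean() - 300.0) < 3 * max(se, 1.0)

    def test_svr_determinism(self):
        a = svr_scale_factor(100.0, 189, 2.0, 200.0, 300.0, np.random.default_rng(4))
        b = svr_scale_factor(100.0, 189, 2.0, 200.0, 300.0, np.random.default_rng(4))
        assert a == b

    def test_svr_relaxes_towards_target(self):
        rng = np.random.default_rng(0)
        # cold start: rescaling factors should exceed 1 on average
        factors = [
            svr_scale_factor(10.0, 189, 2.0, 50.0, 300.0, rng) for _ in range(200)
        ]
        assert np.mean(factors) > 1.0
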