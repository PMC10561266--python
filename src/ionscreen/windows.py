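"""Constrained-distance MD windows: the blue-moon sampling unit.

A window holds the two ions at a fixed separation r and records, at every
production step, the antisymmetric projection of the potential forces on
the interionic axis.  Averaging that series gives the mean force at r;
integrating mean forces over a set of windows gives the free-energy
profile (:mod:`ionscreen.profiles`).

Two modes mirror the study design:

``polarizable_charged``
    ions carry their integer charges and the solvent its electronic
    polarizability — the system whose free energy contains the screened
    Coulomb interaction;
``zerocharge_lj``
    all charges and polarizabilities zeroed — the pure van der Waals
    reference whose profile is subtracted out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .forces import LJCoulomb
from .integrators import ConstrainedVerlet, ConstraintSpec, ThermostatSpec
from .polarization import InducedDipoles
from .species import SpeciesTable, default_species_table
from .system import SystemState, build_initial_state, per_particle_arrays

__all__ = ["WindowConfig", "MeanForceWindow", "EnergyModel", "run_window"]

MODES = ("polarizable_charged", "zerocharge_lj")


@dataclass
class MeanForceWindow:
    """Projected interionic force time series at one constrained distance."""

    target_distance: float
    projected_forces: np.ndarray  # kJ/mol/Å, one per production step
    timestep: float  # fs
    production_steps: int
    equilibration_steps: int
    mode: str = "polarizable_charged"
    seed: int = 0

    def __post_init__(self) -> None:
        self.projected_forces = np.asarray(self.projected_forces, dtype=float)
        if len(self.projected_forces) != self.production_steps:
            raise ValueError("force series length must equal production_steps")


@dataclass(frozen=True)
class WindowConfig:
    """Everything needed to run one constrained window reproducibly."""

    target_distance: float
    seed: int
    mode: str = "polarizable_charged"
    ion_species: str = "Na"
    n_solvent: int = 128
    number_density: float = 21.228  # nm^-3
    temperature: float = 300.0
    timestep: float = 2.0  # fs
    equilibration_steps: int = 2500
    production_steps: int = 12500
    scheme: str = "ewald_background"
    solvent_polarizability: float = 0.0  # Å³; ignored in zerocharge_lj mode
    thole_a: float = 0.39
    scf_tolerance: float = 1e-6
    tau_equilibration: float = 50.0  # fs
    tau_production: float = 200.0  # fs
    table: Optional[SpeciesTable] = None
    trajectory_path: Optional[str] = None  # extended-XYZ output (production only)
    trajectory_stride: int = 100  # steps between frames

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.timestep <= 0 or self.target_distance <= 0:
            raise ValueError("timestep and target distance must be positive")

    def species_table(self) -> SpeciesTable:
        table = self.table
        if table is None:
            table = default_species_table(self.solvent_polarizability)
        if self.mode == "zerocharge_lj":
            table = table.zero_charge()
        return table


class EnergyModel:
    """Total potential model: LJ + permanent charges + induced dipoles."""

    def __init__(
        self,
        state: SystemState,
        table: SpeciesTable,
        scheme: str = "ewald_background",
        thole_a: float = 0.39,
        scf_tolerance: float = 1e-6,
        lorentz_field: bool = True,
    ):
        self.table = table
        self.pair = LJCoulomb(
            state.species_index, state.species_names, table, state.box, scheme
        )
        _, charge, alpha, _, _ = per_particle_arrays(state, table)
        self.polar: Optional[InducedDipoles] = None
        if np.any(alpha > 0) and np.any(charge != 0.0):
            self.polar = InducedDipoles(
                alpha, charge, state.box, thole_a=thole_a,
                tolerance=scf_tolerance, lorentz_field=lorentz_field,
            )

    def __call__(self, positions: np.ndarray):
        forces, energy = self.pair.evaluate(positions)
        if self.polar is not None:
            _, e_pol, f_pol = self.polar.energy_and_forces(positions)
            forces = forces + f_pol
            energy += e_pol
        return forces, energy


def run_window(config: WindowConfig) -> MeanForceWindow:
    """Equilibrate and sample one constrained-distance window.

    Deterministic for a given config (seed controls initial placement,
    velocities and the thermostat noise).  Raises on temperature runaway
    (instantaneous kinetic temperature above 5x the target).
    """
    table = config.species_table()
    state = build_initial_state(
        config.n_solvent,
        config.ion_species,
        config.target_distance,
        config.number_density,
        config.seed,
        table=table,
        temperature=config.temperature,
    )
    masses, _, _, _, _ = per_particle_arrays(state, table)
    model = EnergyModel(
        state, table, scheme=config.scheme,
        thole_a=config.thole_a, scf_tolerance=config.scf_tolerance,
    )
    constraint = ConstraintSpec((0, 1), config.target_distance, tolerance=1e-6)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))

    integ = ConstrainedVerlet(
        model, masses, config.timestep, constraint=constraint,
        thermostat=ThermostatSpec(config.temperature, config.tau_equilibration),
        rng=rng,
    )
    t_limit = 5.0 * config.temperature
    kb_factor = integ.n_dof  # dof for temperature checks

    for _ in range(config.equilibration_steps):
        res = integ.step(state)
        _check_temperature(res.kinetic_energy, kb_factor, t_limit)

    integ.thermostat = ThermostatSpec(config.temperature, config.tau_production)
    series = np.empty(config.production_steps)
    frames = []
    symbols = [state.species_names[i] for i in state.species_index]
    for k in range(config.production_steps):
        res = integ.step(state)
        _check_temperature(res.kinetic_energy, kb_factor, t_limit)
        series[k] = res.projected_force
        if config.trajectory_path is not None and k % config.trajectory_stride == 0:
            from .io import Frame

            frames.append(
                Frame(symbols, state.positions % state.box.side_length, state.box.side_length, k)
            )
    if config.trajectory_path is not None:
        from .io import write_xyz_trajectory

        write_xyz_trajectory(frames, config.trajectory_path)
    return MeanForceWindow(
        target_distance=config.target_distance,
        projected_forces=series,
        timestep=config.timestep,
        production_steps=config.production_steps,
        equilibration_steps=config.equilibration_steps,
        mode=config.mode,
        seed=config.seed,
    )


def _check_temperature(kinetic: float, n_dof: int, t_limit: float) -> None:
    from .constants import BOLTZMANN_KJ_MOL_K

    t_inst = 2.0 * kinetic / (n_dof * BOLTZMANN_KJ_MOL_K)
    if t_inst > t_limit:
        raise RuntimeError(
            f"temperature runaway: instantaneous T = {t_inst:.0f} K exceeds 5x target"
        )
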