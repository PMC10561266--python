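"""Simulation cell, particle state, and initial-configuration building."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import BOLTZMANN_KJ_MOL_K, KINETIC_TO_KJ_MOL
from .species import SpeciesParams, SpeciesTable

__all__ = ["SimulationBox", "SystemState", "build_initial_state", "maxwell_boltzmann_velocities"]


@dataclass(frozen=True)
class SimulationBox:
    """Cubic periodic cell; side length in Å.

    Minimum-image pair interactions are valid only up to side_length/2.
    """

    side_length: float
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("box side length must be positive")

    @property
    def volume(self) -> float:
        return self.side_length**3

    def minimum_image(self, dr: np.ndarray) -> np.ndarray:
        """Wrap displacement vectors into the Wigner-Seitz cell."""
        if not self.periodic:
            return dr
        L = self.side_length
        return dr - L * np.round(dr / L)


@dataclass
class SystemState:
    """Positions (Å), velocities (Å/fs), species indices and the box."""

    positions: np.ndarray
    velocities: np.ndarray
    species_index: np.ndarray
    species_names: Sequence[str]
    box: SimulationBox
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        self.species_index = np.asarray(self.species_index, dtype=int)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must have the same shape")
        if self.positions.shape[0] != self.species_index.shape[0]:
            raise ValueError("species_index length must match particle count")
        if self.species_index.min(initial=0) < 0 or (
            len(self.species_index) and self.species_index.max() >= len(self.species_names)
        ):
            raise ValueError("species index out of range")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def resolve(self, table: SpeciesTable) -> list[SpeciesParams]:
        return [table[self.species_names[i]] for i in self.species_index]

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(),
            self.velocities.copy(),
            self.species_index.copy(),
            list(self.species_names),
            self.box,
            self.rng_seed,
        )


def per_particle_arrays(state: SystemState, table: SpeciesTable):
    """(mass, charge, alpha, sigma, epsilon) arrays resolved per particle."""
    sp = [table[name] for name in state.species_names]
    idx = state.species_index
    mass = np.array([s.mass for s in sp])[idx]
    charge = np.array([s.charge for s in sp])[idx]
    alpha = np.array([s.polarizability_volume for s in sp])[idx]
    sigma = np.array([s.lj_sigma for s in sp])[idx]
    eps = np.array([s.lj_epsilon for s in sp])[idx]
    return mass, charge, alpha, sigma, eps


def maxwell_boltzmann_velocities(
    masses: np.ndarray, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Thermal velocities (Å/fs) at ``temperature`` with zero net momentum."""
    sigma_v = np.sqrt(BOLTZMANN_KJ_MOL_K * temperature / (masses * KINETIC_TO_KJ_MOL))
    v = rng.normal(size=(len(masses), 3)) * sigma_v[:, None]
    p = (masses[:, None] * v).sum(axis=0)
    v -= p / masses.sum()
    return v


def kinetic_temperature(state: SystemState, masses: np.ndarray, n_dof: Optional[int] = None) -> float:
    """Instantaneous kinetic temperature (K)."""
    if n_dof is None:
        n_dof = 3 * state.n_particles - 3
    ke = 0.5 * KINETIC_TO_KJ_MOL * float((masses[:, None] * state.velocities**2).sum())
    return 2.0 * ke / (n_dof * BOLTZMANN_KJ_MOL_K)


def box_side_from_density(n_particles: int, number_density_nm3: float) -> float:
    """Cubic side (Å) holding ``n_particles`` at ``number_density_nm3`` (nm⁻³)."""
    if number_density_nm3 <= 0:
        raise ValueError("number density must be positive")
    return 10.0 * (n_particles / number_density_nm3) ** (1.0 / 3.0)


def build_initial_state(
    n_solvent: int,
    ion_species: str,
    target_distance: float,
    number_density: float,
    seed: int,
    *,
    table: Optional[SpeciesTable] = None,
    solvent_species: str = "Ar",
    temperature: float = 300.0,
    min_separation_factor: float = 0.85,
    max_retries: int = 50,
) -> SystemState:
    """Two ions at ``target_distance`` (Å) straddling the box centre, plus
    ``n_solvent`` solvent atoms on a perturbed simple-cubic lattice.

    The box side is ((n_solvent + 2)/ρ)^(1/3) with ρ in nm⁻³.  No solvent
    pair (and no solvent–ion pair) is closer than
    ``min_separation_factor``·σ of the pair; velocities are
    Maxwell–Boltzmann at ``temperature`` with zero net momentum.
    """
    from .species import default_species_table

    if n_solvent < 32:
        raise ValueError("need at least 32 solvent atoms")
    if target_distance <= 0:
        raise ValueError("target distance must be positive")
    if table is None:
        table = default_species_table()
    n_total = n_solvent + 2
    side = box_side_from_density(n_total, number_density)
    if target_distance >= side / 2:
        raise ValueError(
            f"target distance {target_distance:.2f} Å violates the minimum-image "
            f"convention for box side {side:.2f} Å (limit {side / 2:.2f} Å)"
        )
    box = SimulationBox(side)
    rng = np.random.default_rng(seed)

    ion = table[ion_species]
    solv = table[solvent_species]
    centre = np.full(3, side / 2.0)
    ion_pos = np.array(
        [centre + [target_distance / 2.0, 0, 0], centre - [target_distance / 2.0, 0, 0]]
    )

    # simple-cubic candidate sites, kept away from the ions
    m = int(np.ceil(n_total ** (1.0 / 3.0)))
    while m**3 < n_total + 8:
        m += 1
    spacing = side / m
    grid = (np.arange(m) + 0.5) * spacing
    sites = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1).reshape(-1, 3)

    sig_ss = solv.lj_sigma
    sig_si = 0.5 * (solv.lj_sigma + ion.lj_sigma)
    d_ion = np.linalg.norm(
        box.minimum_image(sites[:, None, :] - ion_pos[None, :, :]), axis=-1
    ).min(axis=1)
    ok = d_ion > min_separation_factor * sig_si
    sites = sites[ok][np.argsort(-d_ion[ok])]
    if len(sites) < n_solvent:
        raise ValueError("density/side combination leaves too few non-overlapping sites")

    jitter = 0.45 * max(spacing - min_separation_factor * sig_ss, 0.05 * spacing)
    for attempt in range(max_retries):
        chosen = sites[rng.permutation(len(sites))[:n_solvent]]
        pos = chosen + rng.uniform(-jitter, jitter, size=chosen.shape)
        pos %= side
        all_pos = np.vstack([ion_pos, pos])
        dr = box.minimum_image(all_pos[:, None, :] - all_pos[None, :, :])
        dist = np.linalg.norm(dr, axis=-1)
        iu = np.triu_indices(n_total, k=1)
        dmin = dist[iu]
        # pairwise separation floors: solvent-solvent and ion-solvent
        limit = np.full(n_total, min_separation_factor * sig_ss)
        limit[:2] = min_separation_factor * sig_si
        pair_limit = np.minimum(limit[iu[0]], limit[iu[1]])
        pair_limit_full = np.where(
            (iu[0] < 2) & (iu[1] < 2), 0.0, pair_limit
        )  # ion-ion distance is the constraint target, not checked here
        if np.all(dmin >= pair_limit_full):
            break
        jitter *= 0.7
    else:
        raise RuntimeError(
            f"could not place {n_solvent} solvent atoms without overlaps "
            f"after {max_retries} retries"
        )

    species_names = [solvent_species, ion_species]
    species_index = np.array([1, 1] + [0] * n_solvent)
    masses = np.where(species_index == 1, ion.mass, solv.mass)
    velocities = maxwell_boltzmann_velocities(masses, temperature, rng)
    return SystemState(all_pos, velocities, species_index, species_names, box, rng_seed=seed)
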