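"""Constrained velocity-Verlet dynamics with stochastic velocity rescaling.

The interionic distance is held by the SHAKE/RATTLE pair of projections
(positions, then velocities) for a single holonomic distance constraint,
solved in closed form.  Temperature is controlled by the stochastic
velocity rescaling (SVR) thermostat, which rescales the total kinetic
energy towards its canonical equilibrium distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np

from .constants import BOLTZMANN_KJ_MOL_K, FORCE_TO_ACCEL, KINETIC_TO_KJ_MOL
from .system import SystemState

__all__ = [
    "ConstraintSpec",
    "ThermostatSpec",
    "ConstrainedVerlet",
    "rattle_constrained_step",
    "svr_scale_factor",
]

ForceProvider = Callable[[np.ndarray], Tuple[np.ndarray, float]]


@dataclass(frozen=True)
class ConstraintSpec:
    """Holonomic distance constraint between two particles."""

    ion_indices: Tuple[int, int]
    target_distance: float
    tolerance: float = 1e-8  # relative

    def __post_init__(self) -> None:
        i, j = self.ion_indices
        if i == j:
            raise ValueError("constraint indices must be distinct")
        if self.target_distance <= 0:
            raise ValueError("target distance must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass(frozen=True)
class ThermostatSpec:
    """Stochastic velocity rescaling (canonical-sampling) thermostat."""

    temperature: float
    time_constant: float  # fs
    scheme: str = "svr"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.time_constant <= 0:
            raise ValueError("time constant must be positive")


def svr_scale_factor(
    kinetic: float,
    n_dof: int,
    dt: float,
    tau: float,
    target_temperature: float,
    rng: np.random.Generator,
) -> float:
    """Velocity scale factor for one SVR step (Bussi-style resampling of the
    total kinetic energy towards the canonical distribution)."""
    if kinetic <= 0:
        return 1.0
    c = np.exp(-dt / tau)
    kbar = 0.5 * n_dof * BOLTZMANN_KJ_MOL_K * target_temperature
    r1 = rng.standard_normal()
    s = rng.chisquare(n_dof - 1) if n_dof > 1 else 0.0
    a2 = (
        c
        + (1.0 - c) * kbar / (n_dof * kinetic) * (r1 * r1 + s)
        + 2.0 * r1 * np.sqrt(c * (1.0 - c) * kbar / (n_dof * kinetic))
    )
    return float(np.sqrt(max(a2, 0.0)))


@dataclass
class StepResult:
    potential_energy: float
    kinetic_energy: float
    constraint_force: float
    projected_force: float
    distance: float


class ConstrainedVerlet:
    """Velocity-Verlet integrator with an optional single distance constraint
    and optional SVR thermostat.

    ``force_provider(positions) -> (forces, potential_energy)`` supplies the
    potential forces (constraint forces are handled internally).
    """

    def __init__(
        self,
        force_provider: ForceProvider,
        masses: np.ndarray,
        dt: float,
        constraint: Optional[ConstraintSpec] = None,
        thermostat: Optional[ThermostatSpec] = None,
        rng: Optional[np.random.Generator] = None,
    ):
        if dt <= 0:
            raise ValueError("timestep must be positive")
        self.force_provider = force_provider
        self.masses = np.asarray(masses, dtype=float)
        self.dt = dt
        self.constraint = constraint
        self.thermostat = thermostat
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self._forces: Optional[np.ndarray] = None
        self._potential: float = 0.0

    @property
    def n_dof(self) -> int:
        n = 3 * len(self.masses) - 3
        if self.constraint is not None:
            n -= 1
        return n

    def kinetic_energy(self, velocities: np.ndarray) -> float:
        return 0.5 * KINETIC_TO_KJ_MOL * float(
            (self.masses[:, None] * velocities**2).sum()
        )

    def _shake(self, pos_new, pos_old, vel_half):
        """Closed-form position projection for the distance constraint.

        Returns the SHAKE Lagrange force magnitude with positive values
        meaning the potential forces push the ions apart.
        """
        cons = self.constraint
        i, j = cons.ion_indices
        d = cons.target_distance
        inv_mu = 1.0 / self.masses[i] + 1.0 / self.masses[j]
        d_ref = pos_old[i] - pos_old[j]
        s = pos_new[i] - pos_new[j]
        a = float(d_ref @ d_ref) * inv_mu**2
        b = 2.0 * float(s @ d_ref) * inv_mu
        c = float(s @ s) - d * d
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            raise RuntimeError(
                "constraint solver failed (timestep too large for the constraint)"
            )
        # root of smaller magnitude, numerically stable form
        qf = -0.5 * (b + np.copysign(np.sqrt(disc), b))
        lam = c / qf if qf != 0.0 else 0.0
        pos_new[i] += lam / self.masses[i] * d_ref
        pos_new[j] -= lam / self.masses[j] * d_ref
        vel_half[i] += lam / (self.masses[i] * self.dt) * d_ref
        vel_half[j] -= lam / (self.masses[j] * self.dt) * d_ref
        dist = float(np.linalg.norm(pos_new[i] - pos_new[j]))
        if abs(dist - d) / d > cons.tolerance:
            raise RuntimeError("constraint iteration diverged")
        # applied force on i is 2 lam d_ref / (dt^2 * FORCE_TO_ACCEL); report
        # its negative projection, i.e. the mean interparticle force it balances
        g = -2.0 * lam * float(np.linalg.norm(d_ref)) / (self.dt**2 * FORCE_TO_ACCEL)
        return g

    def _rattle(self, pos, vel):
        i, j = self.constraint.ion_indices
        d = pos[i] - pos[j]
        inv_mu = 1.0 / self.masses[i] + 1.0 / self.masses[j]
        v_rel = vel[i] - vel[j]
        k = -float(v_rel @ d) / (inv_mu * float(d @ d))
        vel[i] += k / self.masses[i] * d
        vel[j] -= k / self.masses[j] * d

    def projected_force(self, positions: np.ndarray, forces: np.ndarray) -> float:
        """Antisymmetric projection ½(F_i − F_j)·r̂ of the potential forces on
        the interionic axis; positive = pushing the ions apart."""
        i, j = self.constraint.ion_indices
        d = positions[i] - positions[j]
        rhat = d / np.linalg.norm(d)
        return 0.5 * float((forces[i] - forces[j]) @ rhat)

    def step(self, state: SystemState) -> StepResult:
        """Advance ``state`` in place by one timestep."""
        dt = self.dt
        pos, vel = state.positions, state.velocities
        if self._forces is None:
            self._forces, self._potential = self.force_provider(pos)
        acc = FORCE_TO_ACCEL * self._forces / self.masses[:, None]
        vel += 0.5 * dt * acc
        pos_old = pos.copy()
        pos += dt * vel
        g = 0.0
        if self.constraint is not None:
            g = self._shake(pos, pos_old, vel)
        forces_new, potential = self.force_provider(pos)
        vel += 0.5 * dt * FORCE_TO_ACCEL * forces_new / self.masses[:, None]
        if self.constraint is not None:
            self._rattle(pos, vel)
        f_proj = (
            self.projected_force(pos, forces_new) if self.constraint is not None else 0.0
        )
        if self.thermostat is not None:
            ke = self.kinetic_energy(vel)
            factor = svr_scale_factor(
                ke, self.n_dof, dt, self.thermostat.time_constant,
                self.thermostat.temperature, self.rng,
            )
            vel *= factor
        self._forces, self._potential = forces_new, potential
        ke = self.kinetic_energy(vel)
        dist = 0.0
        if self.constraint is not None:
            i, j = self.constraint.ion_indices
            dist = float(np.linalg.norm(pos[i] - pos[j]))
        return StepResult(potential, ke, g, f_proj, dist)

    def invalidate_forces(self) -> None:
        self._forces = None


def rattle_constrained_step(
    state: SystemState,
    constraint: ConstraintSpec,
    dt: float,
    force_provider: ForceProvider,
    masses: np.ndarray,
) -> Tuple[SystemState, float]:
    """Single constrained velocity-Verlet step (convenience wrapper).

    Advances ``state`` in place and returns it together with the constraint
    Lagrange force magnitude (positive = pushing the ions apart).  For MD
    loops use :class:`ConstrainedVerlet`, which caches forces between steps.
    """
    integ = ConstrainedVerlet(force_provider, masses, dt, constraint=constraint)
    res = integ.step(state)
    return state, res.constraint_force
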