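"""Lennard-Jones parameter toolkit.

Combination rules, vacuum-Coulomb subtraction from supplied interaction
energy scans (e.g. quantum-chemical gas-phase curves provided as TSV),
and LJ 12-6 least-squares fitting.  No electronic-structure calculations
are performed here: scans are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
from scipy.optimize import least_squares

from .constants import COULOMB_CONSTANT
from .species import SpeciesParams

__all__ = [
    "EnergyScan",
    "combine_lorentz_berthelot",
    "subtract_vacuum_coulomb",
    "fit_lj_curve",
    "lj_energy",
]


@dataclass(frozen=True)
class EnergyScan:
    """Interaction energy curve E(r) for one species pair.

    distances in Å (strictly increasing), energies in kJ/mol, charges in e.
    """

    distances: np.ndarray
    energies: np.ndarray
    species_pair: Tuple[str, str] = ("A", "B")
    charges: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "distances", np.asarray(self.distances, dtype=float))
        object.__setattr__(self, "energies", np.asarray(self.energies, dtype=float))
        if self.distances.shape != self.energies.shape or self.distances.ndim != 1:
            raise ValueError("distances and energies must be 1-d arrays of equal length")
        if len(self.distances) < 4:
            raise ValueError("need at least four scan points")
        if not np.all(np.diff(self.distances) > 0):
            raise ValueError("scan distances must be strictly increasing")


def combine_lorentz_berthelot(i: SpeciesParams, j: SpeciesParams) -> Tuple[float, float]:
    """Lorentz–Berthelot cross terms: σ arithmetic mean, ε geometric mean."""
    if i.lj_epsilon < 0 or j.lj_epsilon < 0:
        raise ValueError("negative epsilon")
    return 0.5 * (i.lj_sigma + j.lj_sigma), float(np.sqrt(i.lj_epsilon * j.lj_epsilon))


def subtract_vacuum_coulomb(scan: EnergyScan) -> EnergyScan:
    """Remove k_C·q₁q₂/r pointwise, leaving the van der Waals part.

    The result carries zero charges, so re-adding the Coulomb term after
    restoring the charges is an exact inverse.
    """
    if np.any(scan.distances <= 0):
        raise ValueError("scan contains non-positive distances")
    q1, q2 = scan.charges
    coul = COULOMB_CONSTANT * q1 * q2 / scan.distances
    return replace(scan, energies=scan.energies - coul, charges=(0.0, 0.0))


def lj_energy(r: np.ndarray, sigma: float, epsilon: float) -> np.ndarray:
    """LJ 12-6: 4ε[(σ/r)¹² − (σ/r)⁶]."""
    s6 = (sigma / np.asarray(r, dtype=float)) ** 6
    return 4.0 * epsilon * (s6 * s6 - s6)


def fit_lj_curve(scan: EnergyScan) -> Tuple[float, float, float]:
    """Least-squares LJ 12-6 fit of a scan; returns (σ Å, ε kJ/mol, rms).

    Deterministic multistart over σ seeded from the scan's minimum location
    (r_min = 2^(1/6)·σ for an exact LJ curve).  A scan with no attractive
    well (all energies ≥ 0) is rejected as ill-posed for ε.
    """
    r, e = scan.distances, scan.energies
    i_min = int(np.argmin(e))
    if e[i_min] >= 0:
        raise ValueError(
            "scan has no attractive well (all energies >= 0); epsilon is not "
            "identifiable from a repulsive-only curve"
        )
    sigma0 = r[i_min] / 2.0 ** (1.0 / 6.0)
    eps0 = -float(e[i_min])

    def residuals(p):
        ls, le = p  # log-parameterized for positivity
        return lj_energy(r, np.exp(ls), np.exp(le)) - e

    best = None
    for fac in (1.0, 0.9, 1.1, 0.75, 1.25):
        try:
            sol = least_squares(
                residuals,
                x0=[np.log(sigma0 * fac), np.log(eps0)],
                method="lm",
                max_nfev=2000,
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("LJ fit failed to converge from all starts")
    sigma, eps = np.exp(best.x)
    rms = float(np.sqrt(np.mean(residuals(best.x) ** 2)))
    return float(sigma), float(eps), rms
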