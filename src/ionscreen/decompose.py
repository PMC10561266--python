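"""Free-energy decomposition: extracting the Coulombic contribution.

Writing the constrained free energy as F = U_C + U_vdW − T·S and assuming
the van der Waals and entropic terms of the charged and zero-charge
systems match (the engine guarantees identical LJ parameters between the
two modes by construction), subtracting the zero-charge profile from the
charged one leaves the screened Coulomb interaction U_C(r).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .profiles import FreeEnergyProfile

__all__ = ["CoulombProfile", "extract_coulomb_profile"]


@dataclass
class CoulombProfile:
    """U_C(r): electrostatic residual after the zero-charge subtraction."""

    distances: np.ndarray  # Å
    coulomb_energy: np.ndarray  # kJ/mol
    sigma: Optional[np.ndarray] = None  # kJ/mol

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.coulomb_energy = np.asarray(self.coulomb_energy, dtype=float)
        if self.distances.shape != self.coulomb_energy.shape:
            raise ValueError("grid length mismatch")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.distances.shape:
                raise ValueError("sigma grid length mismatch")
        if not np.all(np.diff(self.distances) > 0):
            raise ValueError("distance grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.distances)


def extract_coulomb_profile(
    charged: FreeEnergyProfile, zerocharge: FreeEnergyProfile
) -> CoulombProfile:
    """U_C = F_charged − F_zerocharge on the charged profile's grid.

    The zero-charge profile is linearly interpolated onto the charged grid;
    charged grid points outside the overlap are dropped.  Uncertainties are
    combined in quadrature (interpolation treated as exact).  Both profiles
    must carry the volume-entropy correction at the same temperature (the
    correction then cancels exactly in the subtraction).
    """
    if charged.corrected != zerocharge.corrected:
        raise ValueError("profiles disagree on the volume-entropy correction flag")
    if (
        charged.temperature is not None
        and zerocharge.temperature is not None
        and not np.isclose(charged.temperature, zerocharge.temperature)
    ):
        raise ValueError("profiles were corrected at different temperatures")
    lo = max(charged.distances[0], zerocharge.distances[0])
    hi = min(charged.distances[-1], zerocharge.distances[-1])
    keep = (charged.distances >= lo - 1e-12) & (charged.distances <= hi + 1e-12)
    if keep.sum() < 2:
        raise ValueError("profiles have no usable distance overlap")
    r = charged.distances[keep]
    f_zero = np.interp(r, zerocharge.distances, zerocharge.free_energy)
    u_c = charged.free_energy[keep] - f_zero
    sigma = None
    if charged.sigma is not None or zerocharge.sigma is not None:
        s_c = charged.sigma[keep] if charged.sigma is not None else np.zeros_like(r)
        s_z = (
            np.interp(r, zerocharge.distances, zerocharge.sigma)
            if zerocharge.sigma is not None
            else np.zeros_like(r)
        )
        sigma = np.sqrt(s_c**2 + s_z**2)
    return CoulombProfile(distances=r, coulomb_energy=u_c, sigma=sigma)
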