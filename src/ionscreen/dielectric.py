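"""Clausius–Mossotti relations and the electronic-continuum-correction scaling factor.

The electronic dielectric constant of a nonpolar fluid of isotropic
polarizability volume α′ (Å³) at number density ρ (Å⁻³) follows the
Clausius–Mossotti relation

    (ε − 1)/(ε + 2) = (4π/3) ρ α′,

and the ECC charge-scaling factor is s = ε_el^(−1/2): scaling ionic
charges by s embeds the system in an electronic dielectric continuum of
permittivity ε_el in a mean-field way.  ε_nuc = 1 for the argon-like
solvent modelled here, so ε_el is the only dielectric response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import FOUR_PI_OVER_3, molar_to_number_density

__all__ = [
    "DielectricSpec",
    "clausius_mossotti_epsilon",
    "alpha_for_epsilon",
    "scaling_from_epsilon",
    "epsilon_from_scaling",
    "molar_to_number_density",
]


def clausius_mossotti_epsilon(polarizability_volume: float, number_density: float) -> float:
    """Electronic dielectric constant from α′ (Å³) and ρ (Å⁻³).

    Raises ``ValueError`` below/at the polarization catastrophe
    (4π/3·ρ·α′ ≥ 1, where ε diverges) or for negative inputs.
    """
    if polarizability_volume < 0:
        raise ValueError("polarizability volume must be non-negative")
    if number_density <= 0:
        raise ValueError("number density must be positive")
    x = FOUR_PI_OVER_3 * number_density * polarizability_volume
    if x >= 1.0:
        raise ValueError(
            f"(4pi/3) rho alpha' = {x:.4f} >= 1: beyond the polarization catastrophe"
        )
    return (1.0 + 2.0 * x) / (1.0 - x)


def alpha_for_epsilon(epsilon_el: float, number_density: float) -> float:
    """Polarizability volume (Å³) that yields ``epsilon_el`` at ρ (Å⁻³).

    Exact inverse of :func:`clausius_mossotti_epsilon`.
    """
    if epsilon_el < 1.0:
        raise ValueError("epsilon_el must be >= 1")
    if number_density <= 0:
        raise ValueError("number density must be positive")
    x = (epsilon_el - 1.0) / (epsilon_el + 2.0)
    return x / (FOUR_PI_OVER_3 * number_density)


def scaling_from_epsilon(epsilon_el: float) -> float:
    """ECC charge-scaling factor s = 1/sqrt(ε_el); 0 < s ≤ 1."""
    if epsilon_el < 1.0:
        raise ValueError("epsilon_el must be >= 1")
    return 1.0 / math.sqrt(epsilon_el)


def epsilon_from_scaling(s: float) -> float:
    """Inverse of :func:`scaling_from_epsilon`: ε_el = s⁻²."""
    if not 0.0 < s <= 1.0:
        raise ValueError("scaling factor must lie in (0, 1]")
    return 1.0 / (s * s)


@dataclass(frozen=True)
class DielectricSpec:
    """Consistent (ε_el, ρ, α′) triple; any two determine the third.

    Construct via :meth:`from_epsilon` or :meth:`from_alpha`.  Density in
    Å⁻³, polarizability volume in Å³.
    """

    epsilon_el: float
    number_density: float
    polarizability_volume: float

    def __post_init__(self) -> None:
        if self.epsilon_el < 1.0:
            raise ValueError("epsilon_el must be >= 1")
        if self.number_density <= 0:
            raise ValueError("number density must be positive")
        eps = clausius_mossotti_epsilon(self.polarizability_volume, self.number_density)
        if not math.isclose(eps, self.epsilon_el, rel_tol=1e-6):
            raise ValueError("fields are not Clausius-Mossotti consistent")

    @classmethod
    def from_epsilon(cls, epsilon_el: float, number_density: float) -> "DielectricSpec":
        alpha = alpha_for_epsilon(epsilon_el, number_density)
        return cls(epsilon_el, number_density, alpha)

    @classmethod
    def from_alpha(cls, polarizability_volume: float, number_density: float) -> "DielectricSpec":
        eps = clausius_mossotti_epsilon(polarizability_volume, number_density)
        return cls(eps, number_density, polarizability_volume)

    @property
    def scaling_factor(self) -> float:
        return scaling_from_epsilon(self.epsilon_el)
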