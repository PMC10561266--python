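"""Species parameters: mass, charge, polarizability and Lennard-Jones terms."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable

__all__ = ["SpeciesParams", "SpeciesTable", "default_species_table"]


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species force-field parameters.

    mass in g/mol, charge in elementary charges, polarizability volume α′
    in Å³ (isotropic), LJ σ in Å and ε in kJ/mol.
    """

    name: str
    mass: float
    charge: float = 0.0
    polarizability_volume: float = 0.0
    lj_sigma: float = 1.0
    lj_epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"{self.name}: mass must be positive")
        if self.polarizability_volume < 0:
            raise ValueError(f"{self.name}: polarizability volume must be non-negative")
        if self.lj_sigma <= 0:
            raise ValueError(f"{self.name}: lj_sigma must be positive")
        if self.lj_epsilon < 0:
            raise ValueError(f"{self.name}: lj_epsilon must be non-negative")

    def neutral(self) -> "SpeciesParams":
        """Copy with charge and polarizability zeroed (zero-charge LJ mode)."""
        return replace(self, charge=0.0, polarizability_volume=0.0)


class SpeciesTable:
    """Ordered mapping of species name -> :class:`SpeciesParams`."""

    def __init__(self, species: Iterable[SpeciesParams]):
        self._table: Dict[str, SpeciesParams] = {}
        for sp in species:
            if sp.name in self._table:
                raise ValueError(f"duplicate species {sp.name!r}")
            self._table[sp.name] = sp
        if not self._table:
            raise ValueError("species table may not be empty")

    def __getitem__(self, name: str) -> SpeciesParams:
        return self._table[name]

    def __contains__(self, name: str) -> bool:
        return name in self._table

    def __iter__(self):
        return iter(self._table.values())

    def __len__(self) -> int:
        return len(self._table)

    @property
    def names(self):
        return list(self._table)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def zero_charge(self) -> "SpeciesTable":
        """Table with every charge and polarizability zeroed."""
        return SpeciesTable(sp.neutral() for sp in self)

    def with_species(self, sp: SpeciesParams) -> "SpeciesTable":
        out = dict(self._table)
        out[sp.name] = sp
        return SpeciesTable(out.values())


# Representative parameters: OPLS-AA argon; monovalent-ion LJ values of the
# magnitudes used for aqueous-solution force fields.  The decomposition is
# insensitive to the exact ion vdW terms because the zero-charge reference
# run uses the same ones and they cancel in the subtraction.
_DEFAULTS = {
    "Ar": SpeciesParams("Ar", mass=39.948, lj_sigma=3.401, lj_epsilon=0.9786),
    "Na": SpeciesParams("Na", mass=22.990, charge=1.0, lj_sigma=2.35, lj_epsilon=0.544),
    "K": SpeciesParams("K", mass=39.098, charge=1.0, lj_sigma=2.94, lj_epsilon=0.42),
    "Cl": SpeciesParams("Cl", mass=35.453, charge=-1.0, lj_sigma=4.10, lj_epsilon=0.49),
    "Br": SpeciesParams("Br", mass=79.904, charge=-1.0, lj_sigma=4.35, lj_epsilon=0.45),
}


def default_species_table(solvent_polarizability: float = 0.0) -> SpeciesTable:
    """Default Ar + alkali/halide table; solvent α′ set by the caller
    (typically from :func:`ionscreen.dielectric.alpha_for_epsilon`)."""
    ar = replace(_DEFAULTS["Ar"], polarizability_volume=solvent_polarizability)
    return SpeciesTable([ar] + [_DEFAULTS[k] for k in ("Na", "K", "Cl", "Br")])
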