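"""Physical constants and unit conversions for the internal unit system.

Internal units: length Å, time fs, mass g/mol, energy kJ/mol, charge e,
temperature K.  Electrostatic quantities are carried in Gaussian-like
e-units (field e/Å², dipole e·Å) and converted to kJ/mol with
``COULOMB_CONSTANT``.
"""

import math

#: e^2 / (4 pi eps0) in kJ·Å/mol — Coulomb energy of two unit charges 1 Å apart.
COULOMB_CONSTANT = 1389.35457644382

#: Boltzmann constant in kJ/mol/K (CODATA, molar).
BOLTZMANN_KJ_MOL_K = 0.00831446261815324

#: Avogadro constant in 1/mol.
AVOGADRO = 6.02214076e23

#: 1 (g/mol)·(Å/fs)^2 expressed in kJ/mol; kinetic energy is
#: 0.5 * m * v^2 * KINETIC_TO_KJ_MOL.
KINETIC_TO_KJ_MOL = 1.0e4

#: Acceleration in Å/fs^2 per (kJ/mol/Å) / (g/mol).
FORCE_TO_ACCEL = 1.0e-4

FOUR_PI_OVER_3 = 4.0 * math.pi / 3.0


def molar_to_number_density(molar_density_mol_m3: float) -> float:
    """Convert a molar density in mol/m³ to a number density in nm⁻³.

    Example: liquid argon near 1 bar, 35250 mol/m³ → 21.228 nm⁻³.
    """
    if molar_density_mol_m3 <= 0:
        raise ValueError("molar density must be positive")
    return molar_density_mol_m3 * AVOGADRO * 1e-27
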