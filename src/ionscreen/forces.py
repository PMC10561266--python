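"""Lennard-Jones and permanent-charge electrostatic forces.

LJ 12-6 interactions use Lorentz–Berthelot cross terms and a shifted-force
cutoff (energy and force both continuous at the cutoff), so analytic forces
are the exact negative gradient of the reported energy everywhere.

Permanent-charge electrostatics supports three schemes:

``none``
    direct cutoff-free sum over the charges as placed (no periodic images);
``shifted_force_cutoff``
    minimum-image shifted-force Coulomb at the cutoff;
``ewald_background``
    full Ewald summation with an implicit uniform neutralizing background
    for net-charged cells (the like-charge ion pair carries ±2e).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.special import erfc

from .constants import COULOMB_CONSTANT
from .species import SpeciesTable
from .system import SimulationBox, SystemState, per_particle_arrays

__all__ = ["LJCoulomb", "lj_coulomb_forces", "SCHEMES"]

SCHEMES = ("ewald_background", "shifted_force_cutoff", "none")

_MIN_PAIR_DISTANCE = 0.1  # Å; below this the configuration is unphysical


@lru_cache(maxsize=8)
def _ewald_kvectors(side: float, alpha: float, accuracy: float = 1e-10):
    """Reciprocal vectors and Gaussian weights for a cubic cell (cached)."""
    kcut = 2.0 * alpha * math.sqrt(-math.log(accuracy))
    nmax = int(math.ceil(kcut * side / (2.0 * math.pi)))
    rng = np.arange(-nmax, nmax + 1)
    n = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    n = n[np.any(n != 0, axis=1)]
    k = 2.0 * math.pi / side * n.astype(float)
    k2 = np.einsum("ij,ij->i", k, k)
    keep = k2 <= kcut**2
    k, k2 = k[keep], k2[keep]
    coeff = np.exp(-k2 / (4.0 * alpha**2)) / k2
    return k, coeff


class LJCoulomb:
    """Pairwise LJ + permanent-charge force field bound to a fixed topology.

    Pre-computes the pair LJ parameter matrices so that :meth:`evaluate`
    can be called once per MD step with only the positions changing.
    """

    def __init__(
        self,
        species_index: np.ndarray,
        species_names,
        table: SpeciesTable,
        box: SimulationBox,
        scheme: str = "ewald_background",
        lj_cutoff: float | None = None,
        coulomb_cutoff: float | None = None,
        ewald_alpha: float | None = None,
    ):
        if scheme not in SCHEMES:
            raise ValueError(f"unknown electrostatics scheme {scheme!r}; choose from {SCHEMES}")
        if scheme == "ewald_background" and not box.periodic:
            raise ValueError("Ewald summation requires a periodic box")
        self.box = box
        self.scheme = scheme
        _, charge, _, sigma, eps = per_particle_arrays(
            SystemState(
                np.zeros((len(species_index), 3)),
                np.zeros((len(species_index), 3)),
                species_index,
                species_names,
                box,
            ),
            table,
        )
        self.charges = charge
        half = box.side_length / 2.0 if box.periodic else math.inf
        self.lj_cutoff = half if lj_cutoff is None else lj_cutoff
        self.coulomb_cutoff = half if coulomb_cutoff is None else coulomb_cutoff
        if box.periodic and (
            self.lj_cutoff > half + 1e-9
            or (scheme == "shifted_force_cutoff" and self.coulomb_cutoff > half + 1e-9)
        ):
            raise ValueError("cutoffs must not exceed half the box side (minimum image)")
        self.ewald_alpha = 7.0 / box.side_length if ewald_alpha is None else ewald_alpha

        n = len(species_index)
        self._n = n
        self._iu = np.triu_indices(n, k=1)
        sig_ij = 0.5 * (sigma[:, None] + sigma[None, :])[self._iu]
        eps_ij = np.sqrt(eps[:, None] * eps[None, :])[self._iu]
        self._sig6 = sig_ij**6
        self._eps_ij = eps_ij
        self._active_lj = eps_ij > 0.0
        self._qidx = np.flatnonzero(charge != 0.0)

    # -- LJ (shifted force) -------------------------------------------------
    def _lj(self, dr, r):
        rc = self.lj_cutoff
        mask = self._active_lj & (r < rc)
        e = np.zeros_like(r)
        fmag = np.zeros_like(r)
        if np.any(mask):
            rm = r[mask]
            s6 = self._sig6[mask] / rm**6
            s12 = s6 * s6
            epsm = self._eps_ij[mask]
            e[mask] = 4.0 * epsm * (s12 - s6)
            fmag[mask] = 24.0 * epsm * (2.0 * s12 - s6) / rm
            if math.isfinite(rc):  # shifted-force continuity terms
                s6c = self._sig6[mask] / rc**6
                s12c = s6c * s6c
                u_rc = 4.0 * epsm * (s12c - s6c)
                f_rc = 24.0 * epsm * (2.0 * s12c - s6c) / rc
                e[mask] += -u_rc + (rm - rc) * f_rc
                fmag[mask] -= f_rc
        return e, fmag

    # -- Coulomb ------------------------------------------------------------
    def _coulomb_pairwise(self, positions):
        """Energy/forces of direct or shifted-force Coulomb among charges."""
        q = self.charges[self._qidx]
        pos = positions[self._qidx]
        m = len(q)
        if m < 2:
            return 0.0, np.zeros((self._n, 3))
        iu = np.triu_indices(m, k=1)
        dr = pos[iu[0]] - pos[iu[1]]
        if self.scheme == "shifted_force_cutoff":
            dr = self.box.minimum_image(dr)
        r = np.linalg.norm(dr, axis=1)
        qq = q[iu[0]] * q[iu[1]]
        kc = COULOMB_CONSTANT
        if self.scheme == "none":
            e = kc * qq / r
            fmag = kc * qq / r**2
        else:
            rc = self.coulomb_cutoff
            inside = r < rc
            e = np.zeros_like(r)
            fmag = np.zeros_like(r)
            rm = r[inside]
            qqm = qq[inside]
            e[inside] = kc * qqm * (1.0 / rm - 1.0 / rc + (rm - rc) / rc**2)
            fmag[inside] = kc * qqm * (1.0 / rm**2 - 1.0 / rc**2)
        forces = np.zeros((self._n, 3))
        fvec = (fmag / r)[:, None] * dr
        np.add.at(forces, self._qidx[iu[0]], fvec)
        np.add.at(forces, self._qidx[iu[1]], -fvec)
        return float(e.sum()), forces

    def _coulomb_ewald(self, positions):
        q = self.charges[self._qidx]
        pos = positions[self._qidx]
        kc = COULOMB_CONSTANT
        alpha = self.ewald_alpha
        V = self.box.volume
        forces = np.zeros((self._n, 3))

        energy = -kc * alpha / math.sqrt(math.pi) * float(np.sum(q * q))  # self
        energy -= kc * math.pi / (2.0 * alpha**2 * V) * float(np.sum(q)) ** 2  # background

        m = len(q)
        if m >= 2:
            iu = np.triu_indices(m, k=1)
            dr = self.box.minimum_image(pos[iu[0]] - pos[iu[1]])
            r = np.linalg.norm(dr, axis=1)
            qq = q[iu[0]] * q[iu[1]]
            ar = alpha * r
            erfc_ar = erfc(ar)
            energy += kc * float(np.sum(qq * erfc_ar / r))
            fmag = kc * qq * (
                erfc_ar / r**2 + 2.0 * alpha / math.sqrt(math.pi) * np.exp(-(ar**2)) / r
            )
            fvec = (fmag / r)[:, None] * dr
            np.add.at(forces, self._qidx[iu[0]], fvec)
            np.add.at(forces, self._qidx[iu[1]], -fvec)

        kvec, coeff = _ewald_kvectors(self.box.side_length, alpha)
        phase = kvec @ pos.T  # (K, m)
        cosp, sinp = np.cos(phase), np.sin(phase)
        re_s = cosp @ q
        im_s = sinp @ q
        energy += kc * (2.0 * math.pi / V) * float(np.sum(coeff * (re_s**2 + im_s**2)))
        # F_i = kc (4 pi / V) q_i sum_k coeff * (sin(k.r_i) Re S - cos(k.r_i) Im S) k
        proj = coeff[:, None] * (sinp * re_s[:, None] - cosp * im_s[:, None])  # (K, m)
        f_q = kc * (4.0 * math.pi / V) * (q[:, None] * (proj.T @ kvec))
        forces[self._qidx] += f_q
        return energy, forces

    # -- total --------------------------------------------------------------
    def evaluate(self, positions: np.ndarray):
        """Return (forces (N,3) kJ/mol/Å, potential energy kJ/mol)."""
        # LJ terms are always minimum-image; the electrostatics scheme only
        # governs how the (few) permanent charges interact.
        dr = self.box.minimum_image(positions[self._iu[0]] - positions[self._iu[1]])
        r = np.linalg.norm(dr, axis=1)
        if float(r.min(initial=np.inf)) < _MIN_PAIR_DISTANCE:
            raise ValueError(
                f"pair distance {r.min():.3f} Å below {_MIN_PAIR_DISTANCE} Å: unphysical overlap"
            )
        e_lj, fmag = self._lj(dr, r)
        forces = np.zeros((self._n, 3))
        fvec = (fmag / r)[:, None] * dr
        np.add.at(forces, self._iu[0], fvec)
        np.add.at(forces, self._iu[1], -fvec)
        energy = float(e_lj.sum())

        if len(self._qidx) >= 1:
            if self.scheme == "ewald_background":
                e_c, f_c = self._coulomb_ewald(positions)
            else:
                e_c, f_c = self._coulomb_pairwise(positions)
            energy += e_c
            forces += f_c
        return forces, energy


def lj_coulomb_forces(
    state: SystemState,
    table: SpeciesTable,
    scheme: str = "ewald_background",
    **kwargs,
):
    """One-shot evaluation of LJ + permanent-charge forces for ``state``.

    Returns (forces kJ/mol/Å, potential_energy kJ/mol).  For repeated
    evaluation in an MD loop construct :class:`LJCoulomb` once instead.
    """
    ff = LJCoulomb(state.species_index, state.species_names, table, state.box, scheme, **kwargs)
    return ff.evaluate(state.positions)
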