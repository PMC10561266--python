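"""Mean forces, thermodynamic integration, and the volume-entropy correction.

The free-energy profile along the interionic distance is obtained by the
blue-moon route: the mean projected force at each constrained window is
integrated with the cumulative trapezoidal rule, anchored at the largest
sampled distance (F(r_max) = 0), and the radial volume-entropy term
2·k_B·T·ln(r/r_ref) is added so the profile refers to the distance
coordinate rather than a fixed relative position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .constants import BOLTZMANN_KJ_MOL_K
from .windows import MeanForceWindow

__all__ = [
    "FreeEnergyProfile",
    "window_mean_force",
    "block_means",
    "integrate_mean_force",
    "add_entropy_correction",
]


@dataclass
class FreeEnergyProfile:
    """F(r) on a strictly increasing distance grid, with optional per-point σ.

    ``reference`` names the anchoring convention (free energy is zero at the
    reference distance); ``corrected`` records whether the 2kT·ln r
    volume-entropy term has been applied.
    """

    distances: np.ndarray  # Å
    free_energy: np.ndarray  # kJ/mol
    sigma: Optional[np.ndarray] = None  # kJ/mol
    reference: str = "rmax"
    temperature: Optional[float] = None
    corrected: bool = False

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.distances.shape:
                raise ValueError("sigma grid length mismatch")
        if self.distances.shape != self.free_energy.shape:
            raise ValueError("distance and free-energy arrays must have equal length")
        if self.distances.ndim != 1 or len(self.distances) < 2:
            raise ValueError("need a 1-d grid with at least two points")
        if not np.all(np.diff(self.distances) > 0):
            raise ValueError("distance grid must be strictly increasing")

    @property
    def reference_distance(self) -> float:
        return float(self.distances[-1] if self.reference == "rmax" else self.distances[0])

    def __len__(self) -> int:
        return len(self.distances)


def block_means(series: np.ndarray, block_samples: int) -> np.ndarray:
    """Non-overlapping block means; a trailing partial block is dropped."""
    series = np.asarray(series, dtype=float)
    if block_samples < 1:
        raise ValueError("block size must be at least one sample")
    n_blocks = len(series) // block_samples
    if n_blocks < 1:
        raise ValueError("series shorter than one block")
    return series[: n_blocks * block_samples].reshape(n_blocks, block_samples).mean(axis=1)


def window_mean_force(
    window: MeanForceWindow, block_fs: float = 1000.0
) -> Tuple[float, float]:
    """Mean projected force and its block standard error for one window.

    The production series is divided into non-overlapping blocks of
    ``block_fs`` (default 1 ps) to absorb serial correlation; the standard
    error is std(block means)/sqrt(n_blocks).
    """
    if window.production_steps == 0:
        raise ValueError("window has no production samples")
    if block_fs < window.timestep:
        raise ValueError("block length must be at least one timestep")
    series = window.projected_forces
    mean = float(series.mean())
    block_samples = max(int(round(block_fs / window.timestep)), 1)
    if len(series) // block_samples < 2:
        raise ValueError("need at least two blocks for an uncertainty estimate")
    blocks = block_means(series, block_samples)
    stderr = float(blocks.std(ddof=1) / np.sqrt(len(blocks)))
    return mean, stderr


def integrate_mean_force(
    windows: Sequence[Tuple[float, float, float]],
    temperature: Optional[float] = None,
) -> FreeEnergyProfile:
    """Cumulative-trapezoid TI of (r, mean force, stderr) triples.

    F(r) = −∫_{r_max}^{r} f dr′ with F(r_max) = 0, so a repulsive
    (positive) mean force gives a free energy that decreases with
    separation.  Window uncertainties are propagated through the trapezoid
    weights assuming independent windows.
    """
    if len(windows) < 2:
        raise ValueError("need at least two windows to integrate")
    arr = np.asarray(sorted(windows, key=lambda w: w[0]), dtype=float)
    r, f, sig = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.any(np.diff(r) <= 0):
        raise ValueError("duplicate window distances")
    if np.any(~np.isfinite(f)):
        raise ValueError("missing/non-finite mean force")
    dr = np.diff(r)
    # segment integrals, then cumulative sum from the top end downwards
    seg = 0.5 * dr * (f[:-1] + f[1:])
    free = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    # quadrature propagation: coefficient of window j in F(r_k) is its
    # total trapezoid weight over the segments between r_k and r_max
    n = len(r)
    sigma = np.zeros(n)
    j = np.arange(n)
    for k in range(n - 1):
        w = np.zeros(n)
        left = (j >= k) & (j <= n - 2)  # f_j opens segment j
        w[left] += 0.5 * dr[j[left]]
        right = j >= k + 1  # f_j closes segment j-1
        w[right] += 0.5 * dr[j[right] - 1]
        sigma[k] = float(np.sqrt(np.sum((w * sig) ** 2)))
    return FreeEnergyProfile(
        distances=r, free_energy=free, sigma=sigma, reference="rmax",
        temperature=temperature, corrected=False,
    )


def add_entropy_correction(profile: FreeEnergyProfile, temperature: float) -> FreeEnergyProfile:
    """Add the radial volume-entropy term 2·k_B·T·ln(r/r_ref).

    The reference anchoring F(r_ref) = 0 is preserved.  A profile can be
    corrected only once; a second application raises.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if profile.corrected:
        raise ValueError("profile already carries the volume-entropy correction")
    if np.any(profile.distances <= 0):
        raise ValueError("distances must be positive")
    r_ref = profile.reference_distance
    corr = 2.0 * BOLTZMANN_KJ_MOL_K * temperature * np.log(profile.distances / r_ref)
    return replace(
        profile,
        free_energy=profile.free_energy + corr,
        temperature=temperature,
        corrected=True,
    )
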