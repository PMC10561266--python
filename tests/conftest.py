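"""Shared fixtures: species tables and small non-overlapping random states."""

import numpy as np
import pytest

from ionscreen.species import SpeciesParams, SpeciesTable
from ionscreen.system import SimulationBox, SystemState


@pytest.fixture
def argon_table():
    """Polarizable argon (α′ = 1.64 Å³) plus a +1e sodium-like ion."""
    return SpeciesTable(
        [
            SpeciesParams("Ar", 39.948, 0.0, 1.64, 3.401, 0.9786),
            SpeciesParams("Na", 22.990, 1.0, 0.0, 2.35, 0.544),
        ]
    )


@pytest.fixture
def neutral_argon_table():
    return SpeciesTable([SpeciesParams("Ar", 39.948, 0.0, 0.0, 3.401, 0.9786)])


def spread_state(n, box_side, species_index, names, seed=0, min_dist=2.6, periodic=True):
    """Random positions pushed apart until no pair is closer than min_dist."""
    rng = np.random.default_rng(seed)
    box = SimulationBox(box_side, periodic=periodic)
    pos = rng.uniform(0, box_side, size=(n, 3))
    for _ in range(500):
        dr = box.minimum_image(pos[:, None, :] - pos[None, :, :])
        d = np.linalg.norm(dr, axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > min_dist:
            break
        i, j = np.unravel_index(np.argmin(d), d.shape)
        pos[i] += 0.3 * dr[i, j] / d[i, j]
    else:
        raise RuntimeError("could not spread test state")
    return SystemState(pos, np.zeros((n, 3)), species_index, names, box, rng_seed=seed)


@pytest.fixture
def mixed_state(argon_table):
    """8 Ar + 2 Na in a 12 Å periodic box, all pairs > 2.6 Å apart."""
    return spread_state(10, 12.0, [0] * 8 + [1] * 2, ["Ar", "Na"], seed=3)
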