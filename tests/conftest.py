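import warnings

import numpy as np
import pytest

from polytherm.core.types import AtomSet, Box, Trajectory

warnings.filterwarnings("ignore", category=DeprecationWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="MDAnalysis")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trajectory(coords, box=None, times=None, **atom_kwargs):
    """Build a Trajectory from an (F, N, 3) array with defaulted metadata."""
    coords = np.asarray(coords, dtype=float)
    f, n, _ = coords.shape
    box = box or Box(5.0, 5.0, 5.0)
    defaults = dict(
        elements=np.array(["C"] * n, dtype=object),
        vdw_radii=np.full(n, 0.17),
        molecule_ids=np.arange(n),
    )
    defaults.update(atom_kwargs)
    atoms = AtomSet(positions=coords[0], **defaults)
    times = np.arange(f, dtype=float) if times is None else times
    return Trajectory(times=times, coordinates=coords, boxes=[box] * f, atoms=atoms)


@pytest.fixture
def random_frame(rng):
    """Single random 40-atom frame in a 3 nm box."""
    coords = rng.uniform(0, 3, size=(1, 40, 3))
    return make_trajectory(coords, box=Box(3.0, 3.0, 3.0))
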