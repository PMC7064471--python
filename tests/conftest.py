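"""Shared fixtures: coarse unit cells and a short coupled seeding run.

Everything is generated at test time; expensive builds are session-scoped.
"""

import numpy as np
import pytest

from cellseed import geometry as geo
from cellseed.simulate import SeedingConfig, run_seeding


@pytest.fixture(scope="session")
def cubic_spec():
    return geo.default_spec("cubic")


@pytest.fixture(scope="session")
def to_spec():
    return geo.default_spec("truncated_octahedron")


@pytest.fixture(scope="session")
def cubic_cell(cubic_spec):
    """One cubic unit cell at 25-um voxels."""
    return geo.build_cubic_cell(cubic_spec, voxel=0.025)


@pytest.fixture(scope="session")
def to_cell(to_spec):
    """One TO unit cell at 25-um voxels."""
    return geo.build_to_cell(to_spec, voxel=0.025)


@pytest.fixture(scope="session")
def short_run():
    """A short coupled seeding run on a coarse grid (for invariants)."""
    cfg = SeedingConfig(design="cubic", grid_n=32, total_time=2.0,
                        scaffold_voxel_um=50.0, seed=7)
    return cfg, run_seeding(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
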