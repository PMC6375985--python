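"""Shared fixtures: tiny analytic grids and one default-scale synthetic patient."""

from __future__ import annotations

import numpy as np
import pytest

from ptxshim.core_model import Grid3D, RegionMask, TissueModel
from ptxshim.shim_core import CoilFieldMaps
from ptxshim.study_runner import CohortConfig, make_patient


@pytest.fixture(scope="session")
def small_grid() -> Grid3D:
    """5^3 grid with unit-ish spacing for hand-checkable metric tests."""
    return Grid3D.centered((5, 5, 5), (0.004, 0.004, 0.004))


@pytest.fixture(scope="session")
def uniform_tissue(small_grid) -> TissueModel:
    head = np.ones(small_grid.dims, bool)
    return TissueModel.homogeneous(small_grid, head)


@pytest.fixture(scope="session")
def cohort_config() -> CohortConfig:
    return CohortConfig()


@pytest.fixture(scope="session")
def default_patient(cohort_config):
    """First synthetic patient at the study's default scale."""
    return make_patient(cohort_config, 0)


def toy_maps(
    n_channels: int = 2,
    dims=(4, 4, 4),
    seed: int = 0,
    identical_e: bool = False,
    proportional_e: complex | None = None,
) -> tuple[CoilFieldMaps, RegionMask, RegionMask]:
    """Small random-but-seeded maps plus VOI / ROM masks for optimizer tests.

    ``identical_e`` copies channel 0's e-map to every channel;
    ``proportional_e=c`` makes channel n's e-map c**n times channel 0's
    (an exact antiphase-style null exists without the quadrature
    reference itself degenerating to zero).
    """
    rng = np.random.default_rng(seed)
    grid = Grid3D.centered(dims, (0.004, 0.004, 0.004))
    shape = (n_channels,) + tuple(dims)
    E = rng.normal(size=shape + (3,)) + 1j * rng.normal(size=shape + (3,))
    B1 = (rng.normal(size=shape) + 1j * rng.normal(size=shape)) * 1e-6
    if identical_e:
        E = np.repeat(E[:1], n_channels, axis=0)
    if proportional_e is not None:
        factors = proportional_e ** np.arange(n_channels)
        E = E[:1] * factors[:, None, None, None, None]
    maps = CoilFieldMaps(grid=grid, E=E, B1=B1)
    voi = np.zeros(dims, bool)
    voi[1:3, 1:3, 1:3] = True
    rom = np.zeros(dims, bool)
    rom[2, 2, 2] = True
    rom[1, 2, 2] = True
    return (
        maps,
        RegionMask(mask=voi, grid=grid, role="VOI"),
        RegionMask(mask=rom, grid=grid, role="ROM"),
    )
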