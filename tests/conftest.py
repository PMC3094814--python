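"""Shared fixtures.

Heavy simulation products (the default phantom study) are session-scoped so
every test that needs realistic reconstructions shares one computation.
Small-grid fixtures keep unit tests fast.
"""

from __future__ import annotations

import numpy as np
import pytest

import striatospect as ss


@pytest.fixture(scope="session")
def default_phantom() -> ss.PhantomVolume:
    return ss.build_phantom(ss.PhantomSpec())


@pytest.fixture(scope="session")
def default_vois(default_phantom) -> ss.VoiSet:
    return ss.define_vois(default_phantom)


@pytest.fixture(scope="session")
def small_phantom() -> ss.PhantomVolume:
    """A compact phantom on a 32x32x16 grid for fast reconstruction tests."""
    grid = ss.VoxelGrid((32, 32, 16), 5.9)
    spec = ss.PhantomSpec(
        grid=grid,
        head_semiaxes_mm=(60.0, 70.0, 40.0),
        scalp_thickness_mm=11.8,
        chambers={
            "left_caudate": ss.Ellipsoid((-14.0, 18.0, 2.0), (7.0, 13.0, 10.0)),
            "right_caudate": ss.Ellipsoid((14.0, 18.0, 2.0), (7.0, 13.0, 10.0)),
            "left_putamen": ss.Ellipsoid((-26.0, -8.0, 0.0), (8.0, 14.0, 10.0)),
            "right_putamen": ss.Ellipsoid((26.0, -8.0, 0.0), (8.0, 14.0, 10.0)),
        },
    )
    return ss.build_phantom(spec)


@pytest.fixture(scope="session")
def small_geometry() -> ss.AcquisitionGeometry:
    return ss.AcquisitionGeometry(orbit_radius_mm=120.0)


@pytest.fixture(scope="session")
def full_study() -> ss.StudyResult:
    """The default 7-acquisition study under all six correction combinations."""
    return ss.run_phantom_study(ss.StudyConfig(master_seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
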