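import numpy as np
import pytest

import bonefab as bf


@pytest.fixture(scope="session")
def ball32() -> bf.BinaryVolume:
    """Solid sphere, radius 10 voxels, in a 32^3 grid (1 mm voxels)."""
    spec = bf.PhantomSpec(kind="sphere", shape=32, voxel_size_um=1000.0, params={"radius": 10})
    return bf.make_phantom(spec)


@pytest.fixture(scope="session")
def ball64() -> bf.BinaryVolume:
    """Solid sphere, radius 20 voxels, in a 64^3 grid (1 mm voxels)."""
    spec = bf.PhantomSpec(kind="sphere", shape=64, voxel_size_um=1000.0, params={"radius": 20})
    return bf.make_phantom(spec)


@pytest.fixture(scope="session")
def plates60() -> bf.BinaryVolume:
    """Parallel plates, thickness 2 / period 10, normal along z, 60^3."""
    spec = bf.PhantomSpec(
        kind="parallel_plates", shape=60, voxel_size_um=80.0,
        params={"thickness": 2, "period": 10},
    )
    return bf.make_phantom(spec)


@pytest.fixture(scope="session")
def grf_iso64() -> bf.BinaryVolume:
    """Isotropic trabecular phantom, 64^3, target BV/TV 0.133, seed 42."""
    spec = bf.PhantomSpec(
        kind="grf_trabecular", shape=64, voxel_size_um=80.0, seed=42,
        params={"bv_tv": 0.133},
    )
    return bf.make_phantom(spec)


@pytest.fixture(scope="session")
def grf_aniso64() -> bf.BinaryVolume:
    """Stretch-2 trabecular phantom oriented along z, 64^3, seed 7."""
    spec = bf.PhantomSpec(
        kind="grf_trabecular", shape=64, voxel_size_um=80.0, seed=7,
        params={"bv_tv": 0.15, "stretch": (2.0, 1.0, 1.0)},
    )
    return bf.make_phantom(spec)


@pytest.fixture(scope="session")
def fabric_iso64(grf_iso64) -> bf.FabricResult:
    """Measured fabric of the isotropic phantom (shared across tests)."""
    return bf.measure_fabric(grf_iso64, n_directions=600, line_spacing=2.0, seed=1)


@pytest.fixture(scope="session")
def calibrated() -> bf.KabelConstants:
    return bf.KabelConstants.profile("calibrated")


@pytest.fixture(scope="session")
def printed() -> bf.KabelConstants:
    return bf.KabelConstants.profile("printed")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
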