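"""Shared fixtures: one desk-scale phantom and its derived clouds."""

from __future__ import annotations

import numpy as np
import pytest

from ripc import (
    PhantomSpec,
    RIPointCloud,
    SamplerConfig,
    generate_phantom,
    normalize_unit_sphere,
    segmented_equilibrium_sample,
    voxel_to_points,
)


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom_volume(default_spec):
    return generate_phantom(default_spec, label=0, seed=42)


@pytest.fixture(scope="session")
def phantom_cloud(phantom_volume) -> RIPointCloud:
    """Full foreground cloud of one default phantom (~1.5e5 points)."""
    return voxel_to_points(phantom_volume.volume, phantom_volume.mask)


@pytest.fixture(scope="session")
def sampled_cloud(phantom_cloud) -> RIPointCloud:
    """Segmented-equilibrium 10k cloud, unit-sphere normalized."""
    seg = segmented_equilibrium_sample(
        phantom_cloud, SamplerConfig(M=10_000, L=6, seed=3)
    )
    return normalize_unit_sphere(seg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_cloud(rng: np.random.Generator, n: int, ri_range=(1.33, 1.40)) -> RIPointCloud:
    """Helper for tests: a uniform random cloud with RI attributes."""
    return RIPointCloud(
        rng.uniform(-5, 5, size=(n, 3)),
        rng.uniform(*ri_range, size=n),
    )
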