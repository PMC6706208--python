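"""Shared fixtures: small synthetic worlds built at test time."""

import numpy as np
import pytest

from canopylight import (
    CameraPosition,
    PointCloud,
    StandSpec,
    TerrainGrid,
    generate_stand,
    generate_terrain,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_terrain():
    """Constant-elevation 3-km DTM at 100-m cells, centered on (0, 0)."""
    return generate_terrain(extent=3000, cell_size=100, slope=0, z0=0.0)


@pytest.fixture
def camera():
    return CameraPosition(0.0, 0.0, 0.0, 1.0, latitude=47.0, altitude=500.0)


@pytest.fixture
def small_stand():
    """Modest conifer stand on flat ground (deterministic)."""
    return generate_stand(
        StandSpec(extent=60.0, stem_density=300.0, slope=0.0, seed=7)
    )


def make_cloud(x, y, z, codes, first=None):
    """Hand-built point cloud helper."""
    x = np.atleast_1d(np.asarray(x, float))
    n = len(x)
    codes = np.broadcast_to(np.asarray(codes, np.uint8), n)
    first = np.ones(n, bool) if first is None else np.asarray(first, bool)
    return PointCloud(
        x, np.broadcast_to(np.asarray(y, float), n),
        np.broadcast_to(np.asarray(z, float), n),
        codes, np.where(first, 1, 2), first,
    )


@pytest.fixture
def make_points():
    return make_cloud
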