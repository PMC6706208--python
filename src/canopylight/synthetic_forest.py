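"""Synthetic forests with known ground truth.

The generators emulate the study conditions the pipeline targets: conifer
stands scanned at >= 10 returns/m^2, sloping terrain with surrounding
ridges, and understory communities whose species turn over along a light
gradient.  Stems are placed by a Poisson process; crowns are solid cones
(the conifer archetype) filled with uniformly distributed vegetation
returns; ground returns are uniform on the terrain plane.  First-return
flags are assigned to the highest return in each 0.5-m vertical column, a
simplification of pulse geometry that is adequate for count-ratio cover.

Communities follow Gaussian niches on a (0, 1] light gradient with
multiplicative lognormal abundance noise; species Landolt light values are
tied to their niche optima so weighted indicator values track true light.

Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community_analysis import CommunityMatrix
from .geodata_io import PointCloud, TerrainGrid

__all__ = [
    "StandSpec",
    "CommunitySpec",
    "generate_terrain",
    "generate_stand",
    "generate_community",
    "percent_to_braun_blanquet",
]

GROUND_CODE = 2
VEGETATION_CODE = 5  # ASPRS "high vegetation"


@dataclass
class StandSpec:
    """Conifer stand blueprint.

    extent: side length of the square domain (m), centered on (0, 0);
    stem_density in stems/ha; cone crowns from ``crown_base`` up to
    ``tree_height`` with the given base radius; densities in pts/m^3
    (crown) and pts/m^2 (ground; defaults give >= 10 returns/m^2 total in
    a stocked stand); ground plane dips along ``aspect`` (downslope azimuth,
    degrees) at ``slope`` degrees through z = z0 at the domain center.
    """

    extent: float = 100.0
    stem_density: float = 400.0
    tree_height: float = 25.0
    crown_base: float = 5.0
    crown_radius: float = 3.0
    crown_point_density: float = 0.5
    ground_point_density: float = 8.0
    slope: float = 0.0
    aspect: float = 180.0
    z0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ground_point_density <= 0 or self.crown_point_density <= 0:
            raise ValueError("point densities must be positive")
        if not 0 <= self.slope <= 60:
            raise ValueError("slope must lie in [0, 60] degrees")

    def ground_z(self, x, y) -> np.ndarray:
        """Terrain plane elevation: z0 at the center, dipping toward aspect."""
        az = np.deg2rad(self.aspect)
        downslope = np.sin(az) * np.asarray(x) + np.cos(az) * np.asarray(y)
        return self.z0 - np.tan(np.deg2rad(self.slope)) * downslope


@dataclass
class CommunitySpec:
    """Species pool on a (0, 1] light gradient.

    Each species has a Gaussian niche (optimum, breadth) on the gradient and
    a Landolt light value derived from its optimum (L = 1 + round(4 * opt)),
    so light-demanding species carry high L.  Abundances get multiplicative
    lognormal noise with the given sigma.
    """

    n_species: int = 80
    niche_breadth: float = 0.15
    max_cover: float = 60.0  # percent cover of a species at its optimum
    noise_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.niche_breadth <= 0:
            raise ValueError("niche breadth must be positive")


# ---------------------------------------------------------------------------


def generate_terrain(extent: float = 3000.0, cell_size: float = 100.0,
                     slope: float = 0.0, aspect: float = 180.0,
                     z0: float = 0.0,
                     ridges: list[tuple[float, float, float, float]] | None = None,
                     seed: int = 0) -> TerrainGrid:
    """Planar terrain with optional Gaussian ridges.

    ``ridges`` is a list of (azimuth_deg, distance_m, height_m, width_m):
    each adds a straight ridge whose crest runs perpendicular to the azimuth
    direction at the given distance from the domain center, with a Gaussian
    cross-profile of the given 1-sigma width.  The grid is centered on (0, 0).
    """
    n = int(round(extent / cell_size))
    half = n * cell_size / 2.0
    origin = (-half, -half)
    xs = origin[0] + (np.arange(n) + 0.5) * cell_size
    ys_desc = origin[1] + (n - np.arange(n) - 0.5) * cell_size
    X, Y = np.meshgrid(xs, ys_desc)
    az = np.deg2rad(aspect)
    elev = z0 - np.tan(np.deg2rad(slope)) * (np.sin(az) * X + np.cos(az) * Y)
    for r_az, r_dist, r_height, r_width in ridges or []:
        a = np.deg2rad(r_az)
        s = np.sin(a) * X + np.cos(a) * Y  # signed distance along the azimuth
        elev += r_height * np.exp(-((s - r_dist) ** 2) / (2 * r_width**2))
    return TerrainGrid(elev, origin, cell_size)


def _cone_points(rng: np.random.Generator, n: int, apex_z: float,
                 base_z: float, base_radius: float) -> np.ndarray:
    """Uniform points in a solid cone (apex up); returns (n, 3) offsets."""
    # height fraction below apex ~ u^(1/3) so volume slices are uniform
    u = rng.random(n) ** (1.0 / 3.0)
    z = apex_z - u * (apex_z - base_z)
    r = base_radius * u * np.sqrt(rng.random(n))
    ang = rng.random(n) * 2 * np.pi
    return np.column_stack([r * np.cos(ang), r * np.sin(ang), z])


def generate_stand(spec: StandSpec) -> PointCloud:
    """Simulate a classified ALS point cloud of a conifer stand."""
    rng = np.random.default_rng(spec.seed)
    half = spec.extent / 2.0
    area = spec.extent**2

    n_ground = rng.poisson(spec.ground_point_density * area)
    gx = rng.uniform(-half, half, n_ground)
    gy = rng.uniform(-half, half, n_ground)
    gz = spec.ground_z(gx, gy)
    # guarantee triangulable ground: pin the four domain corners
    cx = np.array([-half, -half, half, half])
    cy = np.array([-half, half, -half, half])
    gx, gy = np.concatenate([gx, cx]), np.concatenate([gy, cy])
    gz = np.concatenate([gz, spec.ground_z(cx, cy)])

    n_stems = rng.poisson(spec.stem_density * area / 1e4)
    vx = np.empty(0)
    vy = np.empty(0)
    vz = np.empty(0)
    if n_stems:
        sx = rng.uniform(-half, half, n_stems)
        sy = rng.uniform(-half, half, n_stems)
        crown_h = spec.tree_height - spec.crown_base
        volume = np.pi * spec.crown_radius**2 * crown_h / 3.0
        counts = rng.poisson(spec.crown_point_density * volume, n_stems)
        parts = []
        for i in range(n_stems):
            if counts[i] == 0:
                continue
            off = _cone_points(
                rng, counts[i], spec.tree_height, spec.crown_base, spec.crown_radius
            )
            base = spec.ground_z(sx[i], sy[i])
            parts.append(
                np.column_stack(
                    [sx[i] + off[:, 0], sy[i] + off[:, 1], base + off[:, 2]]
                )
            )
        if parts:
            veg = np.concatenate(parts)
            vx, vy, vz = veg[:, 0], veg[:, 1], veg[:, 2]

    x = np.concatenate([gx, vx])
    y = np.concatenate([gy, vy])
    z = np.concatenate([gz, vz])
    codes = np.concatenate(
        [np.full(len(gx), GROUND_CODE, np.uint8),
         np.full(len(vx), VEGETATION_CODE, np.uint8)]
    )

    # first-return flag: highest return per 0.5-m horizontal column
    col = np.floor((x + half) / 0.5).astype(np.int64)
    row = np.floor((y + half) / 0.5).astype(np.int64)
    col -= col.min()
    row -= row.min()
    key = col * (row.max() + 2) + row
    order = np.lexsort((-z, key))
    first_sorted = np.ones(len(x), dtype=bool)
    first_sorted[1:] = key[order][1:] != key[order][:-1]
    is_first = np.empty(len(x), dtype=bool)
    is_first[order] = first_sorted
    return_number = np.where(is_first, 1, 2).astype(np.int32)

    return PointCloud(x, y, z, codes, return_number, is_first)


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

_BB_EDGES = [
    (0.2, "r"), (1.0, "+"), (5.0, "1"), (25.0, "2"),
    (50.0, "3"), (75.0, "4"), (100.0 + 1e-9, "5"),
]


def percent_to_braun_blanquet(percent: float) -> str | None:
    """Inverse of the midpoint conversion by cover interval; None if absent."""
    if percent <= 0:
        return None
    for upper, label in _BB_EDGES:
        if percent <= upper:
            return label
    return "5"


def generate_community(spec: CommunitySpec, plot_light,
                       plot_ids=None) -> CommunityMatrix:
    """Simulate a plot x species community along a known light gradient.

    ``plot_light`` gives each plot's true light availability in (0, 1].
    Raw Gaussian-niche abundances with lognormal noise are snapped onto the
    Braun-Blanquet scale and back to midpoints, mirroring the survey process.
    """
    light = np.asarray(plot_light, dtype=float)
    if np.any(light <= 0) or np.any(light > 1):
        raise ValueError("plot light values must lie in (0, 1]")
    rng = np.random.default_rng(spec.seed)
    if plot_ids is None:
        plot_ids = [f"plot{i:03d}" for i in range(len(light))]
    optima = rng.uniform(0.0, 1.0, spec.n_species)
    landolt = np.clip(np.rint(1.0 + 4.0 * optima), 1, 5).astype(int)
    species = [f"sp{i:03d}" for i in range(spec.n_species)]

    response = np.exp(
        -((light[:, None] - optima[None, :]) ** 2) / (2 * spec.niche_breadth**2)
    )
    noise = np.exp(rng.normal(0.0, spec.noise_sigma, response.shape))
    raw = spec.max_cover * response * noise
    raw[raw < 0.05] = 0.0  # detection limit of the releve

    from .community_analysis import braun_blanquet_to_cover

    snapped = np.zeros_like(raw)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            label = percent_to_braun_blanquet(min(raw[i, j], 100.0))
            if label is not None:
                snapped[i, j] = braun_blanquet_to_cover(label)

    abundance = pd.DataFrame(snapped, index=plot_ids, columns=species)
    return CommunityMatrix(abundance, pd.Series(landolt, index=species, dtype=float))
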