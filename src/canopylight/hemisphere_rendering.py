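"""Synthetic hemispherical images from classified lidar point clouds.

Each return within a 100-m radius of the camera is transformed into
camera-centered spherical coordinates and stamped onto a square, equiangular
(polar) fisheye raster as a filled black disk whose diameter shrinks linearly
with distance (7 px at the camera, 0.5 px at the radius cutoff), so that
near canopy elements occlude more sky, as overlapping leaves would in a real
photograph.  Terrain enters twice: a macro-terrain horizon line computed from
a coarse DTM masks all directions below the local horizon, and ground
returns above the camera position are stamped as micro-terrain.  Returns are
used in true (non-normalized) coordinates so canopy on the uphill slope
plots closer to the zenith.

Image orientation is that of an upward-looking fisheye: North up, East left,
azimuth increasing clockwise in the world (0 = North, 90 = East).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geodata_io import PointCloud, TerrainGrid

__all__ = [
    "CameraPosition",
    "SphericalPoints",
    "HorizonProfile",
    "HemiImage",
    "RenderConfig",
    "to_spherical",
    "marker_size",
    "project_equiangular",
    "unproject_equiangular",
    "horizon_line",
    "horizon_mask",
    "render_hemisphere",
]


@dataclass
class CameraPosition:
    """Virtual camera: horizontal position, ground elevation, eye height."""

    x: float
    y: float
    z_ground: float
    height_above_ground: float = 1.0
    latitude: float = 47.0
    altitude: float = 500.0

    def __post_init__(self) -> None:
        if self.height_above_ground < 0:
            raise ValueError("camera height_above_ground must be >= 0")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("latitude out of range")

    @property
    def z_eye(self) -> float:
        return self.z_ground + self.height_above_ground


@dataclass
class SphericalPoints:
    """Camera-centered spherical coordinates of a set of returns.

    r: distance (m); theta: elevation above the horizontal (rad,
    [-pi/2, pi/2]); phi: azimuth (rad, [0, 2pi), 0 = North, clockwise).
    """

    r: np.ndarray
    theta: np.ndarray
    phi: np.ndarray

    def __len__(self) -> int:
        return len(self.r)


@dataclass
class HorizonProfile:
    """Terrain horizon elevation (radians, >= 0) on a regular azimuth grid."""

    azimuth_bins: np.ndarray
    horizon_elevation: np.ndarray

    def __post_init__(self) -> None:
        if len(self.azimuth_bins) < 72:
            raise ValueError("horizon profile needs >= 72 azimuth bins")
        if np.any(self.horizon_elevation < 0) or np.any(
            self.horizon_elevation >= np.pi / 2
        ):
            raise ValueError("horizon elevations must lie in [0, pi/2)")

    def elevation_at(self, phi) -> np.ndarray:
        """Horizon elevation at azimuth(s) phi, nearest-bin lookup."""
        phi = np.asarray(phi, dtype=float) % (2 * np.pi)
        step = 2 * np.pi / len(self.azimuth_bins)
        idx = np.round(phi / step).astype(int) % len(self.azimuth_bins)
        return self.horizon_elevation[idx]


@dataclass
class RenderConfig:
    max_radius: float = 100.0       # m; point cutoff around the camera
    marker_near_px: float = 7.0     # disk diameter at r = 0
    marker_far_px: float = 0.5      # disk diameter at r = max_radius
    image_side_px: int = 1200
    marker_reference_side: int = 1200  # side at which marker anchors are defined
    horizon_bins: int = 360
    flip_east_west: bool = False    # map-oriented output instead of upward view

    def __post_init__(self) -> None:
        if self.max_radius <= 0:
            raise ValueError("max_radius must be positive")
        if not self.marker_near_px >= self.marker_far_px > 0:
            raise ValueError("need marker_near_px >= marker_far_px > 0")
        if self.image_side_px < 16:
            raise ValueError("image_side_px too small")


@dataclass
class HemiImage:
    """Square equiangular occupancy raster with three boolean channels.

    A pixel is "obscured" iff any of canopy, macro_terrain or micro_terrain
    is set.  Pixels outside the circumscribed circle are invalid.
    """

    side: int
    canopy: np.ndarray
    macro_terrain: np.ndarray
    micro_terrain: np.ndarray
    camera: CameraPosition | None = None
    config: RenderConfig | None = None
    _valid: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("canopy", "macro_terrain", "micro_terrain"):
            ch = np.asarray(getattr(self, name), dtype=bool)
            if ch.shape != (self.side, self.side):
                raise ValueError(f"channel {name} must be ({self.side}, {self.side})")
            setattr(self, name, ch)
        if self._valid is None:
            self._valid = _valid_mask(self.side)

    @classmethod
    def empty(cls, side: int, camera: CameraPosition | None = None,
              config: RenderConfig | None = None) -> "HemiImage":
        z = np.zeros((side, side), dtype=bool)
        return cls(side, z.copy(), z.copy(), z.copy(), camera, config)

    @property
    def valid(self) -> np.ndarray:
        return self._valid

    @property
    def obscured(self) -> np.ndarray:
        return (self.canopy | self.macro_terrain | self.micro_terrain) & self._valid

    def zenith_azimuth(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel zenith angle and azimuth (radians) at pixel centers."""
        return _pixel_angles(self.side)

    def to_png(self, path) -> None:
        """Export a composite image: sky white, canopy black, macro-terrain
        red, micro-terrain green (later channels never overdraw canopy)."""
        from PIL import Image

        rgb = np.full((self.side, self.side, 3), 255, dtype=np.uint8)
        rgb[self.macro_terrain] = (200, 30, 30)
        rgb[self.micro_terrain & ~self.macro_terrain] = (30, 160, 30)
        rgb[self.canopy] = (0, 0, 0)
        rgb[~self._valid] = (220, 220, 220)
        Image.fromarray(rgb).save(Path(path))

    def save_channels(self, path) -> None:
        """Export the raw channels (.npz) plus a JSON metadata sidecar."""
        path = Path(path)
        np.savez_compressed(
            path,
            canopy=self.canopy,
            macro_terrain=self.macro_terrain,
            micro_terrain=self.micro_terrain,
        )
        meta = {"side": self.side}
        if self.camera is not None:
            meta["camera"] = vars(self.camera)
        if self.config is not None:
            meta["config"] = vars(self.config)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def to_spherical(cloud: PointCloud, camera: CameraPosition,
                 max_radius: float = 100.0) -> SphericalPoints:
    """Transform returns into camera-centered spherical coordinates.

    Points at distance 0 or beyond ``max_radius`` are dropped.  The azimuth of
    a point straight overhead (or underfoot) is 0 by convention.
    """
    if len(cloud) == 0:
        raise ValueError("empty point cloud")
    de = cloud.x - camera.x
    dn = cloud.y - camera.y
    dz = cloud.z - camera.z_eye
    r = np.sqrt(de * de + dn * dn + dz * dz)
    keep = (r > 0) & (r <= max_radius)
    de, dn, dz, r = de[keep], dn[keep], dz[keep], r[keep]
    theta = np.arcsin(np.clip(dz / r, -1.0, 1.0))
    phi = np.arctan2(de, dn) % (2 * np.pi)
    phi[np.hypot(de, dn) == 0] = 0.0
    return SphericalPoints(r, theta, phi)


def marker_size(r, cfg: RenderConfig) -> np.ndarray:
    """Marker diameter (px), linear in distance between the near and far anchors."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or np.any(r > cfg.max_radius):
        raise ValueError("marker distance out of (0, max_radius]")
    return cfg.marker_near_px + (cfg.marker_far_px - cfg.marker_near_px) * (
        r / cfg.max_radius
    )


def project_equiangular(theta, phi, side: int,
                        flip_east_west: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Equiangular fisheye projection to continuous pixel coordinates.

    Radial pixel distance is proportional to zenith angle: the zenith maps to
    the image center, the horizon (theta = 0) to the rim.  Returns (col, row);
    pixel centers sit at integer coordinates.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    radius = side / 2.0
    c = (side - 1) / 2.0
    rho = radius * (np.pi / 2 - theta) / (np.pi / 2)
    sgn = 1.0 if flip_east_west else -1.0
    col = c + sgn * rho * np.sin(phi)
    row = c - rho * np.cos(phi)
    return col, row


def unproject_equiangular(col, row, side: int,
                          flip_east_west: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`project_equiangular` (theta, phi from pixel coords)."""
    col = np.asarray(col, dtype=float)
    row = np.asarray(row, dtype=float)
    radius = side / 2.0
    c = (side - 1) / 2.0
    sgn = 1.0 if flip_east_west else -1.0
    dx = sgn * (col - c)
    dy = c - row
    rho = np.hypot(dx, dy)
    theta = np.pi / 2 * (1 - rho / radius)
    phi = np.arctan2(dx, dy) % (2 * np.pi)
    return theta, phi


def _pixel_angles(side: int) -> tuple[np.ndarray, np.ndarray]:
    c = (side - 1) / 2.0
    radius = side / 2.0
    rows, cols = np.mgrid[0:side, 0:side]
    dx = -(cols - c)
    dy = c - rows
    rho = np.hypot(dx, dy)
    zenith = np.pi / 2 * rho / radius
    phi = np.arctan2(dx, dy) % (2 * np.pi)
    return zenith, phi


def _valid_mask(side: int) -> np.ndarray:
    zenith, _ = _pixel_angles(side)
    return zenith <= np.pi / 2


# ---------------------------------------------------------------------------
# terrain horizon
# ---------------------------------------------------------------------------


def horizon_line(grid: TerrainGrid, camera: CameraPosition,
                 bins: int = 360) -> HorizonProfile:
    """Macro-terrain horizon from a coarse DTM.

    For each azimuth bin center a ray is marched from the camera to the grid
    edge in steps of half a cell; the horizon elevation is the maximum
    (floored at zero) of atan2(cell elevation - eye elevation, distance).
    """
    if not grid.contains(camera.x, camera.y):
        raise ValueError("camera lies outside the terrain grid")
    az = (np.arange(bins) + 0.5) * (2 * np.pi / bins)
    x0, y0, x1, y1 = grid.bounds
    max_range = float(np.hypot(x1 - x0, y1 - y0))
    step = grid.cell_size / 2.0
    dist = np.arange(step, max_range + step, step)
    # sample all (bin, step) cells at once
    sx = camera.x + np.sin(az)[:, None] * dist[None, :]
    sy = camera.y + np.cos(az)[:, None] * dist[None, :]
    elev = grid.sample(sx, sy)
    with np.errstate(invalid="ignore"):
        ang = np.arctan2(elev - camera.z_eye, dist[None, :])
    ang = np.where(np.isnan(ang), -np.inf, ang)
    horizon = np.maximum(ang.max(axis=1), 0.0)
    horizon = np.minimum(horizon, np.pi / 2 - 1e-9)
    return HorizonProfile(az, horizon)


def horizon_mask(profile: HorizonProfile, side: int) -> np.ndarray:
    """Boolean raster: pixels whose direction lies below the horizon line."""
    zenith, phi = _pixel_angles(side)
    elevation = np.pi / 2 - zenith
    return (elevation < profile.elevation_at(phi)) & (zenith <= np.pi / 2)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _stamp_disks(mask: np.ndarray, col: np.ndarray, row: np.ndarray,
                 diam: np.ndarray) -> None:
    """Stamp filled disks (diameter in px) into a boolean raster, in place.

    A pixel is set when its center lies within diam/2 of the disk center.
    Sub-pixel disks (< 1 px) deterministically set the nearest pixel.
    """
    side = mask.shape[0]
    if len(col) == 0:
        return
    small = diam < 1.0
    if small.any():
        ci = np.round(col[small]).astype(int)
        ri = np.round(row[small]).astype(int)
        ok = (ci >= 0) & (ci < side) & (ri >= 0) & (ri < side)
        mask[ri[ok], ci[ok]] = True
    big = ~small
    if not big.any():
        return
    col, row, diam = col[big], row[big], diam[big]
    # group by quantized radius so each group shares one offset stencil
    q = np.round(diam * 4).astype(int)  # 0.25-px diameter buckets
    for qv in np.unique(q):
        sel = q == qv
        c, rw, d = col[sel], row[sel], diam[sel]
        rad = d.max() / 2.0
        hw = int(np.ceil(rad))
        offs = np.mgrid[-hw : hw + 1, -hw : hw + 1].reshape(2, -1).T  # (k, 2) row,col
        base_r = np.round(rw).astype(int)
        base_c = np.round(c).astype(int)
        pr = base_r[:, None] + offs[None, :, 0]
        pc = base_c[:, None] + offs[None, :, 1]
        d2 = (pr - rw[:, None]) ** 2 + (pc - c[:, None]) ** 2
        hit = d2 <= (d[:, None] / 2.0) ** 2
        hit &= (pr >= 0) & (pr < side) & (pc >= 0) & (pc < side)
        mask[pr[hit], pc[hit]] = True


def render_hemisphere(cloud: PointCloud, grid: TerrainGrid | None,
                      camera: CameraPosition,
                      cfg: RenderConfig | None = None) -> HemiImage:
    """Render the synthetic hemispherical image at a camera position.

    Channels: ``canopy`` — vegetation returns at or above the camera's
    horizontal plane, stamped as distance-scaled disks; ``macro_terrain`` —
    pixels below the DTM horizon line (skipped if ``grid`` is None);
    ``micro_terrain`` — ground returns above the camera, same marker rule.
    """
    cfg = cfg or RenderConfig()
    side = cfg.image_side_px
    img = HemiImage.empty(side, camera, cfg)

    if grid is not None:
        profile = horizon_line(grid, camera, cfg.horizon_bins)
        img.macro_terrain |= horizon_mask(profile, side)

    if len(cloud):
        for class_mask, channel, lowest in (
            (cloud.is_vegetation, img.canopy, 0.0),
            (cloud.is_ground, img.micro_terrain, 1e-12),
        ):
            sub = cloud.subset(class_mask)
            if len(sub) == 0:
                continue
            sph = to_spherical(sub, camera, cfg.max_radius)
            keep = sph.theta >= lowest
            if not keep.any():
                continue
            r, theta, phi = sph.r[keep], sph.theta[keep], sph.phi[keep]
            col, row = project_equiangular(theta, phi, side, cfg.flip_east_west)
            # marker anchors are defined at the reference side; scale so the
            # angular footprint is resolution-independent
            scale = side / cfg.marker_reference_side
            _stamp_disks(channel, col, row, marker_size(r, cfg) * scale)

    img.canopy &= img.valid
    img.micro_terrain &= img.valid
    img.macro_terrain &= img.valid
    return img
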