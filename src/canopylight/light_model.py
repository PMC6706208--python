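"""Light indices from a synthetic hemispherical image.

Three point-based metrics are derived from the occupancy image:

* **canopy closure** — the solid-angle proportion of the sky vault obscured
  by canopy or terrain;
* **diffuse light index (DLI)** — diffuse irradiance on a horizontal sensor
  under a Standard Overcast Sky (SOC, Steven & Unsworth gradation
  ``L(z)/L_zenith = (1 + b cos z)/(1 + b)``, b = 1) transmitted through the
  unobscured sky, relative to the same sky with no obstruction;
* **direct (beam) light index (BLI)** — growing-season (May–September)
  beam irradiance on a horizontal sensor, tracking the sun disk through the
  image mask, relative to open flat ground at the same latitude and
  altitude.  Beam transmission through the atmosphere is
  ``tau ** m`` with tau = 0.40 at sea level and m the Kasten–Young relative
  air mass, pressure-corrected for altitude (barometric scale height
  8,434 m); the extraterrestrial constant cancels in the ratio.

Because the SOC angular shape does not change over time, the seasonal
diffuse ratio collapses to a single spatial integral over the image.  Solar
positions use true solar time (declination + hour angle geometry), so no
longitude or equation-of-time input is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hemisphere_rendering import CameraPosition, HemiImage, project_equiangular

__all__ = [
    "RadiationConfig",
    "LightIndices",
    "solar_position",
    "solar_declination",
    "air_mass",
    "soc_radiance",
    "canopy_closure",
    "diffuse_index",
    "direct_index",
    "compute_indices",
    "uniform_horizon_image",
]


@dataclass
class RadiationConfig:
    b_soc: float = 1.0                  # SOC gradation parameter
    tau_direct: float = 0.40            # beam transmission at sea level
    frac_diffuse: float = 0.20          # diffuse fraction of extraterrestrial
    season: tuple[int, int] = (121, 273)  # day-of-year window, May 1 - Sep 30
    time_step: float = 10.0             # minutes
    sun_disk_radius: float = 0.266      # degrees
    pressure_scale_height: float = 8434.0  # m

    def __post_init__(self) -> None:
        if not 0 < self.tau_direct < 1:
            raise ValueError("tau_direct must be in (0, 1)")
        if not 0 <= self.frac_diffuse < 1:
            raise ValueError("frac_diffuse must be in [0, 1)")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if self.b_soc < 0:
            raise ValueError("b_soc must be >= 0")


@dataclass
class LightIndices:
    diffuse_index: float
    direct_index: float
    canopy_closure: float

    def __post_init__(self) -> None:
        for name in ("diffuse_index", "direct_index", "canopy_closure"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"{name} out of [0, 1]: {v}")


# ---------------------------------------------------------------------------
# solar geometry
# ---------------------------------------------------------------------------


def solar_declination(day_of_year) -> np.ndarray:
    """Solar declination (radians) from the Spencer Fourier series."""
    g = 2 * np.pi * (np.asarray(day_of_year, dtype=float) - 1) / 365.0
    return (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.001480 * np.sin(3 * g)
    )


def solar_position(latitude: float, day_of_year, solar_time) -> tuple[np.ndarray, np.ndarray]:
    """Solar elevation and azimuth (degrees) in true solar time.

    Azimuth is 0 at North, increasing clockwise (90 = East, 180 = South).
    Vectorized over ``day_of_year`` and ``solar_time``.
    """
    day = np.asarray(day_of_year, dtype=float)
    t = np.asarray(solar_time, dtype=float)
    if np.any(day < 1) or np.any(day > 366):
        raise ValueError("day_of_year out of [1, 366]")
    if np.any(t < 0) or np.any(t > 24):
        raise ValueError("solar_time out of [0, 24]")
    lat = np.deg2rad(latitude)
    dec = solar_declination(day)
    hour_angle = np.deg2rad(15.0 * (t - 12.0))
    sin_e = np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.cos(hour_angle)
    elevation = np.arcsin(np.clip(sin_e, -1.0, 1.0))
    # azimuth measured from South, positive toward West, then mapped to N=0 CW
    az_s = np.arctan2(
        np.sin(hour_angle),
        np.cos(hour_angle) * np.sin(lat) - np.tan(dec) * np.cos(lat),
    )
    azimuth = (np.rad2deg(az_s) + 180.0) % 360.0
    return np.rad2deg(elevation), azimuth


def air_mass(elevation: float, altitude: float,
             cfg: RadiationConfig | None = None) -> np.ndarray:
    """Relative optical air mass (Kasten–Young) with barometric altitude
    correction ``p/p0 = exp(-altitude / scale_height)``."""
    cfg = cfg or RadiationConfig()
    e = np.asarray(elevation, dtype=float)
    if np.any(e <= 0):
        raise ValueError("air mass requires solar elevation > 0")
    pressure_ratio = np.exp(-altitude / cfg.pressure_scale_height)
    denom = np.sin(np.deg2rad(e)) + 0.50572 * (e + 6.07995) ** -1.6364
    return pressure_ratio / denom


def soc_radiance(zenith, b: float = 1.0) -> np.ndarray:
    """Standard Overcast Sky relative radiance, normalized at the zenith."""
    zenith = np.asarray(zenith, dtype=float)
    return (1.0 + b * np.cos(zenith)) / (1.0 + b)


# ---------------------------------------------------------------------------
# image integrals
# ---------------------------------------------------------------------------


def _pixel_weights(img: HemiImage) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel solid angle (relative) and zenith angle for valid pixels.

    For the equiangular projection the Jacobian gives a solid angle per unit
    image area proportional to sin(z)/z; the z -> 0 limit (the pixel
    containing the zenith) is 1, the exact value of the shrinking cap.
    """
    zenith, _ = img.zenith_azimuth()
    w = np.where(zenith > 0, np.sin(zenith) / np.where(zenith > 0, zenith, 1.0), 1.0)
    w = np.where(img.valid, w, 0.0)
    return w, zenith


def canopy_closure(img: HemiImage) -> float:
    """Solid-angle proportion of the hemisphere obscured by any channel."""
    w, _ = _pixel_weights(img)
    total = w.sum()
    if total == 0:
        raise ValueError("image has no valid pixels")
    return float(w[img.obscured].sum() / total)


def diffuse_index(img: HemiImage, cfg: RadiationConfig | None = None) -> float:
    """SOC-weighted horizontal diffuse irradiance through the unobscured sky,
    relative to a fully open sky (time-invariant under the SOC shape)."""
    cfg = cfg or RadiationConfig()
    w, zenith = _pixel_weights(img)
    flux = soc_radiance(zenith, cfg.b_soc) * np.cos(zenith) * w
    denom = flux[img.valid].sum()
    num = flux[img.valid & ~img.obscured].sum()
    return float(num / denom)


def _season_samples(latitude: float, cfg: RadiationConfig):
    """All growing-season sun positions with elevation > 0 and their
    horizontal beam weight w = tau^m * sin(e) (altitude correction applied
    by the caller through the air-mass term)."""
    d0, d1 = cfg.season
    days = np.arange(d0, d1 + 1)
    times = np.arange(cfg.time_step / 2.0, 24 * 60, cfg.time_step) / 60.0
    dd, tt = np.meshgrid(days, times, indexing="ij")
    elev, azim = solar_position(latitude, dd.ravel(), tt.ravel())
    up = elev > 0
    return elev[up], azim[up]


def direct_index(img: HemiImage, camera: CameraPosition,
                 cfg: RadiationConfig | None = None) -> float:
    """Season-integrated beam irradiance through the mask relative to open
    flat ground: sum_t w(t) v(t) / sum_t w(t), where v(t) is the visible
    fraction of the sun disk (supersampled on a fixed 5x5-in-disk pattern)."""
    cfg = cfg or RadiationConfig()
    if camera is None or camera.latitude is None:
        raise ValueError("camera latitude required for the direct index")
    elev, azim = _season_samples(camera.latitude, cfg)
    if len(elev) == 0:
        return 0.0
    m = air_mass(elev, camera.altitude, cfg)
    w = cfg.tau_direct ** m * np.sin(np.deg2rad(elev))

    # fixed supersampling pattern: 5x5 grid clipped to the unit disk (13 pts)
    g = np.linspace(-1.0, 1.0, 5)
    ox, oy = np.meshgrid(g, g)
    inside = ox**2 + oy**2 <= 1.0 + 1e-12
    ox, oy = ox[inside], oy[inside]
    s = np.deg2rad(cfg.sun_disk_radius)
    theta = np.deg2rad(elev)[:, None] + s * oy[None, :]
    cos_t = np.maximum(np.cos(np.deg2rad(elev)), 1e-6)
    phi = np.deg2rad(azim)[:, None] + s * ox[None, :] / cos_t[:, None]

    flip = bool(img.config.flip_east_west) if img.config is not None else False
    col, row = project_equiangular(theta, phi, img.side, flip)
    ci = np.round(col).astype(int)
    ri = np.round(row).astype(int)
    ok = (theta >= 0) & (ci >= 0) & (ci < img.side) & (ri >= 0) & (ri < img.side)
    visible = np.zeros(theta.shape, dtype=bool)
    open_sky = ~img.obscured & img.valid
    visible[ok] = open_sky[ri[ok], ci[ok]]
    v = visible.mean(axis=1)
    return float((w * v).sum() / w.sum())


def compute_indices(img: HemiImage, camera: CameraPosition,
                    cfg: RadiationConfig | None = None) -> LightIndices:
    """Bundle the three image metrics for one camera position."""
    cfg = cfg or RadiationConfig()
    return LightIndices(
        diffuse_index=diffuse_index(img, cfg),
        direct_index=direct_index(img, camera, cfg),
        canopy_closure=canopy_closure(img),
    )


# ---------------------------------------------------------------------------
# analytic helpers
# ---------------------------------------------------------------------------


def uniform_horizon_image(horizon_elevation_deg: float, side: int = 1200,
                          camera: CameraPosition | None = None) -> HemiImage:
    """Image whose macro-terrain channel obscures all directions below a
    constant horizon elevation — the geometry with closed-form indices:
    closure = cos(theta_h) and DLI = 1 - (3 cos^2 + 2 cos^3)/5 with
    theta_h = 90 deg - horizon elevation (the visible cap half-angle)."""
    img = HemiImage.empty(side, camera)
    zenith, _ = img.zenith_azimuth()
    elevation = np.pi / 2 - zenith
    img.macro_terrain |= (elevation < np.deg2rad(horizon_elevation_deg)) & img.valid
    return img
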