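"""Point-cloud and terrain-raster I/O, plus height normalization.

Point clouds are exchanged as LAS files (1.2–1.4, point record formats 0–3
and 6–8); only the fields the light pipeline needs are read: coordinates,
classification, return number.  Classification follows the ASPRS convention:
code 2 is ground, codes 3/4/5 are vegetation, everything else is retained
but ignored by the downstream metrics.  Terrain models are single-band
GeoTIFFs with a ModelPixelScale/ModelTiepoint geotransform.

Heights above ground are obtained by linear interpolation over a Delaunay
triangulation of the ground returns, with a nearest-ground fallback outside
the triangulation hull.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError

GROUND_CLASS = 2
VEGETATION_CLASSES = (3, 4, 5)

__all__ = [
    "PointCloud",
    "NormalizedCloud",
    "TerrainGrid",
    "read_point_cloud",
    "write_point_cloud",
    "read_terrain",
    "write_terrain",
    "normalize_heights",
]


class GeodataError(ValueError):
    """Raised for malformed or unsupported geodata inputs."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PointCloud:
    """Classified lidar returns in a projected, metric CRS.

    Attributes
    ----------
    x, y, z : float arrays, meters.
    class_code : uint8 ASPRS classification codes.
    return_number : positive integer per return.
    is_first_return : boolean flag per return.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    class_code: np.ndarray
    return_number: np.ndarray
    is_first_return: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.class_code = np.asarray(self.class_code, dtype=np.uint8)
        self.return_number = np.asarray(self.return_number, dtype=np.int32)
        self.is_first_return = np.asarray(self.is_first_return, dtype=bool)
        n = len(self.x)
        for name in ("y", "z", "class_code", "return_number", "is_first_return"):
            if len(getattr(self, name)) != n:
                raise GeodataError(f"field {name!r} length mismatch")
        if n and not (
            np.isfinite(self.x).all()
            and np.isfinite(self.y).all()
            and np.isfinite(self.z).all()
        ):
            raise GeodataError("point coordinates must be finite")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def is_ground(self) -> np.ndarray:
        return self.class_code == GROUND_CLASS

    @property
    def is_vegetation(self) -> np.ndarray:
        return np.isin(self.class_code, VEGETATION_CLASSES)

    @property
    def class_label(self) -> np.ndarray:
        """Per-return label in {'ground', 'vegetation', 'other'}."""
        labels = np.full(len(self), "other", dtype="<U10")
        labels[self.is_ground] = "ground"
        labels[self.is_vegetation] = "vegetation"
        return labels

    def subset(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.x[mask],
            self.y[mask],
            self.z[mask],
            self.class_code[mask],
            self.return_number[mask],
            self.is_first_return[mask],
        )


@dataclass
class NormalizedCloud(PointCloud):
    """PointCloud with per-return height above the interpolated ground surface."""

    height_above_ground: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        self.height_above_ground = np.asarray(self.height_above_ground, dtype=float)
        if len(self.height_above_ground) != len(self):
            raise GeodataError("height_above_ground length mismatch")
        if len(self) and not np.isfinite(self.height_above_ground).all():
            raise GeodataError("heights must be finite")


@dataclass
class TerrainGrid:
    """Single-band elevation raster.

    ``elevation`` is stored in raster order (row 0 = northernmost row);
    ``origin`` is the (x, y) of the grid's lower-left corner; nodata cells
    hold NaN.
    """

    elevation: np.ndarray
    origin: tuple[float, float]
    cell_size: float

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.ndim != 2:
            raise GeodataError("elevation must be 2-D")
        if not self.cell_size > 0:
            raise GeodataError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def x_centers(self) -> np.ndarray:
        nx = self.shape[1]
        return self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        """Cell-center y coordinates for each raster row (row 0 first, i.e. descending)."""
        ny = self.shape[0]
        return self.origin[1] + (ny - np.arange(ny) - 0.5) * self.cell_size

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        ny, nx = self.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + nx * self.cell_size, y0 + ny * self.cell_size)

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.bounds
        return (x0 <= x <= x1) and (y0 <= y <= y1)

    def sample(self, x, y) -> np.ndarray:
        """Nearest-cell elevation at (x, y); NaN outside the grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ny, nx = self.shape
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = ny - 1 - np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < nx) & (row >= 0) & (row < ny)
        out = np.full(x.shape, np.nan)
        out[inside] = self.elevation[row[inside], col[inside]]
        return out

    def sample_bilinear(self, x: float, y: float) -> float:
        """Bilinearly interpolated elevation at a single point."""
        fx = (x - self.origin[0]) / self.cell_size - 0.5
        ny, nx = self.shape
        fy = (self.bounds[3] - y) / self.cell_size - 0.5
        j0 = int(np.clip(np.floor(fx), 0, nx - 2))
        i0 = int(np.clip(np.floor(fy), 0, ny - 2))
        tx = float(np.clip(fx - j0, 0.0, 1.0))
        ty = float(np.clip(fy - i0, 0.0, 1.0))
        z = self.elevation
        return float(
            z[i0, j0] * (1 - tx) * (1 - ty)
            + z[i0, j0 + 1] * tx * (1 - ty)
            + z[i0 + 1, j0] * (1 - tx) * ty
            + z[i0 + 1, j0 + 1] * tx * ty
        )


# ---------------------------------------------------------------------------
# LAS reading and writing
#
# Only the point fields needed downstream are handled; formats 0-3 share a
# 20-byte leading layout, formats 6-8 a 30-byte one.
# ---------------------------------------------------------------------------

_HEADER_FMT = "<4sHH16sBB32s32sHHHIIBHI5I12d"
_HEADER_SIZE = struct.calcsize(_HEADER_FMT)  # 227 bytes (LAS 1.0-1.3 core)

_LEGACY_POINT_DTYPE = np.dtype(
    [
        ("X", "<i4"),
        ("Y", "<i4"),
        ("Z", "<i4"),
        ("intensity", "<u2"),
        ("flags", "u1"),
        ("classification", "u1"),
        ("scan_angle", "i1"),
        ("user_data", "u1"),
        ("point_source", "<u2"),
    ]
)

_MODERN_POINT_DTYPE = np.dtype(
    [
        ("X", "<i4"),
        ("Y", "<i4"),
        ("Z", "<i4"),
        ("intensity", "<u2"),
        ("returns", "u1"),
        ("class_flags", "u1"),
        ("classification", "u1"),
        ("user_data", "u1"),
        ("scan_angle", "<i2"),
        ("point_source", "<u2"),
    ]
)


def _check_not_geographic(raw: bytes, n_vlr: int, header_size: int, point_offset: int) -> None:
    """Refuse files whose GeoKeyDirectory declares a geographic (degree) CRS."""
    pos = header_size
    for _ in range(n_vlr):
        if pos + 54 > point_offset:
            break
        _, user_id, record_id, length, _ = struct.unpack(
            "<H16sHH32s", raw[pos : pos + 54]
        )
        data = raw[pos + 54 : pos + 54 + length]
        if user_id.rstrip(b"\x00") == b"LASF_Projection" and record_id == 34735:
            keys = np.frombuffer(data, dtype="<u2")
            for k in range(4, len(keys) - 3, 4):
                key_id, loc, _, value = keys[k : k + 4]
                if key_id == 1024 and loc == 0 and value == 2:
                    raise GeodataError(
                        "point cloud uses a geographic (degree) CRS; "
                        "metric projected coordinates are required"
                    )
        pos += 54 + length
    return None


def read_point_cloud(path, bounds: tuple[float, float, float, float] | None = None) -> PointCloud:
    """Read a LAS file into a :class:`PointCloud`.

    Parameters
    ----------
    path : file path to a LAS 1.2-1.4 file (point formats 0-3 or 6-8).
    bounds : optional (xmin, ymin, xmax, ymax) rectangle; only returns whose
        (x, y) fall inside (inclusive) are kept.
    """
    path = Path(path)
    if not path.exists():
        raise GeodataError(f"no such file: {path}")
    raw = path.read_bytes()
    if len(raw) < _HEADER_SIZE or raw[:4] != b"LASF":
        raise GeodataError(f"not a LAS file: {path}")
    fields = struct.unpack(_HEADER_FMT, raw[:_HEADER_SIZE])
    (ver_major, ver_minor) = fields[4], fields[5]
    header_size = fields[10]
    point_offset = fields[11]
    n_vlr = fields[12]
    point_format = fields[13] & 0x3F
    record_length = fields[14]
    n_points = fields[15]
    scales = fields[21:24]
    offsets = fields[24:27]
    if (ver_major, ver_minor) < (1, 0) or (ver_major, ver_minor) > (1, 4):
        raise GeodataError(f"unsupported LAS version {ver_major}.{ver_minor}")
    if n_points == 0 and (ver_major, ver_minor) >= (1, 4) and header_size >= 247 + 8:
        (n_points,) = struct.unpack("<Q", raw[247 : 247 + 8])

    _check_not_geographic(raw, n_vlr, header_size, point_offset)

    if point_format in (0, 1, 2, 3):
        base = _LEGACY_POINT_DTYPE
    elif point_format in (6, 7, 8):
        base = _MODERN_POINT_DTYPE
    else:
        raise GeodataError(f"unsupported LAS point format {point_format}")
    if record_length < base.itemsize:
        raise GeodataError("corrupt LAS: point record shorter than format minimum")
    end = point_offset + n_points * record_length
    if end > len(raw):
        raise GeodataError("corrupt LAS: truncated point data")

    rec = np.frombuffer(
        raw, dtype=np.dtype({"names": base.names,
                             "formats": [base.fields[n][0] for n in base.names],
                             "offsets": [base.fields[n][1] for n in base.names],
                             "itemsize": record_length}),
        count=n_points, offset=point_offset,
    )
    x = rec["X"] * scales[0] + offsets[0]
    y = rec["Y"] * scales[1] + offsets[1]
    z = rec["Z"] * scales[2] + offsets[2]
    if point_format in (0, 1, 2, 3):
        ret = (rec["flags"] & 0x07).astype(np.int32)
        classification = rec["classification"] & 0x1F
    else:
        ret = (rec["returns"] & 0x0F).astype(np.int32)
        classification = rec["classification"]
    ret = np.maximum(ret, 1)

    if bounds is not None:
        xmin, ymin, xmax, ymax = bounds
        keep = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
        x, y, z = x[keep], y[keep], z[keep]
        classification, ret = classification[keep], ret[keep]
    if len(x) == 0:
        raise GeodataError("no points within the requested bounds")
    return PointCloud(x, y, z, classification, ret, ret == 1)


def write_point_cloud(path, cloud: PointCloud, scale: float = 0.001) -> None:
    """Write a :class:`PointCloud` as LAS 1.2, point format 0."""
    path = Path(path)
    n = len(cloud)
    if n == 0:
        raise GeodataError("refusing to write an empty point cloud")
    off = (float(cloud.x.min()), float(cloud.y.min()), float(cloud.z.min()))
    header = struct.pack(
        _HEADER_FMT,
        b"LASF", 0, 0, b"\x00" * 16, 1, 2,
        b"canopylight".ljust(32, b"\x00"),
        b"canopylight".ljust(32, b"\x00"),
        1, 2000, _HEADER_SIZE, _HEADER_SIZE, 0, 0, 20, n,
        n, 0, 0, 0, 0,
        scale, scale, scale, off[0], off[1], off[2],
        float(cloud.x.max()), off[0],
        float(cloud.y.max()), off[1],
        float(cloud.z.max()), off[2],
    )
    rec = np.zeros(n, dtype=_LEGACY_POINT_DTYPE)
    rec["X"] = np.round((cloud.x - off[0]) / scale).astype(np.int32)
    rec["Y"] = np.round((cloud.y - off[1]) / scale).astype(np.int32)
    rec["Z"] = np.round((cloud.z - off[2]) / scale).astype(np.int32)
    ret = np.clip(cloud.return_number, 1, 7).astype(np.uint8)
    nret = np.where(cloud.is_first_return & (ret == 1), 1, np.maximum(ret, 2))
    rec["flags"] = (ret & 0x07) | ((nret.astype(np.uint8) & 0x07) << 3)
    rec["classification"] = cloud.class_code
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(rec.tobytes())


# ---------------------------------------------------------------------------
# GeoTIFF terrain rasters
# ---------------------------------------------------------------------------


def read_terrain(path) -> TerrainGrid:
    """Read a single-band GeoTIFF DTM into a :class:`TerrainGrid`."""
    path = Path(path)
    if not path.exists():
        raise GeodataError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise GeodataError("terrain raster must be single-band")
        tags = page.tags
        if 33550 not in tags or 33922 not in tags:
            raise GeodataError("terrain raster lacks a geotransform "
                               "(ModelPixelScale/ModelTiepoint)")
        sx, sy = tags[33550].value[:2]
        tie = tags[33922].value
        if abs(sx - sy) > 1e-9:
            raise GeodataError("non-square terrain cells are not supported")
        x_top_left, y_top_left = tie[3], tie[4]
        nodata = None
        if 42113 in tags:  # GDAL_NODATA
            try:
                nodata = float(str(tags[42113].value).strip("\x00 "))
            except ValueError:
                nodata = None
    elev = np.asarray(data, dtype=float)
    if nodata is not None:
        elev = np.where(elev == nodata, np.nan, elev)
    ny = elev.shape[0]
    origin = (float(x_top_left), float(y_top_left) - ny * float(sx))
    return TerrainGrid(elev, origin, float(sx))


def write_terrain(path, grid: TerrainGrid, nodata: float = -9999.0) -> None:
    """Write a :class:`TerrainGrid` as a single-band GeoTIFF."""
    data = np.asarray(grid.elevation, dtype=np.float32)
    data = np.where(np.isnan(data), np.float32(nodata), data)
    y_top = grid.origin[1] + grid.shape[0] * grid.cell_size
    extratags = [
        (33550, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (33922, "d", 6, (0.0, 0.0, 0.0, grid.origin[0], y_top, 0.0)),
        (42113, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


# ---------------------------------------------------------------------------
# height normalization
# ---------------------------------------------------------------------------


def normalize_heights(cloud: PointCloud) -> NormalizedCloud:
    """Compute per-return height above a ground surface interpolated from
    ground returns (Delaunay-linear inside the hull, nearest ground return
    outside)."""
    g = cloud.is_ground
    if g.sum() < 3:
        raise GeodataError("need at least 3 ground returns to normalize heights")
    gx, gy, gz = cloud.x[g], cloud.y[g], cloud.z[g]
    pts = np.column_stack([gx, gy])
    try:
        lin = LinearNDInterpolator(pts, gz)
    except QhullError as exc:
        raise GeodataError("ground returns are collinear; cannot triangulate") from exc
    ground = lin(cloud.x, cloud.y)
    outside = np.isnan(ground)
    if outside.any():
        near = NearestNDInterpolator(pts, gz)
        ground[outside] = near(cloud.x[outside], cloud.y[outside])
    return NormalizedCloud(
        cloud.x, cloud.y, cloud.z,
        cloud.class_code, cloud.return_number, cloud.is_first_return,
        height_above_ground=cloud.z - ground,
    )
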