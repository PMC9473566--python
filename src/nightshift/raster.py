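"""Lightweight georeferenced rasters, regions, and their file formats.

Rasters are plain numpy arrays plus a :class:`GridGeometry` (CRS string and
an affine transform in the usual GDAL/rasterio convention).  Files are
written as float32 TIFF with the full geospatial metadata serialized as
JSON into the TIFF image-description tag, so a write/read round trip is
lossless apart from the float32 quantization.  Regions travel as GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile
from shapely.geometry import mapping, shape
from shapely.validation import make_valid

__all__ = [
    "Affine",
    "GridGeometry",
    "Raster",
    "RegionSet",
    "read_raster",
    "write_raster",
    "read_regions",
    "write_regions",
]


@dataclass(frozen=True)
class Affine:
    """Affine map from (col, row) pixel indices to map coordinates.

    x = a*col + b*row + c ; y = d*col + e*row + f — the top-left corner of
    pixel (0, 0) maps to (c, f).
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, x0: float, y0: float, xres: float, yres: float) -> "Affine":
        """North-up grid with origin at the top-left corner."""
        return cls(xres, 0.0, x0, 0.0, -yres, y0)

    def xy(self, rows, cols, center: bool = True):
        """Map coordinates of pixels; ``center=True`` gives pixel centers."""
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        if center:
            rows = rows + 0.5
            cols = cols + 0.5
        x = self.a * cols + self.b * rows + self.c
        y = self.d * cols + self.e * rows + self.f
        return x, y

    def rowcol(self, x, y):
        """Fractional (row, col) of map coordinates (inverse transform)."""
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise ValueError("degenerate affine transform")
        x = np.asarray(x, dtype=float) - self.c
        y = np.asarray(y, dtype=float) - self.f
        col = (self.e * x - self.b * y) / det
        row = (-self.d * x + self.a * y) / det
        return row, col

    def to_list(self) -> list[float]:
        return [self.a, self.b, self.c, self.d, self.e, self.f]


@dataclass(frozen=True)
class GridGeometry:
    """CRS + transform + shape of an analysis grid.

    The study grid is 500-m pixels in the European equal-area projection
    (EPSG:3035).
    """

    crs: str
    transform: Affine
    shape: tuple[int, int]

    @classmethod
    def study_grid(
        cls,
        shape: tuple[int, int] = (300, 300),
        resolution_m: float = 500.0,
        origin: tuple[float, float] = (4_000_000.0, 3_000_000.0),
        crs: str = "EPSG:3035",
    ) -> "GridGeometry":
        return cls(
            crs=crs,
            transform=Affine.from_origin(origin[0], origin[1], resolution_m, resolution_m),
            shape=tuple(shape),
        )

    @property
    def resolution(self) -> float:
        return abs(self.transform.a)

    def pixel_centers(self):
        """(x, y) arrays of shape ``shape`` with every pixel-center coordinate."""
        rows, cols = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        return self.transform.xy(rows, cols, center=True)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GridGeometry)
            and self.crs == other.crs
            and self.shape == other.shape
            and np.allclose(self.transform.to_list(), other.transform.to_list())
        )

    def __hash__(self):
        return hash((self.crs, self.shape, tuple(self.transform.to_list())))


@dataclass
class Raster:
    """Multi-band raster with NaN as the nodata sentinel."""

    data: np.ndarray  # (bands, rows, cols) or (rows, cols)
    geometry: GridGeometry
    band_names: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise ValueError("raster data must be 2-D or 3-D")
        if self.data.shape[1:] != tuple(self.geometry.shape):
            raise ValueError(
                f"data shape {self.data.shape[1:]} does not match grid {self.geometry.shape}"
            )
        if not self.band_names:
            self.band_names = tuple(f"band_{i}" for i in range(self.data.shape[0]))
        if len(self.band_names) != self.data.shape[0]:
            raise ValueError("one band name per band required")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.all(np.isfinite(self.data), axis=0)

    def band(self, name: str) -> np.ndarray:
        return self.data[self.band_names.index(name)]


def write_raster(raster: Raster, path) -> None:
    """Write a raster as float32 TIFF with JSON geospatial metadata."""
    meta = {
        "crs": raster.geometry.crs,
        "transform": raster.geometry.transform.to_list(),
        "band_names": list(raster.band_names),
        "meta": raster.meta,
    }
    tifffile.imwrite(
        str(path),
        raster.data.astype(np.float32),
        description=json.dumps(meta),
        photometric="minisblack",
    )


def read_raster(path) -> Raster:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray().astype(float)
        desc = tif.pages[0].tags.get("ImageDescription")
        if desc is None:
            raise ValueError(f"{path}: no metadata tag; cannot determine CRS")
        meta = json.loads(desc.value)
    if "crs" not in meta or not meta["crs"]:
        raise ValueError(f"{path}: missing CRS in metadata")
    if data.ndim == 2:
        data = data[None]
    geom = GridGeometry(
        crs=meta["crs"],
        transform=Affine(*meta["transform"]),
        shape=data.shape[1:],
    )
    expected = len(meta.get("band_names", []))
    if expected and expected != data.shape[0]:
        raise ValueError(
            f"{path}: band-count mismatch (metadata {expected}, file {data.shape[0]})"
        )
    return Raster(
        data,
        geom,
        band_names=tuple(meta.get("band_names", ())),
        meta=meta.get("meta", {}),
    )


@dataclass
class RegionSet:
    """Named polygons (countries or species ranges) in an equal-area CRS."""

    names: list[str]
    geometries: list
    crs: str = "EPSG:3035"
    kind: str = "partition"  # "partition" (disjoint) or "ranges" (may overlap)

    def __post_init__(self):
        if len(self.names) != len(self.geometries):
            raise ValueError("one name per geometry required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("region IDs must be unique")
        self.geometries = [
            g if g.is_valid else make_valid(g) for g in self.geometries
        ]

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(zip(self.names, self.geometries))


def write_regions(regions: RegionSet, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"name": name},
            "geometry": mapping(geom),
        }
        for name, geom in regions
    ]
    doc = {
        "type": "FeatureCollection",
        "crs_name": regions.crs,
        "kind": regions.kind,
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_regions(path, crs: str | None = None) -> RegionSet:
    with open(path) as fh:
        doc = json.load(fh)
    names = [f["properties"].get("name", f"region_{i}") for i, f in enumerate(doc["features"])]
    geoms = [shape(f["geometry"]) for f in doc["features"]]
    file_crs = doc.get("crs_name") or crs
    if file_crs is None:
        raise ValueError(f"{path}: CRS not declared and none supplied")
    return RegionSet(names, geoms, crs=file_crs, kind=doc.get("kind", "partition"))
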