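"""Grid-aligned raster data model, file I/O and area accounting.

All stages of the pipeline share one convention: a rectangular grid of
square cells on a projected (equal-area) plane, addressed ``(row, col)``
with row 0 the northernmost row. Every cell covers the same ground area
(``cell_area_km2``), so zonal areas are exact cell counts times a
constant. Nodata propagates pessimistically: a derived cell is nodata
whenever any input cell is.

Rasters are stored as single-band TIFF files with the grid geometry,
nodata convention and (for categorical layers) the category dictionary
serialized as JSON into the TIFF ImageDescription tag, so that
``write_raster`` followed by ``read_raster`` is the identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "GridSpec",
    "Layer",
    "EnvStack",
    "AlignmentError",
    "align_stack",
    "read_raster",
    "write_raster",
    "total_area_km2",
    "rasterize_geojson",
]


class AlignmentError(ValueError):
    """Raised when layers that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid with constant per-cell area.

    Parameters
    ----------
    n_rows, n_cols:
        Grid dimensions; at least 1 each.
    origin_x, origin_y:
        Map coordinates of the *upper-left* corner of cell (0, 0).
        Row 0 is the northernmost row.
    cell_size:
        Side length of the square cells in map units.
    crs_label:
        Free-text label of the coordinate reference system.
    cell_area_km2:
        Ground area of one cell in km². Constant across the grid
        (equal-area convention).
    """

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    crs_label: str = "synthetic-equal-area"
    cell_area_km2: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.cell_area_km2 <= 0:
            raise ValueError("cell_area_km2 must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_of_point(self, x: float, y: float) -> tuple[int, int] | None:
        """Cell containing a map point, or None if outside the grid.

        Cells are half-open intervals [x, x + cell_size) in easting and
        (y - cell_size, y] in northing, consistent with row 0 north.
        """
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((self.origin_y - y) / self.cell_size))
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) map coordinates of every cell center, each shaped (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)


@dataclass
class Layer:
    """One named raster band on a :class:`GridSpec`.

    ``values`` is a float or integer array of shape ``grid.shape``;
    ``nodata_mask`` is True where the cell carries no data. Categorical
    layers store integer codes plus a ``categories`` mapping
    ``{code: label}``.
    """

    grid: GridSpec
    name: str
    values: np.ndarray
    nodata_mask: np.ndarray = None  # type: ignore[assignment]
    categories: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"!= grid shape {self.grid.shape}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.grid.shape:
            raise ValueError(f"layer {self.name!r}: nodata mask shape mismatch")

    @property
    def is_categorical(self) -> bool:
        return self.categories is not None

    def valid_values(self) -> np.ndarray:
        """Flat array of values on non-nodata cells."""
        return self.values[~self.nodata_mask]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "Layer":
        return Layer(
            grid=self.grid,
            name=self.name if name is None else name,
            values=values,
            nodata_mask=self.nodata_mask.copy(),
            categories=dict(self.categories) if self.categories else None,
        )

    def copy(self) -> "Layer":
        return self.with_values(self.values.copy())


@dataclass
class EnvStack:
    """A set of aligned continuous layers keyed by name (e.g. bio1..bio19)."""

    grid: GridSpec
    layers: dict[str, Layer] = field(default_factory=dict)
    source_label: str = "current"

    def __post_init__(self) -> None:
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names in stack")
        for name, layer in self.layers.items():
            if layer.grid != self.grid:
                raise AlignmentError(f"layer {name!r} grid differs from stack grid")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def shared_mask(self) -> np.ndarray:
        """Union of nodata over all layers (pessimistic propagation)."""
        mask = np.zeros(self.grid.shape, dtype=bool)
        for layer in self.layers.values():
            mask |= layer.nodata_mask
        return mask

    def __getitem__(self, name: str) -> Layer:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def subset(self, names: list[str], source_label: str | None = None) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return EnvStack(
            grid=self.grid,
            layers={n: self.layers[n] for n in names},
            source_label=self.source_label if source_label is None else source_label,
        )

    def matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Cell-by-variable matrix over non-nodata cells (row-major cell order)."""
        names = names if names is not None else self.layer_names
        valid = ~self.shared_mask
        return np.column_stack([self.layers[n].values[valid] for n in names])


def align_stack(layers: list[Layer], source_label: str = "current") -> EnvStack:
    """Assemble layers into an EnvStack, enforcing one shared grid.

    The union of the input nodata masks is propagated onto every layer
    of the returned stack.
    """
    if not layers:
        raise ValueError("align_stack requires at least one layer")
    grid = layers[0].grid
    for layer in layers[1:]:
        if layer.grid != grid:
            raise AlignmentError(
                f"layer {layer.name!r} is not aligned with layer {layers[0].name!r}"
            )
    union = np.zeros(grid.shape, dtype=bool)
    for layer in layers:
        union |= layer.nodata_mask
    aligned = {}
    for layer in layers:
        if layer.name in aligned:
            raise ValueError(f"duplicate layer name {layer.name!r}")
        aligned[layer.name] = Layer(
            grid=grid,
            name=layer.name,
            values=layer.values.copy(),
            nodata_mask=union.copy(),
            categories=dict(layer.categories) if layer.categories else None,
        )
    return EnvStack(grid=grid, layers=aligned, source_label=source_label)


_NODATA_FLOAT = -9999.0
_NODATA_INT = -9999


def write_raster(layer: Layer, path) -> None:
    """Write a layer as a single-band TIFF with JSON metadata.

    Grid geometry, the nodata sentinel and any category dictionary are
    stored in the ImageDescription tag so the round-trip is exact.
    """
    if layer.is_categorical or np.issubdtype(layer.values.dtype, np.integer):
        data = layer.values.astype(np.int32).copy()
        nodata = _NODATA_INT
        data[layer.nodata_mask] = nodata
    else:
        data = layer.values.astype(np.float64).copy()
        nodata = _NODATA_FLOAT
        data[layer.nodata_mask] = nodata
    meta = {
        "name": layer.name,
        "nodata": nodata,
        "grid": {
            "n_rows": layer.grid.n_rows,
            "n_cols": layer.grid.n_cols,
            "origin_x": layer.grid.origin_x,
            "origin_y": layer.grid.origin_y,
            "cell_size": layer.grid.cell_size,
            "crs_label": layer.grid.crs_label,
            "cell_area_km2": layer.grid.cell_area_km2,
        },
        "categories": (
            {str(k): v for k, v in layer.categories.items()}
            if layer.categories is not None
            else None
        ),
    }
    tifffile.imwrite(str(path), data, description=json.dumps(meta))


def read_raster(path) -> Layer:
    """Read a single-band TIFF written by :func:`write_raster`.

    Honours the nodata tag; rejects multi-band input.
    """
    with tifffile.TiffFile(str(path)) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: multi-band rasters are unsupported")
        page = tif.pages[0]
        data = page.asarray()
        desc = page.description
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single 2-D band, got shape {data.shape}")
    meta = json.loads(desc) if desc else {}
    gridmeta = meta.get("grid")
    if gridmeta is not None:
        grid = GridSpec(**gridmeta)
    else:
        grid = GridSpec(n_rows=data.shape[0], n_cols=data.shape[1])
    nodata = meta.get("nodata")
    if nodata is None:
        nodata = _NODATA_INT if np.issubdtype(data.dtype, np.integer) else _NODATA_FLOAT
    mask = data == nodata
    categories = meta.get("categories")
    if categories is not None:
        categories = {int(k): v for k, v in categories.items()}
    return Layer(
        grid=grid,
        name=meta.get("name", "band1"),
        values=data,
        nodata_mask=mask,
        categories=categories,
    )


def total_area_km2(mask: Layer | np.ndarray, grid: GridSpec) -> float:
    """Total area of the True, non-nodata cells of a boolean mask.

    Exact under the equal-area convention: count × cell_area_km2.
    """
    if isinstance(mask, Layer):
        if mask.grid != grid:
            raise AlignmentError("mask grid differs from the supplied grid")
        true_cells = np.asarray(mask.values, dtype=bool) & ~mask.nodata_mask
    else:
        arr = np.asarray(mask, dtype=bool)
        if arr.shape != grid.shape:
            raise AlignmentError("mask shape differs from grid shape")
        true_cells = arr
    return float(np.count_nonzero(true_cells)) * grid.cell_area_km2


def rasterize_geojson(geojson: dict, grid: GridSpec, name: str = "rasterized") -> Layer:
    """Rasterize GeoJSON polygons onto the grid by cell-center containment.

    Returns a boolean layer: True where a cell center falls inside (or on
    the boundary of) any polygon feature.
    """
    import shapely
    from shapely.geometry import shape

    geoms = []
    if geojson.get("type") == "FeatureCollection":
        feats = geojson["features"]
    elif geojson.get("type") == "Feature":
        feats = [geojson]
    else:
        feats = [{"geometry": geojson}]
    for feat in feats:
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(f"unsupported geometry type {geom.geom_type!r}")
        geoms.append(geom)
    xs, ys = grid.cell_centers()
    inside = np.zeros(grid.shape, dtype=bool)
    for geom in geoms:
        inside |= shapely.intersects_xy(geom, xs, ys)
    return Layer(grid=grid, name=name, values=inside)
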