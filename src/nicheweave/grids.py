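"""Grid geometry and raster containers shared by all pipeline stages.

Rasters are stored row-major with row 0 at the *southern* edge, so the row
index increases with latitude.  Two on-disk formats are supported: a
dependency-light plain-text multi-layer grid dialect (used throughout the
test-suite and for small artifacts) and NetCDF via :mod:`xarray`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Order of the three climate variables everywhere in the package.
CLIMATE_VARIABLES = ("tmax", "tmin", "vpd")

#: Order of the nine harmonic-coefficient predictor layers.
PREDICTOR_LAYERS = tuple(
    f"{var}_{coef}" for var in CLIMATE_VARIABLES for coef in ("a0", "a1", "b1")
)


@dataclass(frozen=True)
class GridGeometry:
    """Rectangular grid: origin at the lower-left (south-west) corner."""

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    x_origin: float = 0.0
    y_origin: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not np.isfinite([self.cell_size, self.x_origin, self.y_origin]).all():
            raise ValueError("grid geometry parameters must be finite")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (lon, lat) arrays of shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        lon = self.x_origin + (cols + 0.5) * self.cell_size
        lat = self.y_origin + (rows + 0.5) * self.cell_size
        return np.meshgrid(lon, lat)

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """Map a coordinate to its (row, col) cell, clipping to the extent edge."""
        col = int(np.clip((lon - self.x_origin) // self.cell_size, 0, self.n_cols - 1))
        row = int(np.clip((lat - self.y_origin) // self.cell_size, 0, self.n_rows - 1))
        return row, col

    def flat_index(self, row: int, col: int) -> int:
        return row * self.n_cols + col


@dataclass
class ClimateGrid:
    """Per-cell 12-month climatologies for tmax (degC), tmin (degC), vpd (kPa)."""

    geometry: GridGeometry
    values: dict[str, np.ndarray]  # var -> (12, n_rows, n_cols)

    def __post_init__(self) -> None:
        for var in CLIMATE_VARIABLES:
            if var not in self.values:
                raise ValueError(f"missing climate variable {var!r}")
            arr = np.asarray(self.values[var], dtype=float)
            if arr.shape != (12, self.geometry.n_rows, self.geometry.n_cols):
                raise ValueError(
                    f"{var}: expected shape (12, {self.geometry.n_rows}, "
                    f"{self.geometry.n_cols}), got {arr.shape}"
                )
            self.values[var] = arr

    def validate_physical(self) -> None:
        """tmax must not fall below tmin in any cell-month with data."""
        tmax, tmin = self.values["tmax"], self.values["tmin"]
        ok = ~np.isnan(tmax) & ~np.isnan(tmin)
        if np.any(tmax[ok] < tmin[ok]):
            raise ValueError("tmax < tmin in at least one cell-month")


@dataclass
class PredictorStack:
    """Nine harmonic-coefficient layers (a0, a1, b1 per climate variable)."""

    geometry: GridGeometry
    layers: np.ndarray  # (9, n_rows, n_cols)
    mask: np.ndarray = field(default=None)  # True where the cell is invalid

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.shape != (9, self.geometry.n_rows, self.geometry.n_cols):
            raise ValueError("predictor stack must have 9 layers of grid shape")
        if self.mask is None:
            self.mask = np.any(~np.isfinite(self.layers), axis=0)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def layer_names(self) -> tuple[str, ...]:
        return PREDICTOR_LAYERS

    def as_table(self, valid_only: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Return (cell_ids, X) with X of shape (n, 9), row-major cell ids."""
        flat = self.layers.reshape(9, -1).T
        ids = np.arange(self.geometry.n_cells)
        if valid_only:
            keep = ~self.mask.reshape(-1)
            return ids[keep], flat[keep]
        return ids, flat

    def cell_vector(self, row: int, col: int) -> np.ndarray:
        return self.layers[:, row, col]


@dataclass
class EcosystemMap:
    """Categorical ecosystem raster with an integer-label legend."""

    geometry: GridGeometry
    labels: np.ndarray  # (n_rows, n_cols) integer labels
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise ValueError("ecosystem labels must match the grid shape")
        if not self.legend:
            self.legend = {int(k): f"eco_{int(k)}" for k in np.unique(self.labels)}

    @property
    def ecosystem_ids(self) -> list[int]:
        return [int(v) for v in np.unique(self.labels)]

    def cells_of(self, ecosystem_id: int) -> np.ndarray:
        """Boolean membership mask for one ecosystem."""
        if ecosystem_id not in self.ecosystem_ids:
            raise KeyError(f"ecosystem {ecosystem_id} not present in map")
        return self.labels == ecosystem_id


# ---------------------------------------------------------------------------
# Plain-text multi-layer grid dialect
#
#   nrows 4
#   ncols 5
#   cellsize 1.0
#   xorigin 0.0
#   yorigin 0.0
#   layer tmax_m01
#   <ncols floats> x nrows lines, southernmost row first
#   layer ...
# ---------------------------------------------------------------------------


def write_text_grid(path: str | Path, geometry: GridGeometry, layers: dict[str, np.ndarray]) -> None:
    lines = [
        f"nrows {geometry.n_rows}",
        f"ncols {geometry.n_cols}",
        f"cellsize {geometry.cell_size!r}",
        f"xorigin {geometry.x_origin!r}",
        f"yorigin {geometry.y_origin!r}",
    ]
    for name, arr in layers.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (geometry.n_rows, geometry.n_cols):
            raise ValueError(f"layer {name!r} does not match the grid shape")
        lines.append(f"layer {name}")
        for row in arr:
            lines.append(" ".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_text_grid(path: str | Path) -> tuple[GridGeometry, dict[str, np.ndarray]]:
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines) and not lines[i].startswith("layer "):
        key, value = lines[i].split(maxsplit=1)
        header[key] = float(value)
        i += 1
    geometry = GridGeometry(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=header["cellsize"],
        x_origin=header["xorigin"],
        y_origin=header["yorigin"],
    )
    layers: dict[str, np.ndarray] = {}
    while i < len(lines):
        if not lines[i].startswith("layer "):
            raise ValueError(f"expected 'layer' at line {i + 1} of {path}")
        name = lines[i].split(maxsplit=1)[1]
        block = lines[i + 1 : i + 1 + geometry.n_rows]
        layers[name] = np.array([[float(v) for v in row.split()] for row in block])
        i += 1 + geometry.n_rows
    return geometry, layers


def climate_layer_names() -> list[str]:
    return [f"{var}_m{m:02d}" for var in CLIMATE_VARIABLES for m in range(1, 13)]


def write_climate_grid(path: str | Path, grid: ClimateGrid) -> None:
    layers = {
        f"{var}_m{m + 1:02d}": grid.values[var][m]
        for var in CLIMATE_VARIABLES
        for m in range(12)
    }
    write_text_grid(path, grid.geometry, layers)


def read_climate_grid(path: str | Path) -> ClimateGrid:
    geometry, layers = read_text_grid(path)
    values = {}
    for var in CLIMATE_VARIABLES:
        values[var] = np.stack([layers[f"{var}_m{m + 1:02d}"] for m in range(12)])
    return ClimateGrid(geometry=geometry, values=values)


def write_predictor_stack(path: str | Path, stack: PredictorStack) -> None:
    layers = {name: stack.layers[i] for i, name in enumerate(PREDICTOR_LAYERS)}
    write_text_grid(path, stack.geometry, layers)


def read_predictor_stack(path: str | Path) -> PredictorStack:
    geometry, layers = read_text_grid(path)
    return PredictorStack(
        geometry=geometry, layers=np.stack([layers[name] for name in PREDICTOR_LAYERS])
    )


def write_ecosystem_map(path: str | Path, eco: EcosystemMap) -> None:
    """Integer raster in the text dialect plus a JSON legend side-car."""
    write_text_grid(path, eco.geometry, {"ecosystem": eco.labels.astype(float)})
    legend_path = Path(path).with_suffix(".legend.json")
    legend_path.write_text(json.dumps({str(k): v for k, v in eco.legend.items()}))


def read_ecosystem_map(path: str | Path) -> EcosystemMap:
    geometry, layers = read_text_grid(path)
    legend_path = Path(path).with_suffix(".legend.json")
    legend = {}
    if legend_path.exists():
        legend = {int(k): v for k, v in json.loads(legend_path.read_text()).items()}
    return EcosystemMap(geometry=geometry, labels=layers["ecosystem"].astype(int), legend=legend)


def climate_to_netcdf(path: str | Path, grid: ClimateGrid) -> None:
    """Write the climate grid as a NetCDF file (lat/lon/month dimensions)."""
    import xarray as xr

    lon, lat = grid.geometry.cell_centers()
    ds = xr.Dataset(
        {var: (("month", "lat", "lon"), grid.values[var]) for var in CLIMATE_VARIABLES},
        coords={"month": np.arange(1, 13), "lat": lat[:, 0], "lon": lon[0, :]},
        attrs={"cell_size": grid.geometry.cell_size},
    )
    ds.to_netcdf(path, engine="scipy")


def climate_from_netcdf(path: str | Path) -> ClimateGrid:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        cell = float(ds.attrs["cell_size"])
        lat = ds["lat"].values
        lon = ds["lon"].values
        geometry = GridGeometry(
            n_rows=lat.size,
            n_cols=lon.size,
            cell_size=cell,
            x_origin=float(lon[0]) - cell / 2,
            y_origin=float(lat[0]) - cell / 2,
        )
        values = {var: ds[var].values.astype(float) for var in CLIMATE_VARIABLES}
    return ClimateGrid(geometry=geometry, values=values)
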