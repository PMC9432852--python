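"""Grids, rasters and occurrence records.

Everything downstream (PCA, MaxEnt, diagnostics, habitat classing) operates on
three containers defined here: a :class:`GridSpec` describing a regular
lon/lat grid (WGS84, top-left origin, row index increasing southward), a
:class:`Layer` holding one masked value surface on such a grid, and a
:class:`Stack` of uniquely named layers sharing one grid.  Occurrence records
are plain lon/lat presence points tagged with a species name.

Rasters are read and written as ESRI ASCII grids (plain text, explicit
``NODATA_value``), the portable lowest common denominator for single-band
geographic grids.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

SCENARIOS = ("current", "SSP126", "SSP245", "SSP370", "SSP585")
PERIODS = ("2020-2040", "2040-2060", "2060-2080", "2080-2100")


class GeodataError(ValueError):
    """Malformed input: bad grid, incompatible layers, or unreadable file."""


@dataclass(frozen=True)
class GridSpec:
    """Regular geographic grid: square cells, top-left (NW) origin.

    ``origin_lon`` is the west edge and ``origin_lat`` the north edge of the
    grid; row index increases southward.  A point belongs to a cell by the
    half-open convention [west, east) x (south, north].
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise GeodataError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeodataError("grid must have at least one row and column")
        east = self.origin_lon + self.n_cols * self.cell_size
        south = self.origin_lat - self.n_rows * self.cell_size
        if not (-180.0 - 1e-9 <= self.origin_lon and east <= 180.0 + 1e-9):
            raise GeodataError("grid exceeds [-180, 180] longitude bounds")
        if not (-90.0 - 1e-9 <= south and self.origin_lat <= 90.0 + 1e-9):
            raise GeodataError("grid exceeds [-90, 90] latitude bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_index(self, lon: float | np.ndarray, lat: float | np.ndarray):
        """Map coordinates to (row, col); either may be out of range."""
        col = np.floor((np.asarray(lon) - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((self.origin_lat - np.asarray(lat)) / self.cell_size).astype(int)
        # top edge of the grid belongs to row 0 under (south, north]
        row = np.where(np.asarray(lat) == self.origin_lat, 0, row)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.cell_index(lon, lat)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        lon = self.origin_lon + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.origin_lat - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat


@dataclass
class Layer:
    """One value surface on a grid with an explicit validity mask."""

    spec: GridSpec
    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.spec.shape or self.valid_mask.shape != self.spec.shape:
            raise GeodataError(
                f"layer arrays must have shape {self.spec.shape}, "
                f"got {self.values.shape} / {self.valid_mask.shape}"
            )
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise GeodataError("layer has non-finite values inside the valid mask")

    @classmethod
    def full(cls, spec: GridSpec, values: np.ndarray, mask: np.ndarray | None = None) -> "Layer":
        values = np.asarray(values, dtype=float)
        if mask is None:
            mask = np.isfinite(values)
        return cls(spec, np.where(mask, values, np.nan), mask)

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def same_grid(self, other: "Layer | Stack") -> bool:
        return self.spec == other.spec


@dataclass
class Stack:
    """Ordered, uniquely named layers sharing one grid."""

    spec: GridSpec
    layers: dict[str, Layer] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, layer in self.layers.items():
            if layer.spec != self.spec:
                raise GeodataError(f"layer {name!r} does not share the stack grid")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> Layer:
        return self.layers[name]

    def add(self, name: str, layer: Layer) -> None:
        if name in self.layers:
            raise GeodataError(f"duplicate layer name {name!r}")
        if layer.spec != self.spec:
            raise GeodataError(f"layer {name!r} does not share the stack grid")
        self.layers[name] = layer

    def joint_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        mask = np.ones(self.spec.shape, dtype=bool)
        for layer in self.layers.values():
            mask &= layer.valid_mask
        return mask

    def to_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Valid cells as a (cells x layers) matrix, row-major cell order."""
        if mask is None:
            mask = self.joint_mask()
        return np.column_stack([self.layers[n].values[mask] for n in self.names])

    def subset(self, names: Sequence[str]) -> "Stack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise GeodataError(f"stack is missing layers {missing}")
        return Stack(self.spec, {n: self.layers[n] for n in names})


@dataclass
class OccurrenceSet:
    """Presence records for one species (lon, lat in decimal degrees)."""

    species: str
    records: np.ndarray  # (n, 2) columns lon, lat

    def __post_init__(self) -> None:
        self.records = np.asarray(self.records, dtype=float).reshape(-1, 2)
        if len(self.records):
            lon, lat = self.records[:, 0], self.records[:, 1]
            if not (np.all(np.abs(lon) <= 180) and np.all(np.abs(lat) <= 90)):
                raise GeodataError(f"{self.species}: coordinates outside world bounds")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ScenarioKey:
    """Climate scenario identifier: 'current' or an SSP with a 20-year period."""

    scenario: str
    period: str | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise GeodataError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "current":
            if self.period is not None:
                raise GeodataError("'current' takes no period")
        elif self.period not in PERIODS:
            raise GeodataError(f"future scenario needs a period from {PERIODS}")

    def __str__(self) -> str:
        return self.scenario if self.period is None else f"{self.scenario}_{self.period}"

    @classmethod
    def parse(cls, text: str) -> "ScenarioKey":
        if text == "current":
            return cls("current")
        scenario, _, period = text.partition("_")
        return cls(scenario, period or None)


def future_keys() -> list[ScenarioKey]:
    """All 16 SSP x period keys in canonical order."""
    return [ScenarioKey(s, p) for s in SCENARIOS[1:] for p in PERIODS]


# ---------------------------------------------------------------------------
# occurrences


def read_occurrences(path: str | Path, species: str) -> OccurrenceSet:
    """Read and clean a lon/lat occurrence CSV.

    Rows missing either coordinate are dropped; exact duplicates (after
    rounding to 6 decimal places, about 0.11 m) are collapsed to the first.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise GeodataError(f"{path}: empty file") from None
        cols = {c.strip().lower(): i for i, c in enumerate(header)}
        if "longitude" not in cols or "latitude" not in cols:
            raise GeodataError(f"{path}: header must contain 'longitude' and 'latitude'")
        ilon, ilat = cols["longitude"], cols["latitude"]
        records: list[tuple[float, float]] = []
        seen: set[tuple[float, float]] = set()
        n_missing = n_dup = n_bad = 0
        for row in reader:
            lon_s = row[ilon].strip() if ilon < len(row) else ""
            lat_s = row[ilat].strip() if ilat < len(row) else ""
            if not lon_s or not lat_s:
                n_missing += 1
                continue
            try:
                lon, lat = float(lon_s), float(lat_s)
            except ValueError:
                n_bad += 1
                logger.warning("%s: unparsable coordinate row %r dropped", path, row)
                continue
            key = (round(lon, 6), round(lat, 6))
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            records.append((lon, lat))
    if n_missing or n_dup or n_bad:
        logger.info(
            "%s (%s): dropped %d missing-coordinate, %d duplicate, %d unparsable rows",
            path, species, n_missing, n_dup, n_bad,
        )
    if not records:
        logger.warning("%s: no usable occurrence records for %s", path, species)
        return OccurrenceSet(species, np.empty((0, 2)))
    return OccurrenceSet(species, np.array(records))


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "longitude", "latitude"])
        for lon, lat in occ.records:
            writer.writerow([occ.species, repr(float(lon)), repr(float(lat))])


def thin_to_cells(occ: OccurrenceSet, spec: GridSpec) -> OccurrenceSet:
    """Spatial thinning: keep at most one record per grid cell.

    The first record per cell in input order survives; records outside the
    grid extent are dropped with a warning.
    """
    if len(occ) == 0:
        return OccurrenceSet(occ.species, np.empty((0, 2)))
    lon, lat = occ.records[:, 0], occ.records[:, 1]
    inside = spec.contains(lon, lat)
    n_out = int(np.sum(~inside))
    if n_out:
        logger.warning("%s: %d records outside grid extent dropped", occ.species, n_out)
    rows, cols = spec.cell_index(lon, lat)
    keep: list[int] = []
    occupied: set[tuple[int, int]] = set()
    for i in range(len(occ)):
        if not inside[i]:
            continue
        cell = (int(rows[i]), int(cols[i]))
        if cell not in occupied:
            occupied.add(cell)
            keep.append(i)
    return OccurrenceSet(occ.species, occ.records[keep])


def occurrence_cells(occ: OccurrenceSet, spec: GridSpec) -> np.ndarray:
    """(n, 2) array of (row, col) cell indices; records must lie inside."""
    rows, cols = spec.cell_index(occ.records[:, 0], occ.records[:, 1])
    return np.column_stack([rows, cols])


# ---------------------------------------------------------------------------
# stacks and ensembling


def average_gcms(stacks: Sequence[Stack]) -> Stack:
    """Cellwise mean across GCM variants; nodata propagates (strict intersection)."""
    if len(stacks) < 2:
        raise GeodataError("GCM ensembling needs at least two stacks")
    ref = stacks[0]
    for s in stacks[1:]:
        if s.spec != ref.spec:
            raise GeodataError("GCM stacks have mismatched grids")
        if s.names != ref.names:
            raise GeodataError("GCM stacks have mismatched layer names")
    out = Stack(ref.spec)
    for name in ref.names:
        mask = np.ones(ref.spec.shape, dtype=bool)
        for s in stacks:
            mask &= s[name].valid_mask
        vals = np.mean([np.where(mask, s[name].values, 0.0) for s in stacks], axis=0)
        out.add(name, Layer(ref.spec, np.where(mask, vals, np.nan), mask))
    return out


def cell_area_km2(spec: GridSpec) -> Layer:
    """Spherical cell areas, constant along rows.

    A = R^2 * dlambda * (sin(phi_top) - sin(phi_bottom)) with the IUGG mean
    radius R = 6371.0088 km.
    """
    row_a = row_areas_km2(spec)
    values = np.repeat(row_a[:, None], spec.n_cols, axis=1)
    return Layer(spec, values, np.ones(spec.shape, dtype=bool))


def row_areas_km2(spec: GridSpec) -> np.ndarray:
    """Per-row cell area (km^2); avoids materialising the full grid."""
    rows = np.arange(spec.n_rows)
    top = np.radians(spec.origin_lat - rows * spec.cell_size)
    bottom = np.radians(spec.origin_lat - (rows + 1) * spec.cell_size)
    dlam = math.radians(spec.cell_size)
    return EARTH_RADIUS_KM**2 * dlam * (np.sin(top) - np.sin(bottom))


def masked_area_km2(mask: np.ndarray, spec: GridSpec) -> float:
    """Total area of True cells."""
    row_a = row_areas_km2(spec)
    return float(np.sum(row_a * mask.sum(axis=1)))


# ---------------------------------------------------------------------------
# raster I/O (ESRI ASCII grid)


def write_raster(layer: Layer, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a layer as an ESRI ASCII grid with full float precision."""
    spec = layer.spec
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.origin_lon!r}\n")
        fh.write(f"yllcorner {spec.origin_lat - spec.n_rows * spec.cell_size!r}\n")
        fh.write(f"cellsize {spec.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        vals = np.where(layer.valid_mask, layer.values, nodata)
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_raster(path: str | Path) -> Layer:
    """Read an ESRI ASCII grid; nodata cells become masked."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise GeodataError(f"{path}: truncated ASCII grid")
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if key not in header:
                raise GeodataError(f"{path}: missing ASCII grid header field {key!r}")
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise GeodataError(f"{path}: data shape {values.shape} != header ({n_rows}, {n_cols})")
    spec = GridSpec(
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
    )
    nodata = header.get("nodata_value")
    mask = np.isfinite(values)
    if nodata is not None:
        mask &= values != nodata
    return Layer(spec, np.where(mask, values, np.nan), mask)


def write_stack(stack: Stack, directory: str | Path, key: ScenarioKey | None = None) -> Path:
    """Write all layers plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for name in stack.names:
        fname = f"{name}.asc"
        write_raster(stack[name], directory / fname)
        entries.append({"name": name, "file": fname})
    manifest = {
        "scenario": str(key) if key is not None else None,
        "layers": entries,
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def read_stack(directory: str | Path) -> Stack:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    stack: Stack | None = None
    for entry in manifest["layers"]:
        layer = read_raster(directory / entry["file"])
        if stack is None:
            stack = Stack(layer.spec)
        stack.add(entry["name"], layer)
    if stack is None:
        raise GeodataError(f"{directory}: manifest lists no layers")
    return stack
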