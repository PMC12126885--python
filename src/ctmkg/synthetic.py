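"""Synthetic CHIMERE-like surface output and municipality geometries.

Stands in for a real chemistry-transport-model run so the whole pipeline
(netCDF -> table -> knowledge graph -> queries) is exercisable without any
download.  The generator produces, for a planar gridded domain:

* a seeded Voronoi tessellation of the domain rectangle into M
  municipalities (an exact partition — polygons cover the domain with no
  overlap), and
* hourly surface fields for the nine use-case species (NO2, NO, O3, SO2,
  CH4, NH3, CO, PM10, PM2.5) plus temperature and pressure:

      value[t, y, x] = max(0, baseline + amplitude * sin(2*pi*t/24) + e[t, y, x])

  where ``e`` is a stationary AR(1) process in time per cell (marginal
  standard deviation ``noise_sd``, lag-1 autocorrelation ``ar1_rho``) whose
  innovations mix a domain-wide component with per-cell noise, plus a fixed
  smooth spatial gradient of magnitude ``noise_sd`` so snapshots are not
  flat (in the noise-free limit every value is exactly the baseline plus
  the diurnal term).  Everything is fully determined by the domain seed.  Concentrations are clipped at zero;
  temperature and pressure are not (their baselines keep them far from 0).

Default magnitudes are typical rural-Mediterranean ambient levels in
ug/m3 (CH4 and CO are high because both are reported as mass
concentrations, not ppb), 288 K and standard surface pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .grid import Grid
from .ingest import GriddedField
from .spatial import Municipality, MunicipalitySet

__all__ = [
    "DEFAULT_SPECIES",
    "DomainSpec",
    "FieldSpec",
    "make_municipalities",
    "simulate_fields",
    "write_ctm_netcdf",
    "make_default_fixture",
]

DEFAULT_SPECIES = ["NO2", "NO", "O3", "SO2", "CH4", "NH3", "CO", "PM10", "PM2.5"]

#: baseline concentrations, ug/m3
DEFAULT_BASELINES = {
    "NO2": 18.0,
    "NO": 8.0,
    "O3": 55.0,
    "SO2": 4.0,
    "CH4": 1300.0,
    "NH3": 6.0,
    "CO": 250.0,
    "PM10": 22.0,
    "PM2.5": 11.0,
}

#: diurnal-cycle amplitudes, ug/m3
DEFAULT_AMPLITUDES = {
    "NO2": 6.0,
    "NO": 3.0,
    "O3": 20.0,
    "SO2": 1.0,
    "CH4": 40.0,
    "NH3": 1.5,
    "CO": 50.0,
    "PM10": 6.0,
    "PM2.5": 3.0,
}

#: example consistency-check timestamp: 2023-12-26 06:00:00 UTC in epoch ms
DEFAULT_START_MS = 1_703_570_400_000
HOUR_MS = 3_600_000


@dataclass(frozen=True)
class DomainSpec:
    """Planar gridded domain: nx x ny square cells of cell_size metres."""

    nx: int = 15
    ny: int = 15
    cell_size: float = 1000.0
    origin: tuple[float, float] = (0.0, 0.0)
    n_municipalities: int = 45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("nx and ny must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not 1 <= self.n_municipalities <= self.nx * self.ny:
            raise ValueError(
                f"n_municipalities must be in [1, nx*ny={self.nx * self.ny}]"
            )

    @property
    def grid(self) -> Grid:
        return Grid(
            x0=self.origin[0],
            y0=self.origin[1],
            cell_size=self.cell_size,
            nx=self.nx,
            ny=self.ny,
        )


@dataclass(frozen=True)
class FieldSpec:
    """What to simulate: species, duration, magnitudes and noise structure."""

    species: tuple[str, ...] = tuple(DEFAULT_SPECIES)
    hours: int = 73
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    noise_sd: float = 2.0
    ar1_rho: float = 0.7
    temperature_baseline: float = 288.15
    temperature_amplitude: float = 5.0
    pressure_baseline: float = 101_325.0
    start_ms: int = DEFAULT_START_MS

    def __post_init__(self) -> None:
        if self.hours < 1:
            raise ValueError("hours must be >= 1")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for s in self.species:
            b = self.baselines.get(s)
            if b is None:
                raise ValueError(f"no baseline for species {s!r}")
            if b < 0:
                raise ValueError(f"baseline for {s!r} must be >= 0")


def make_municipalities(domain: DomainSpec) -> MunicipalitySet:
    """Seeded Voronoi partition of the domain rectangle into M polygons.

    Polygons are valid, pairwise non-overlapping and exactly cover the
    domain; names are "M001".. in seed-point order.  Deterministic in
    ``domain.seed``.
    """
    grid = domain.grid
    rect = box(*grid.bounds())
    m = domain.n_municipalities
    if m == 1:
        return MunicipalitySet([Municipality(id="M001", name="M001", polygon=rect)])

    rng = np.random.default_rng(domain.seed)
    xmin, ymin, xmax, ymax = grid.bounds()
    pts = np.column_stack(
        [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
    )
    cells = voronoi_diagram(MultiPoint(pts.tolist()), envelope=rect)
    clipped = [g.intersection(rect) for g in cells.geoms]
    # voronoi_diagram returns cells in arbitrary order: match each to its seed
    ordered = []
    remaining = list(clipped)
    for x, y in pts:
        p = Point(x, y)
        hit = next((i for i, c in enumerate(remaining) if c.covers(p)), None)
        if hit is None:
            raise RuntimeError("Voronoi cell lookup failed; degenerate seed points")
        ordered.append(remaining.pop(hit))
    entries = [
        Municipality(id=f"M{i + 1:03d}", name=f"M{i + 1:03d}", polygon=poly)
        for i, poly in enumerate(ordered)
    ]
    return MunicipalitySet(entries)


def _ar1_noise(rng: np.random.Generator, h: int, ny: int, nx: int,
               sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1)-in-time noise cube with marginal sd and lag-1 rho.

    Innovations mix a shared domain-wide term with per-cell terms (half the
    variance each) so neighbouring hours AND the whole map co-fluctuate.
    """
    if sd == 0.0:
        return np.zeros((h, ny, nx))
    shared = rng.standard_normal(h)[:, None, None]
    local = rng.standard_normal((h, ny, nx))
    eps = np.sqrt(0.5) * (shared + local)  # unit-variance innovations
    out = np.empty((h, ny, nx))
    out[0] = eps[0]
    scale = np.sqrt(1.0 - rho * rho)
    for t in range(1, h):
        out[t] = rho * out[t - 1] + scale * eps[t]
    return sd * out


def _spatial_pattern(grid: Grid) -> np.ndarray:
    """Fixed smooth modulation in [-1, 1] over the domain (unitless)."""
    x = (np.arange(grid.nx) + 0.5) / grid.nx
    y = (np.arange(grid.ny) + 0.5) / grid.ny
    return np.sin(np.pi * x)[None, :] * np.cos(np.pi * y)[:, None]


def simulate_fields(domain: DomainSpec, spec: FieldSpec) -> list[GriddedField]:
    """Simulate every species plus temperature and pressure.

    Deterministic in ``domain.seed``; concentrations clipped to >= 0.
    """
    grid = domain.grid
    rng = np.random.default_rng(domain.seed)
    h = spec.hours
    ts = spec.start_ms + HOUR_MS * np.arange(h, dtype=np.int64)
    t = np.arange(h)
    diurnal = np.sin(2.0 * np.pi * t / 24.0)[:, None, None]
    pattern = _spatial_pattern(grid)[None, :, :]

    # the deterministic spatial gradient scales with noise_sd so the
    # noise-free limit is exactly the baseline everywhere
    fields = []
    for s in spec.species:
        base = spec.baselines[s]
        amp = spec.amplitudes.get(s, 0.0)
        noise = _ar1_noise(rng, h, grid.ny, grid.nx, spec.noise_sd, spec.ar1_rho)
        vals = base + spec.noise_sd * pattern + amp * diurnal + noise
        np.clip(vals, 0.0, None, out=vals)
        fields.append(GriddedField(s, "ug/m3", ts, grid, vals))

    tsd = min(spec.noise_sd, 1.0)
    tnoise = _ar1_noise(rng, h, grid.ny, grid.nx, tsd, spec.ar1_rho)
    temp = (
        spec.temperature_baseline
        + spec.temperature_amplitude * diurnal
        + 2.0 * tsd * pattern
        + tnoise
    )
    fields.append(GriddedField("temperature", "K", ts, grid, temp))

    pnoise = _ar1_noise(rng, h, grid.ny, grid.nx, 20.0 * tsd, spec.ar1_rho)
    pres = spec.pressure_baseline + 50.0 * tsd * pattern + pnoise
    fields.append(GriddedField("pressure", "Pa", ts, grid, pres))
    return fields


def write_ctm_netcdf(fields: list[GriddedField], path) -> None:
    """Write fields to netCDF with dims (time, level=1, y, x).

    The time variable holds epoch milliseconds (stored as float64, exact
    for any realistic epoch); grid geometry goes into global attributes so
    the reader can reconstruct it.  Classic netCDF-3 via the scipy backend,
    readable by any netCDF implementation.
    """
    import xarray as xr

    if not fields:
        raise ValueError("no fields to write")
    grid = fields[0].grid
    ts = fields[0].timestamps
    for f in fields[1:]:
        if f.grid != grid or f.values.shape != fields[0].values.shape:
            raise ValueError(f"field {f.name!r} has mismatched grid/shape")
        if not np.array_equal(f.timestamps, ts):
            raise ValueError(f"field {f.name!r} has a mismatched time axis")

    data_vars = {}
    for f in fields:
        arr = f.values[:, None, :, :]  # insert length-1 level dim
        data_vars[f.name] = xr.DataArray(
            arr, dims=("time", "level", "y", "x"), attrs={"units": f.unit}
        )
    ds = xr.Dataset(
        data_vars,
        coords={"time": ("time", ts.astype("float64"),
                         {"units": "milliseconds since 1970-01-01 00:00:00 UTC"})},
        attrs={
            "x0": grid.x0,
            "y0": grid.y0,
            "cell_size": grid.cell_size,
            "source": "ctmkg synthetic CTM surface output",
        },
    )
    ds.to_netcdf(str(path), engine="scipy")


def make_default_fixture(seed: int = 0, hours: int = 73, n_municipalities: int = 45,
                         species: tuple[str, ...] | None = None):
    """Convenience: (fields, municipalities) at the default use-case scale.

    73 hourly steps x 45 municipalities x 9 species on a 15 x 15 km domain.
    """
    domain = DomainSpec(seed=seed, n_municipalities=n_municipalities)
    spec = FieldSpec(hours=hours, species=tuple(species or DEFAULT_SPECIES))
    return simulate_fields(domain, spec), make_municipalities(domain)
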