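"""Read CTM netCDF output and build the tabular/XML pipeline intermediates.

The pipeline mirrors a standard ontology-driven ETL for gridded forecast
output: the netCDF multidimensional arrays are reduced to the surface
level, aggregated per administrative unit, and laid out as one record per
(municipality, timestamp) carrying every selected species plus temperature
and pressure.  That table is what the mapping engine consumes; it can also
be round-tripped through CSV and through XML+XSD.

CSV dialect (fixed so round-trips are bit-stable): comma-separated, UTF-8,
'.' decimal point, header ``municipality,timestamp,<species...>,
temperature,pressure``.  Floats are written with Python's shortest
round-trip repr, so write->read recovers the exact binary values.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from lxml import etree

from .grid import Grid
from .spatial import MunicipalitySet, area_weighted_mean, overlap_weights

__all__ = [
    "GriddedField",
    "ForecastTable",
    "read_ctm_netcdf",
    "build_forecast_table",
    "write_csv",
    "read_csv",
    "write_xml",
    "read_xml",
]

HOUR_MS = 3_600_000

#: variables that are physical state, not pollutant concentrations
NON_SPECIES_VARS = ("temperature", "pressure")


@dataclass
class GriddedField:
    """One variable's surface values on a regular grid over hourly steps.

    ``values`` has shape (H, ny, nx); ``timestamps`` are epoch milliseconds
    at strict hourly spacing.  Concentrations (unit ``ug/m3``) must be
    non-negative and every value finite.
    """

    name: str
    unit: str
    timestamps: np.ndarray
    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"{self.name}: values must be (time, y, x)")
        h, ny, nx = self.values.shape
        if (h, ny, nx) != (len(self.timestamps), self.grid.ny, self.grid.nx):
            raise ValueError(
                f"{self.name}: shape {self.values.shape} does not match "
                f"H={len(self.timestamps)}, ny={self.grid.ny}, nx={self.grid.nx}"
            )
        _check_time_axis(self.timestamps)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.name}: non-finite values")
        if self.unit == "ug/m3" and self.values.min() < 0:
            raise ValueError(f"{self.name}: negative concentration values")

    @property
    def n_hours(self) -> int:
        return len(self.timestamps)


def _check_time_axis(ts: np.ndarray) -> None:
    if len(ts) > 1:
        d = np.diff(ts)
        if not np.all(d > 0):
            raise ValueError("time axis is not strictly increasing")
        if not np.all(d == HOUR_MS):
            raise ValueError("time axis is not hourly (expected 3600000 ms steps)")


@dataclass
class ForecastTable:
    """One row per (municipality, timestamp): S concentrations + T + P.

    Column order is fixed: municipality, timestamp, the S species in the
    given order, temperature, pressure.  (municipality, timestamp) pairs
    are unique.
    """

    df: pd.DataFrame
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = self.columns()
        if list(self.df.columns) != expected:
            raise ValueError(f"columns must be {expected}, got {list(self.df.columns)}")
        if self.df.duplicated(subset=["municipality", "timestamp"]).any():
            raise ValueError("duplicate (municipality, timestamp) rows")

    def columns(self) -> list[str]:
        return ["municipality", "timestamp", *self.species, "temperature", "pressure"]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def municipalities(self) -> list[str]:
        return list(dict.fromkeys(self.df["municipality"]))

    @property
    def timestamps(self) -> list[int]:
        return sorted(set(int(t) for t in self.df["timestamp"]))

    def value(self, municipality: str, timestamp: int, column: str) -> float:
        sel = self.df[
            (self.df["municipality"] == municipality)
            & (self.df["timestamp"] == timestamp)
        ]
        if sel.empty:
            raise KeyError((municipality, timestamp))
        return float(sel.iloc[0][column])

    def equals(self, other: "ForecastTable") -> bool:
        return self.species == other.species and self.df.reset_index(drop=True).equals(
            other.df.reset_index(drop=True)
        )


# ---------------------------------------------------------------------------
# netCDF reading


def read_ctm_netcdf(path, species_map=None, level_index: int = 0) -> list[GriddedField]:
    """Read CTM netCDF output, reducing to one (surface) level.

    Parameters
    ----------
    path
        netCDF file with dimensions (time, level, y, x) and one variable
        per species; classic netCDF-3 and netCDF-4 both work.
    species_map
        Either a list of variable names to read, or a dict mapping file
        variable names to canonical names.  ``None`` reads every data
        variable under its own name.  Variables not listed are ignored.
    level_index
        Index along the level dimension to keep (0 = surface).
    """
    ds = xr.open_dataset(path)
    try:
        available = list(ds.data_vars)
        if species_map is None:
            species_map = {v: v for v in available}
        elif not isinstance(species_map, dict):
            species_map = {v: v for v in species_map}
        missing = [v for v in species_map if v not in available]
        if missing:
            raise KeyError(
                f"variables {missing} not in file; available: {sorted(available)}"
            )

        ts = np.asarray(ds["time"].values)
        if np.issubdtype(ts.dtype, np.datetime64):
            ts = ts.astype("datetime64[ms]").astype(np.int64)
        else:
            ts = np.round(ts).astype(np.int64)  # epoch ms stored as float
        _check_time_axis(ts)

        grid = _grid_from_dataset(ds)
        fields = []
        for var, canonical in species_map.items():
            da = ds[var]
            if "level" in da.dims:
                if not 0 <= level_index < da.sizes["level"]:
                    raise IndexError(
                        f"level_index {level_index} out of range "
                        f"(file has {da.sizes['level']} levels)"
                    )
                da = da.isel(level=level_index)
            unit = da.attrs.get("units")
            if unit is None:
                warnings.warn(f"variable {var!r} has no units attribute")
                unit = ""
            fields.append(
                GriddedField(
                    name=canonical,
                    unit=unit,
                    timestamps=ts,
                    grid=grid,
                    values=np.asarray(da.transpose("time", "y", "x").values, dtype=float),
                )
            )
        return fields
    finally:
        ds.close()


def _grid_from_dataset(ds: xr.Dataset) -> Grid:
    attrs = ds.attrs
    if all(k in attrs for k in ("x0", "y0", "cell_size")):
        return Grid(
            x0=float(attrs["x0"]),
            y0=float(attrs["y0"]),
            cell_size=float(attrs["cell_size"]),
            nx=ds.sizes["x"],
            ny=ds.sizes["y"],
        )
    if "x" in ds.coords and ds.sizes["x"] > 1:
        # cell-centre coordinates: infer spacing and origin
        x = np.asarray(ds["x"].values, dtype=float)
        y = np.asarray(ds["y"].values, dtype=float)
        cs = float(x[1] - x[0])
        return Grid(x0=float(x[0] - cs / 2), y0=float(y[0] - cs / 2),
                    cell_size=cs, nx=ds.sizes["x"], ny=ds.sizes["y"])
    warnings.warn("no grid metadata in file; assuming unit origin and 1 m cells")
    return Grid(x0=0.0, y0=0.0, cell_size=1.0, nx=ds.sizes["x"], ny=ds.sizes["y"])


# ---------------------------------------------------------------------------
# tabular intermediate


def build_forecast_table(
    fields: list[GriddedField], municipalities: MunicipalitySet
) -> ForecastTable:
    """Aggregate gridded fields to one row per (municipality, timestamp).

    Each value is the exact area-weighted mean over the municipality
    polygon.  Fields named ``temperature``/``pressure`` fill those columns;
    every other field is a species column.  Row count is H x M, ordered
    timestamp-major.
    """
    if not fields:
        raise ValueError("no fields given")
    grid = fields[0].grid
    ts = fields[0].timestamps
    for f in fields[1:]:
        if f.grid != grid:
            raise ValueError(f"field {f.name!r} is on a different grid")
        if not np.array_equal(f.timestamps, ts):
            raise ValueError(f"field {f.name!r} has a different time axis")

    weights = overlap_weights(grid, municipalities)
    for m in municipalities:
        if not weights.weights[m.name]:
            raise ValueError(f"municipality {m.name!r} lies wholly outside the grid")

    species = [f.name for f in fields if f.name not in NON_SPECIES_VARS]
    by_name = {f.name: f for f in fields}

    names = municipalities.names
    h = len(ts)
    # per field, an (H, M) matrix of aggregated values
    agg: dict[str, np.ndarray] = {}
    for f in fields:
        flat = f.values.reshape(h, -1)
        cols = np.empty((h, len(names)))
        for j, name in enumerate(names):
            entries = weights.weights[name]
            idx = np.fromiter((i for i, _ in entries), dtype=np.intp, count=len(entries))
            w = np.fromiter((a for _, a in entries), dtype=float, count=len(entries))
            cols[:, j] = flat[:, idx] @ (w / w.sum())
        agg[f.name] = cols

    rows = {
        "municipality": np.tile(names, h),
        "timestamp": np.repeat(ts, len(names)),
    }
    for s in species:
        rows[s] = agg[s].ravel()
    for extra in NON_SPECIES_VARS:
        if extra not in by_name:
            raise ValueError(f"missing required field {extra!r}")
        rows[extra] = agg[extra].ravel()
    df = pd.DataFrame(rows)
    df["timestamp"] = df["timestamp"].astype(np.int64)
    return ForecastTable(df=df, species=species)


# ---------------------------------------------------------------------------
# CSV


def write_csv(table: ForecastTable, path) -> None:
    """One header line plus one line per row, in the fixed dialect."""
    table.df.to_csv(path, index=False)


def read_csv(path) -> ForecastTable:
    """Read a table written by :func:`write_csv`; lossless round trip.

    Malformed rows raise ``ValueError`` carrying the 1-based line number.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV: {exc}") from exc
    cols = list(df.columns)
    if cols[:2] != ["municipality", "timestamp"] or cols[-2:] != ["temperature", "pressure"]:
        raise ValueError(
            "header must be municipality,timestamp,<species...>,temperature,pressure"
        )
    species = cols[2:-2]
    out = {"municipality": df["municipality"].astype(str)}
    for col, dtype in [("timestamp", np.int64)] + [(c, float) for c in species + ["temperature", "pressure"]]:
        try:
            out[col] = df[col].astype(dtype)
        except ValueError as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(f"malformed value in column {col!r} at line {line}") from exc
    return ForecastTable(df=pd.DataFrame(out, columns=cols), species=species)


# ---------------------------------------------------------------------------
# XML + XSD


def _fmt(v: float) -> str:
    return repr(float(v))


def write_xml(table: ForecastTable, xml_path, xsd_path=None) -> tuple[str, str]:
    """Emit one ``<forecast>`` element per row plus a validating XSD.

    Returns the two paths (XSD defaults to the XML path with ``.xsd``).
    Element names follow the CSV header; numeric content uses shortest
    round-trip reprs so parsing recovers the table exactly.
    """
    xsd_path = xsd_path or str(xml_path).rsplit(".", 1)[0] + ".xsd"
    root = etree.Element("forecasts")
    for row in table.df.itertuples(index=False):
        rec = dict(zip(table.columns(), row))
        el = etree.SubElement(root, "forecast")
        etree.SubElement(el, "municipality").text = str(rec["municipality"])
        etree.SubElement(el, "timestamp").text = str(int(rec["timestamp"]))
        for s in table.species:
            etree.SubElement(el, s).text = _fmt(rec[s])
        etree.SubElement(el, "temperature").text = _fmt(rec["temperature"])
        etree.SubElement(el, "pressure").text = _fmt(rec["pressure"])
    etree.ElementTree(root).write(
        str(xml_path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
    _write_xsd(table.species, xsd_path)
    return str(xml_path), str(xsd_path)


def _write_xsd(species: list[str], xsd_path) -> None:
    xs = "http://www.w3.org/2001/XMLSchema"
    schema = etree.Element(f"{{{xs}}}schema", nsmap={"xs": xs})
    top = etree.SubElement(schema, f"{{{xs}}}element", name="forecasts")
    ct = etree.SubElement(top, f"{{{xs}}}complexType")
    seq = etree.SubElement(ct, f"{{{xs}}}sequence")
    fc = etree.SubElement(
        seq, f"{{{xs}}}element", name="forecast", minOccurs="0", maxOccurs="unbounded"
    )
    fct = etree.SubElement(fc, f"{{{xs}}}complexType")
    fseq = etree.SubElement(fct, f"{{{xs}}}sequence")
    etree.SubElement(fseq, f"{{{xs}}}element", name="municipality", type="xs:string")
    etree.SubElement(fseq, f"{{{xs}}}element", name="timestamp", type="xs:long")
    for s in species:
        etree.SubElement(fseq, f"{{{xs}}}element", name=s, type="xs:double")
    etree.SubElement(fseq, f"{{{xs}}}element", name="temperature", type="xs:double")
    etree.SubElement(fseq, f"{{{xs}}}element", name="pressure", type="xs:double")
    etree.ElementTree(schema).write(
        str(xsd_path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def read_xml(xml_path) -> ForecastTable:
    """Parse an XML document written by :func:`write_xml` back to a table."""
    tree = etree.parse(str(xml_path))
    root = tree.getroot()
    recs = []
    species: list[str] = []
    for el in root.iter("forecast"):
        rec = {child.tag: child.text for child in el}
        if not species:
            species = [t for t in rec if t not in ("municipality", "timestamp", *NON_SPECIES_VARS)]
        recs.append(rec)
    cols = ["municipality", "timestamp", *species, "temperature", "pressure"]
    if not recs:
        raise ValueError("no forecast elements in document")
    df = pd.DataFrame(recs, columns=cols)
    df["timestamp"] = df["timestamp"].astype(np.int64)
    for c in species + ["temperature", "pressure"]:
        df[c] = df[c].astype(float)
    return ForecastTable(df=df, species=species)


def validate_xml(xml_path, xsd_path) -> bool:
    """True iff the XML document validates against the XSD schema."""
    schema = etree.XMLSchema(etree.parse(str(xsd_path)))
    return schema.validate(etree.parse(str(xml_path)))
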