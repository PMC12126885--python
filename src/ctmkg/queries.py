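"""Competency questions over the knowledge graph.

Four question families probe whether the graph can answer the queries an
air-quality stakeholder actually asks:

* the concentration **time series** of one pollutant in one municipality;
* the **spatial snapshot** of one pollutant over all municipalities at one
  timestamp (choropleth-ready);
* the number of **superations** -- timestamps at which a pollutant reaches
  or exceeds a threshold (default thresholds: 10 ug/m3 for PM10 and NO2,
  5 ug/m3 for PM2.5);
* the **EU Air Quality Index**: each of PM2.5, PM10, NO2, O3 and SO2 is
  banded (Good .. Extremely Poor) and the index is the most severe band.

Band intervals are left-closed/right-open [lower, upper): a value on a
shared boundary takes the more severe band; values at or above the top
upper bound are Extremely Poor.  All operations are graph traversals; the
equivalent SPARQL 1.1 text ships in ``ctmkg/sparql/``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from rdflib import RDF

from .mapping import KnowledgeGraph

__all__ = [
    "AQI_LABELS",
    "AQIBandTable",
    "ThresholdTable",
    "DEFAULT_AQI_TABLE",
    "DEFAULT_THRESHOLDS",
    "aqi_band",
    "aqi_from_values",
    "time_series",
    "spatial_snapshot",
    "count_superations",
    "aqi_index",
    "aqi_distribution",
]

AQI_LABELS = ["Good", "Fair", "Moderate", "Poor", "Very Poor", "Extremely Poor"]

#: EU index band upper bounds per pollutant, ug/m3 (lower bound of band k is
#: the upper bound of band k-1, starting at 0)
_BAND_UPPERS = {
    "PM2.5": [10.0, 20.0, 25.0, 50.0, 75.0, 800.0],
    "PM10": [20.0, 40.0, 50.0, 100.0, 150.0, 1200.0],
    "NO2": [40.0, 90.0, 120.0, 230.0, 340.0, 1000.0],
    "O3": [50.0, 100.0, 130.0, 240.0, 380.0, 800.0],
    "SO2": [100.0, 200.0, 350.0, 500.0, 750.0, 1200.0],
}


@dataclass
class AQIBandTable:
    """Contiguous severity bands per pollutant: label k covers
    [upper[k-1], upper[k]), with band 0 starting at 0."""

    uppers: dict[str, list[float]] = field(default_factory=lambda: {
        k: list(v) for k, v in _BAND_UPPERS.items()
    })
    labels: list[str] = field(default_factory=lambda: list(AQI_LABELS))

    def __post_init__(self) -> None:
        for pol, ups in self.uppers.items():
            if len(ups) != len(self.labels):
                raise ValueError(f"{pol}: need one upper bound per label")
            if any(b >= a for b, a in zip(ups, ups[1:])) or ups[0] <= 0:
                raise ValueError(f"{pol}: band bounds must be positive and increasing")

    @property
    def pollutants(self) -> list[str]:
        return list(self.uppers)

    def bounds(self, pollutant: str) -> list[tuple[float, float, str]]:
        """(lower, upper, label) triples, starting at 0."""
        ups = self.uppers[pollutant]
        lowers = [0.0] + ups[:-1]
        return list(zip(lowers, ups, self.labels))


DEFAULT_AQI_TABLE = AQIBandTable()


@dataclass
class ThresholdTable:
    """Superation thresholds per species, ug/m3."""

    thresholds: dict[str, float] = field(
        default_factory=lambda: {"PM10": 10.0, "NO2": 10.0, "PM2.5": 5.0}
    )

    def __post_init__(self) -> None:
        for sp, t in self.thresholds.items():
            if t <= 0:
                raise ValueError(f"threshold for {sp!r} must be > 0")


DEFAULT_THRESHOLDS = ThresholdTable()


def aqi_band(species: str, value: float, table: AQIBandTable = DEFAULT_AQI_TABLE) -> str:
    """Band label for one pollutant value; [lower, upper) intervals."""
    if species not in table.uppers:
        raise KeyError(
            f"{species!r} is not an index pollutant (one of {table.pollutants})"
        )
    if value < 0:
        raise ValueError("concentration must be >= 0")
    for upper, label in zip(table.uppers[species], table.labels):
        if value < upper:
            return label
    return table.labels[-1]


def aqi_from_values(values: dict, table: AQIBandTable = DEFAULT_AQI_TABLE) -> str:
    """Most severe band over the five index pollutants.

    ``values`` maps species to concentration; a missing index pollutant
    raises ``KeyError`` naming it.
    """
    missing = [p for p in table.pollutants if p not in values]
    if missing:
        raise KeyError(f"missing index pollutants: {missing}")
    worst = 0
    for p in table.pollutants:
        worst = max(worst, table.labels.index(aqi_band(p, float(values[p]), table)))
    return table.labels[worst]


# ---------------------------------------------------------------------------
# graph traversal helpers


def _concentration_values(kg: KnowledgeGraph):
    """Yield (municipality, timestamp, species, value) for every
    concentration in the graph."""
    ont = kg.ontology
    g = kg.graph
    mun_p = ont.property_iri("hasMunicipality")
    ts_p = ont.property_iri("hasTimestamp")
    conc_p = ont.property_iri("hasConcentration")
    chem_p = ont.property_iri("hasChemicalEntity")
    val_p = ont.property_iri("hasValue")
    base = ont.base_iri
    from urllib.parse import unquote

    for f in g.subjects(RDF.type, ont.class_iri("AirQualityForecast")):
        mun = g.value(f, mun_p)
        ts = g.value(f, ts_p)
        if mun is None or ts is None:
            continue
        for conc in g.objects(f, conc_p):
            chem = g.value(conc, chem_p)
            val = g.value(conc, val_p)
            if chem is None or val is None:
                continue
            ctype = g.value(chem, RDF.type)
            if ctype is None or not str(ctype).startswith(base):
                continue
            species = unquote(str(ctype)[len(base):])
            yield str(mun), int(ts), species, float(val)


def time_series(kg: KnowledgeGraph, municipality: str, species: str) -> list[tuple[int, float]]:
    """(timestamp, value) pairs sorted by time; empty + warning if the
    municipality or species is absent."""
    out = [
        (ts, v)
        for mun, ts, sp, v in _concentration_values(kg)
        if mun == municipality and sp == species
    ]
    if not out:
        warnings.warn(f"no data for municipality={municipality!r}, species={species!r}")
    return sorted(out)


def spatial_snapshot(kg: KnowledgeGraph, timestamp: int, species: str) -> dict[str, float]:
    """municipality -> value at one timestamp; empty + warning if absent."""
    out = {
        mun: v
        for mun, ts, sp, v in _concentration_values(kg)
        if ts == int(timestamp) and sp == species
    }
    if not out:
        warnings.warn(f"no data for timestamp={timestamp}, species={species!r}")
    return out


def count_superations(
    kg: KnowledgeGraph,
    municipality: str,
    window: tuple[int, int] | None = None,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
) -> dict[str, int]:
    """Timestamps at which each thresholded species reaches or exceeds its
    threshold (comparator >=), within the inclusive window [t0, t1]."""
    counts = {sp: 0 for sp in thresholds.thresholds}
    for mun, ts, sp, v in _concentration_values(kg):
        if mun != municipality or sp not in counts:
            continue
        if window is not None and not (window[0] <= ts <= window[1]):
            continue
        if v >= thresholds.thresholds[sp]:
            counts[sp] += 1
    return counts


def _pollutant_vector(kg: KnowledgeGraph, municipality: str, timestamp: int,
                      table: AQIBandTable) -> dict[str, float]:
    vec = {
        sp: v
        for mun, ts, sp, v in _concentration_values(kg)
        if mun == municipality and ts == int(timestamp) and sp in table.uppers
    }
    missing = [p for p in table.pollutants if p not in vec]
    if missing:
        raise KeyError(
            f"missing index pollutants {missing} for {municipality!r} at {timestamp}"
        )
    return vec


def aqi_index(kg: KnowledgeGraph, municipality: str, timestamp: int,
              table: AQIBandTable = DEFAULT_AQI_TABLE) -> str:
    """EU index at one (municipality, timestamp): worst band over the five
    pollutants; missing pollutants raise ``KeyError`` listing them."""
    return aqi_from_values(_pollutant_vector(kg, municipality, timestamp, table), table)


def aqi_distribution(kg: KnowledgeGraph, municipality: str,
                     window: tuple[int, int] | None = None,
                     table: AQIBandTable = DEFAULT_AQI_TABLE) -> dict[str, float]:
    """Percentage of timestamps in each band over the window (inclusive).

    Percentages sum to 100; an empty window raises ``ValueError``.
    """
    by_ts: dict[int, dict[str, float]] = {}
    for mun, ts, sp, v in _concentration_values(kg):
        if mun != municipality or sp not in table.uppers:
            continue
        if window is not None and not (window[0] <= ts <= window[1]):
            continue
        by_ts.setdefault(ts, {})[sp] = v
    if not by_ts:
        raise ValueError(f"no timestamps for {municipality!r} in window {window}")
    counts = {label: 0 for label in table.labels}
    for ts in sorted(by_ts):
        counts[aqi_from_values(by_ts[ts], table)] += 1
    n = sum(counts.values())
    return {label: 100.0 * c / n for label, c in counts.items()}
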