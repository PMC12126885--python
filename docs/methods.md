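# Methods

This note documents the models, conventions and design choices behind
`ctmkg`, in the order data flows through the package.

## Synthetic surface forecasts

The generator emulates the surface level of an hourly chemistry-transport
model run on a planar gridded domain.  For each species

    value[t, y, x] = max(0, baseline + amplitude * sin(2*pi*t/24) + e[t, y, x])

where `e` is stationary AR(1) noise in time per cell with marginal
standard deviation `noise_sd` (default 2 µg/m³) and lag-1 autocorrelation
`ar1_rho` (default 0.7; hourly pollutant series are strongly
persistent).  Innovations mix a domain-wide component with per-cell noise
in equal variance shares, so whole-map fluctuations co-occur with local
ones, and a fixed smooth spatial gradient of magnitude `noise_sd` keeps
snapshots spatially non-trivial.  In the noise-free limit every value is
exactly the baseline plus the diurnal term, which pins the generator's
contract in tests.

Defaults are typical rural-Mediterranean ambient magnitudes in µg/m³
(NO₂ 18, NO 8, O₃ 55, SO₂ 4, CH₄ 1300, NH₃ 6, CO 250, PM10 22, PM2.5 11 —
CH₄ and CO are large because they are mass concentrations, not mixing
ratios), 288.15 K with a 5 K diurnal amplitude for temperature, and
101 325 Pa for pressure.  The default run length is 73 hourly steps —
a 72-hour forecast horizon plus its initial hour — over 45
municipalities and 9 species, the scale of the regional use case the
package targets.

Two deliberate simplifications relative to real CTM output: a single
vertical level (surface only) and no chemistry — species are independent
stochastic processes.  Passing tests therefore demonstrate correctness of
the *pipeline* (aggregation, mapping, queries), not realism of
inter-species correlations or vertical structure.

**Domain.**  The default grid is 15 × 15 cells of 1 km, i.e. a 15 × 15 km
domain; both cell count and cell size are configurable.  Coordinates are
planar metres: real-world GeoJSON in lon/lat must be projected to a
metric CRS by the user before use, which avoids geodesic-area code
entirely.  Municipalities are a seeded Voronoi tessellation of uniform
random points clipped to the domain rectangle — an exact partition
(areas sum to the domain area; pairwise overlaps are degenerate), so the
aggregation conservation identity is testable.

**Time.**  Timestamps are epoch milliseconds at strict hourly spacing,
stored in netCDF as float64 (exact for integers below 2⁵³; millisecond
epochs are ~1.7·10¹²).  Classic netCDF-3 (scipy backend) is written, so
any netCDF implementation can read the files; the epoch-millisecond
convention removes calendar-dialect ambiguity.  The default start is
1703570400000 (2023-12-26 06:00 UTC).

## Zonal aggregation

Cell weights are exact polygon–rectangle intersection areas, not
cell-centre sampling.  Consequences: (i) cells partially overlapping a
municipality contribute fractionally — the weighted mean is bounded by
the contributing cells' min and max, and is linear in the field; (ii) on
a partition the municipality means reconstruct the grid mean exactly
(to 1e-9 relative, the accumulation error of the dot products);
(iii) municipalities smaller than one cell are handled naturally.  A
municipality disjoint from the grid yields an empty weight list; the
table builder treats that as an error naming the municipality.

## Ontology

The class model: a `Simulation` is composed of `AirQualityForecast`
instances (one per municipality-hour); a forecast holds `Concentration`
instances, each linked to **exactly one** `ChemicalEntity`, plus exactly
one `Temperature` and one `Pressure`, and can be linked to an inferred
`AirQualityIndex`.  Chemical species are grouped as inorganic gases
(NO₂, NO, SO₂, NH₃, CO), elemental molecular entities (O₃), organic
entities (CH₄) and nanoparticles, with PM2.5 ⊂ PM10 (mass below 2.5 µm
is also below 10 µm), so PM10's census is twice the per-species count.

`hasMunicipality` and `hasTimestamp` are *data* properties (string and
decimal literals): the consistency queries filter on literal values, and
modelling them as object properties would complicate exactly the queries
the graph exists to answer.  The Simulation→forecast link is named
`hasForecast` (the link's existence is fixed by the model; its name is an
implementation choice).  External vocabulary alignments (ChEBI, ENVO,
PATO identifiers) are configuration, emitted as `hasDbXref` annotations;
none are hard-coded.  Serialization is OWL in Turtle or RDF/XML via
rdflib, with exact cardinalities as `owl:Restriction` nodes;
`parse_ontology` round-trips the structure.

## Mapping engine

Rules are declarative and compiled against the ontology before any row is
processed: unknown classes/properties, missing columns and domain/range
mismatches fail fast; exact-cardinality overflows abort generation with
no graph emitted.  IRIs are deterministic:
`base/{kind}/{municipality}/{timestamp}[/{species}]` with percent-encoded
keys, so identical inputs give identical triple sets and distinct rows
give distinct IRIs.

Identity rules are key projections for IRI minting: declaring
`(chemical, [species])` makes all rows share one chemical-entity
individual per species.  The **default rule set uses no identity rules**:
chemical-entity individuals are minted per forecast, which is what makes
the per-species census equal the forecast count (2S+3 = 21 individuals
per row for S=9).  Materializing the air-quality index adds a 22nd
individual per row behind an opt-in flag.

The census counts individuals under subclass closure (a PM2.5 individual
is a PM10, Nanoparticle and ChemicalEntity member).  Absolute
individual/triple totals depend on serialization and modelling choices,
so the package reports them but the tested contract is the per-class
closed forms: `|AirQualityForecast| = H·M`, `|Concentration| =
|ChemicalEntity| = S·H·M`, each leaf species `H·M`, `|PM10| = 2·H·M`.

**Canonical Turtle.**  The Turtle writer emits one sorted N-Triples line
per triple (valid Turtle).  This trades file size for a guarantee:
identical graphs produce byte-identical files, which makes end-to-end
determinism testable.  RDF/XML output delegates to rdflib.

## Consistency checking

"Spatial" = per-timestamp municipality completeness; "temporal" =
per-municipality timestamp completeness.  Checks return reports (never
raise), are pure, and are also shipped as SPARQL files whose results are
tested equal to the traversal path.  The structural check approximates a
description-logic consistency test structurally: typing, exact-1
multiplicity (including *absent* required links), domain/range
conformance and literal datatypes.  A documented six-mutation suite
(dropped forecast, duplicated timestamp, orphan concentration, double
chemical entity, wrong datatype, unknown municipality) is caught by at
least one check each.

## Competency queries

Band intervals of the EU index table are left-closed/right-open
[lower, upper): a value on a shared boundary (e.g. PM2.5 = 10 µg/m³)
takes the more severe band; values at or above the top bound are
Extremely Poor.  This convention is configurable via `AQIBandTable`.  The
superation comparator is ≥ ("reaches or exceeds").  The index uses
hourly values, matching the per-timestamp structure of the graph;
regulatory indices computed on 24-h means would need a resampling step
that is out of scope.  CO, CH₄, NO and NH₃ are not index pollutants and
are ignored by the AQI.  Superation windows are inclusive on both ends.

## Ontology metrics

Nineteen structural metrics; exact formulas in
`docs/oquare_metrics.md`.  `CROnto` is 0 for the shipped ontology because
the template ontology is unpopulated by design (individuals live in the
generated graphs).  Published score ranges for a comparable ontology are
reported informatively in the test suite but never asserted: this
reconstruction has a slightly shallower chemical hierarchy (depth 4)
than an ontology importing external ancestry.

## Benchmark

Hour counts double from 1 to 2^e (default e = 7, i.e. up to 128 h);
for each, the fixture is regenerated, converted and serialized, and
counts/bytes/wall time recorded (`reps` = 5 repetitions by default; the
counts are deterministic so only timing benefits from repetition).
Three OLS fits are reported; only the hardware-independent
bytes~individuals fit (R² ≥ 0.999) is part of the tested contract, and
the individual count is asserted to follow `(2S+3)·h·M` exactly.  The
benchmark exposes the municipality count as a parameter since scaling
behaviour in the number of spatial units is of independent interest.

## Degenerate inputs and numerical conventions

* Aggregation tolerances: conservation and round-trip identities hold to
  1e-9 relative; Monte-Carlo area cross-checks use 10⁶ points at 0.5%.
* CSV and XML use shortest round-trip float reprs, so table → file →
  table is lossless bit-for-bit.
* An empty forecast table yields an empty graph and an all-zero census;
  a one-cell domain, a single municipality and a single hour are all
  valid limits exercised in tests.
* Concentrations are clipped at zero at generation; the reader rejects
  negative concentrations, non-finite values and non-hourly or
  non-monotone time axes.

## Known limitations

Single vertical level; no inter-species correlation in the generator;
no ppb↔µg/m³ conversion (inputs are assumed in mass units); no reasoner
integration (the structural check is deliberately weaker than OWL-DL
satisfiability); no SPARQL endpoint or triple-store loading — the
shipped SPARQL files target any external SPARQL 1.1 service.
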