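"""ctmkg: chemistry-transport-model output as ontology-backed knowledge graphs.

Pipeline: synthetic or real netCDF surface forecasts -> per-municipality
forecast table (exact area-weighted zonal means) -> CSV/XML intermediates
-> rule-based RDF knowledge graph under the simulation ontology ->
consistency checks, competency queries (time series, snapshots,
superations, EU Air Quality Index), ontology quality metrics and a
scalability benchmark.
"""

from importlib import resources

from .grid import Grid
from .synthetic import (
    DEFAULT_SPECIES,
    DomainSpec,
    FieldSpec,
    make_default_fixture,
    make_municipalities,
    simulate_fields,
    write_ctm_netcdf,
)
from .ingest import (
    ForecastTable,
    GriddedField,
    build_forecast_table,
    read_csv,
    read_ctm_netcdf,
    read_xml,
    write_csv,
    write_xml,
)
from .spatial import (
    Municipality,
    MunicipalitySet,
    OverlapWeights,
    area_weighted_mean,
    overlap_weights,
)
from .ontology import (
    OntologyModel,
    build_ontology,
    parse_ontology,
    serialize_ontology,
)
from .mapping import (
    KnowledgeGraph,
    MappingRuleSet,
    default_ruleset,
    generate_graph,
    kg_from_graph,
    mint_iri,
    read_graph,
    serialize_graph,
    write_graph,
)
from .validation import (
    ConsistencyReport,
    cardinality_audit,
    expected_census,
    full_audit,
    spatial_consistency,
    structural_consistency,
    temporal_consistency,
)
from .queries import (
    AQIBandTable,
    ThresholdTable,
    aqi_band,
    aqi_distribution,
    aqi_from_values,
    aqi_index,
    count_superations,
    spatial_snapshot,
    time_series,
)
from .metrics import MetricReport, compute_metrics
from .bench import BenchResult, fit_line, run_benchmark

__version__ = "0.1.0"


def load_sparql(name: str) -> str:
    """Return the text of a shipped SPARQL query (e.g. ``"q1_spatial_consistency"``)."""
    fname = name if name.endswith(".rq") else name + ".rq"
    return (resources.files("ctmkg") / "sparql" / fname).read_text(encoding="utf-8")
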