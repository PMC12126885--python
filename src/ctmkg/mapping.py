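"""Declarative mapping engine: forecast table -> ontology-conformant RDF.

The engine applies a rule set to each table row and appends the minted
triples to a growing graph, the standard shape of ontology-driven
tabular-to-RDF integration tools:

* **entity rules** mint typed individuals (one forecast, one concentration
  and one chemical-entity individual per species, one temperature, one
  pressure per row -- 2S+3 individuals for S species);
* **attribute rules** attach typed literals (municipality as xsd:string,
  timestamp as xsd:decimal epoch milliseconds, values as xsd:double);
* **relation rules** link individuals through the ontology's object
  properties;
* **identity rules** project the minting keys of a kind, so individuals
  sharing the projected keys collapse into one (the default rule set uses
  none: chemical-entity individuals are deliberately minted per forecast).

Ontology constraints are enforced during generation: unknown classes or
properties, columns missing from the table, domain/range violations and
exact-cardinality overflows abort the run with no graph emitted.

IRIs are deterministic functions of the rule keys
(``base/{kind}/{key1}/{key2}[...]`` with percent-encoded keys), so the
same table always yields the identical triple set, and the canonical
Turtle writer (sorted N-Triples lines, which are valid Turtle) yields
byte-identical files for identical graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable
from urllib.parse import quote

from rdflib import Graph, Literal, RDF, URIRef
from rdflib.namespace import XSD

from .ingest import ForecastTable
from .ontology import OntologyModel

__all__ = [
    "EntityRule",
    "AttributeRule",
    "RelationRule",
    "IdentityRule",
    "MappingRuleSet",
    "KnowledgeGraph",
    "default_ruleset",
    "generate_graph",
    "mint_iri",
    "serialize_graph",
    "kg_from_graph",
    "write_graph",
    "read_graph",
    "DEFAULT_DATA_BASE",
]

DEFAULT_DATA_BASE = "https://purl.org/chimere-kg/"

#: placeholder resolving to the current species name / value column
SPECIES = "@species"


@dataclass(frozen=True)
class EntityRule:
    """Mint one individual of ``ontology_class`` per row (or per species)."""

    kind: str
    ontology_class: str  # class name, or "@species" for the species' own class
    per: str = "row"  # "row" | "species"


@dataclass(frozen=True)
class AttributeRule:
    """Attach a typed literal from a source column to a minted individual."""

    target_kind: str
    column: str  # column name, or "@species" for the species value column
    data_property: str
    datatype: str  # xsd local name: string | decimal | double


@dataclass(frozen=True)
class RelationRule:
    """Link two minted individuals through an object property."""

    subject_kind: str
    object_property: str
    object_kind: str
    per: str = "row"


@dataclass(frozen=True)
class IdentityRule:
    """Keys under which individuals of a kind are considered identical.

    Fields may be "municipality", "timestamp", "species".  Projecting the
    minting keys onto these fields makes equal-key individuals share one
    IRI, i.e. merge.
    """

    kind: str
    key_fields: tuple[str, ...]


@dataclass
class MappingRuleSet:
    entity_rules: list[EntityRule] = dc_field(default_factory=list)
    attribute_rules: list[AttributeRule] = dc_field(default_factory=list)
    relation_rules: list[RelationRule] = dc_field(default_factory=list)
    identity_rules: list[IdentityRule] = dc_field(default_factory=list)
    #: computed attributes: (target_kind, data_property, datatype, fn(record)->value)
    computed_attributes: list[tuple[str, str, str, Callable]] = dc_field(
        default_factory=list
    )

    def identity_for(self, kind: str) -> tuple[str, ...] | None:
        for r in self.identity_rules:
            if r.kind == kind:
                return r.key_fields
        return None


@dataclass
class KnowledgeGraph:
    """Typed individuals and triples, plus the per-class census."""

    graph: Graph
    ontology: OntologyModel
    base_iri: str = DEFAULT_DATA_BASE
    direct_counts: dict[str, int] = dc_field(default_factory=dict)

    @property
    def n_triples(self) -> int:
        return len(self.graph)

    @property
    def n_individuals(self) -> int:
        return sum(self.direct_counts.values())

    def census(self) -> dict[str, int]:
        """Individuals per class under subclass closure (zero counts kept)."""
        out = {}
        for cls in self.ontology.classes:
            out[cls] = sum(
                self.direct_counts.get(d, 0) for d in self.ontology.descendants(cls)
            )
        return out


def mint_iri(base: str, kind: str, keys: tuple) -> URIRef:
    """Deterministic, collision-free IRI: base/kind/key1/key2[...]."""
    if not keys:
        raise ValueError("mint_iri requires at least one key")
    path = "/".join(quote(str(k), safe="") for k in keys)
    return URIRef(f"{base}{quote(kind, safe='')}/{path}")


def default_ruleset(ontology: OntologyModel, materialize_aqi: bool = False) -> MappingRuleSet:
    """The standard rule set for the forecast-table profile.

    Per row it mints 1 AirQualityForecast, S Concentration, S
    chemical-entity, 1 Temperature and 1 Pressure individuals (2S+3) and
    links them; ``materialize_aqi`` adds one AirQualityIndex individual per
    row (2S+4) carrying the computed index label.
    """
    required = ["AirQualityForecast", "Concentration", "Temperature", "Pressure",
                "ChemicalEntity"]
    if materialize_aqi:
        required.append("AirQualityIndex")
    for cls in required:
        if cls not in ontology.classes:
            raise ValueError(f"ontology is missing required class {cls!r}")

    rs = MappingRuleSet(
        entity_rules=[
            EntityRule("forecast", "AirQualityForecast", per="row"),
            EntityRule("concentration", "Concentration", per="species"),
            EntityRule("chemical", SPECIES, per="species"),
            EntityRule("temperature", "Temperature", per="row"),
            EntityRule("pressure", "Pressure", per="row"),
        ],
        attribute_rules=[
            AttributeRule("forecast", "municipality", "hasMunicipality", "string"),
            AttributeRule("forecast", "timestamp", "hasTimestamp", "decimal"),
            AttributeRule("concentration", SPECIES, "hasValue", "double"),
            AttributeRule("temperature", "temperature", "hasValue", "double"),
            AttributeRule("pressure", "pressure", "hasValue", "double"),
        ],
        relation_rules=[
            RelationRule("forecast", "hasConcentration", "concentration", per="species"),
            RelationRule("concentration", "hasChemicalEntity", "chemical", per="species"),
            RelationRule("forecast", "hasTemperature", "temperature", per="row"),
            RelationRule("forecast", "hasPressure", "pressure", per="row"),
        ],
    )
    if materialize_aqi:
        from .queries import aqi_from_values  # local import avoids a cycle

        def label(record: dict) -> str | None:
            try:
                return aqi_from_values(record)
            except KeyError:
                return None

        rs.entity_rules.append(EntityRule("aqi", "AirQualityIndex", per="row"))
        rs.relation_rules.append(
            RelationRule("forecast", "hasAirQualityIndex", "aqi", per="row")
        )
        rs.computed_attributes.append(("aqi", "hasIndexLabel", "string", label))
    return rs


_XSD = {"string": XSD.string, "decimal": XSD.decimal, "double": XSD.double,
        "integer": XSD.integer}


def _literal(value, datatype: str) -> Literal:
    dt = _XSD.get(datatype)
    if dt is None:
        raise ValueError(f"unsupported datatype {datatype!r}")
    if datatype == "decimal":
        value = int(value)
    elif datatype == "double":
        value = float(value)
    else:
        value = str(value)
    return Literal(value, datatype=dt)


def generate_graph(
    table: ForecastTable,
    rules: MappingRuleSet,
    ontology: OntologyModel,
    base_iri: str = DEFAULT_DATA_BASE,
) -> KnowledgeGraph:
    """Apply the rule set row by row and append triples to one graph.

    Linear in the row count.  An empty table yields an empty graph and an
    all-zero census.
    """
    _compile_check(table, rules, ontology)
    species = table.species

    g = Graph()
    g.bind("", ontology.base_iri)
    direct_counts: dict[str, int] = {}
    minted: set[URIRef] = set()
    # subjects already carrying each exactly-1 object property
    card1_props = {
        op.name: {} for op in ontology.object_properties.values() if op.exactly == 1
    }
    cols = table.columns()

    def keys_for(kind: str, per: str, mun, ts, sp=None) -> tuple:
        fields = rules.identity_for(kind)
        if fields is None:
            return (mun, ts) if per == "row" else (mun, ts, sp)
        pool = {"municipality": mun, "timestamp": ts, "species": sp}
        return tuple(pool[f] for f in fields)

    for row in table.df.itertuples(index=False):
        record = dict(zip(cols, row))
        mun = record["municipality"]
        ts = int(record["timestamp"])
        iris: dict[tuple, URIRef] = {}

        def mint(kind: str, cls: str, per: str, sp) -> URIRef:
            iri = mint_iri(base_iri, kind, keys_for(kind, per, mun, ts, sp))
            if iri not in minted:
                minted.add(iri)
                g.add((iri, RDF.type, ontology.class_iri(cls)))
                direct_counts[cls] = direct_counts.get(cls, 0) + 1
            return iri

        for er in rules.entity_rules:
            if er.per == "row":
                iri = mint(er.kind, er.ontology_class, "row", None)
                iris[(er.kind, None)] = iri
                for sp in species:  # row-level kinds addressable per species too
                    iris[(er.kind, sp)] = iri
            else:
                for sp in species:
                    cls = sp if er.ontology_class == SPECIES else er.ontology_class
                    iris[(er.kind, sp)] = mint(er.kind, cls, "species", sp)

        for ar in rules.attribute_rules:
            if ar.column == SPECIES:
                for sp in species:
                    g.add((iris[(ar.target_kind, sp)],
                           ontology.property_iri(ar.data_property),
                           _literal(record[sp], ar.datatype)))
            else:
                g.add((iris[(ar.target_kind, None)],
                       ontology.property_iri(ar.data_property),
                       _literal(record[ar.column], ar.datatype)))

        for kind, prop, datatype, fn in rules.computed_attributes:
            val = fn(record)
            if val is not None:
                g.add((iris[(kind, None)], ontology.property_iri(prop),
                       _literal(val, datatype)))

        for rr in rules.relation_rules:
            targets = species if rr.per == "species" else [None]
            prop_iri = ontology.property_iri(rr.object_property)
            seen = card1_props.get(rr.object_property)
            for sp in targets:
                s = iris[(rr.subject_kind, sp)]
                o = iris[(rr.object_kind, sp)]
                if seen is not None:
                    prev = seen.get(s)
                    if prev is not None and prev != o:
                        raise ValueError(
                            f"cardinality violation: {s} has two values for "
                            f"exactly-1 property {rr.object_property}"
                        )
                    seen[s] = o
                g.add((s, prop_iri, o))

    return KnowledgeGraph(graph=g, ontology=ontology, base_iri=base_iri,
                          direct_counts=direct_counts)


def _compile_check(table: ForecastTable, rules: MappingRuleSet,
                   ontology: OntologyModel) -> None:
    cols = set(table.columns())
    kinds: dict[str, EntityRule] = {}
    for er in rules.entity_rules:
        if er.ontology_class == SPECIES:
            for sp in table.species:
                if sp not in ontology.classes:
                    raise ValueError(f"species class {sp!r} missing from ontology")
        elif er.ontology_class not in ontology.classes:
            raise ValueError(
                f"entity rule {er.kind!r} references unknown class {er.ontology_class!r}"
            )
        kinds[er.kind] = er
    for ar in rules.attribute_rules:
        if ar.column != SPECIES and ar.column not in cols:
            raise ValueError(
                f"attribute rule {ar.data_property!r} references missing column {ar.column!r}"
            )
        if ar.data_property not in ontology.data_properties:
            raise ValueError(f"unknown data property {ar.data_property!r}")
        if ar.target_kind not in kinds:
            raise ValueError(f"attribute rule targets unknown kind {ar.target_kind!r}")
    for rr in rules.relation_rules:
        op = ontology.object_properties.get(rr.object_property)
        if op is None:
            raise ValueError(f"unknown object property {rr.object_property!r}")
        for k in (rr.subject_kind, rr.object_kind):
            if k not in kinds:
                raise ValueError(f"relation rule references unknown kind {k!r}")
        # domain/range conformance of the kinds' classes
        s_cls = kinds[rr.subject_kind].ontology_class
        o_cls = kinds[rr.object_kind].ontology_class
        s_set = [s_cls] if s_cls != SPECIES else list(table.species)
        o_set = [o_cls] if o_cls != SPECIES else list(table.species)
        for c in s_set:
            if c != op.domain and op.domain not in ontology.ancestors(c):
                raise ValueError(
                    f"domain violation: {c} is not a {op.domain} "
                    f"(property {op.name})"
                )
        for c in o_set:
            if c != op.range and op.range not in ontology.ancestors(c):
                raise ValueError(
                    f"range violation: {c} is not a {op.range} (property {op.name})"
                )


# ---------------------------------------------------------------------------
# serialization


def serialize_graph(kg: KnowledgeGraph, format: str = "turtle") -> bytes:
    """Serialize the graph to bytes.

    ``turtle`` uses a canonical writer -- one sorted N-Triples line per
    triple (valid Turtle) -- so identical graphs give byte-identical
    output.  ``rdf/xml`` delegates to rdflib.
    """
    fmt = format.lower()
    if fmt in ("turtle", "ttl"):
        lines = sorted(
            f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in kg.graph
        )
        return ("\n".join(lines) + "\n").encode("utf-8")
    if fmt in ("xml", "rdf/xml", "rdfxml"):
        return kg.graph.serialize(format="pretty-xml").encode("utf-8")
    raise ValueError(f"unknown format {format!r}; use 'turtle' or 'rdf/xml'")


def kg_from_graph(graph: Graph, ontology: OntologyModel,
                  base_iri: str = DEFAULT_DATA_BASE) -> KnowledgeGraph:
    """Wrap an already-parsed RDF graph, recomputing the census from its
    ``rdf:type`` assertions (used when loading a serialized graph)."""
    from urllib.parse import unquote

    counts: dict[str, int] = {}
    base = ontology.base_iri
    for _, _, o in graph.triples((None, RDF.type, None)):
        if isinstance(o, URIRef) and str(o).startswith(base):
            name = unquote(str(o)[len(base):])
            if name in ontology.classes:
                counts[name] = counts.get(name, 0) + 1
    return KnowledgeGraph(graph=graph, ontology=ontology, base_iri=base_iri,
                          direct_counts=counts)


def write_graph(kg: KnowledgeGraph, path, format: str = "turtle") -> int:
    """Write the graph to a file; returns the byte size written."""
    payload = serialize_graph(kg, format)
    with open(path, "wb") as fh:
        fh.write(payload)
    return len(payload)


def read_graph(path, format: str = "turtle") -> Graph:
    fmt = format.lower()
    if fmt in ("turtle", "ttl"):
        rdflib_fmt = "turtle"
    elif fmt in ("xml", "rdf/xml", "rdfxml"):
        rdflib_fmt = "xml"
    else:
        raise ValueError(f"unknown format {format!r}")
    g = Graph()
    g.parse(str(path), format=rdflib_fmt)
    return g
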