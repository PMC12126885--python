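"""The air-quality simulation ontology: build, serialize, parse, query.

The model captures a chemistry-transport-model simulation as OWL classes:
a ``Simulation`` is composed of ``AirQualityForecast`` instances (one per
municipality and hour), each holding ``Concentration`` instances that are
linked to exactly one ``ChemicalEntity``, plus exactly one ``Temperature``
and one ``Pressure``.  Chemical species sit in a small hierarchy --
inorganic gases (NO2, NO, SO2, NH3, CO), elemental molecular entities
(O3), organic entities (CH4) and nanoparticles, where PM2.5 is a subclass
of PM10 (every PM2.5 particle is also a PM10 particle).

External vocabulary alignments (e.g. ChEBI identifiers) are supplied as a
configuration table and emitted as database cross-reference annotations;
none are hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from urllib.parse import quote, unquote

from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import OWL, XSD

__all__ = [
    "OntClass",
    "ObjectProperty",
    "DataProperty",
    "OntologyModel",
    "build_ontology",
    "serialize_ontology",
    "parse_ontology",
    "DEFAULT_BASE_IRI",
    "CORE_CLASSES",
    "SPECIES_PARENTS",
]

DEFAULT_BASE_IRI = "https://purl.org/chimere-ontology#"

#: the framework classes present even with an empty species list
CORE_CLASSES = (
    "Simulation",
    "AirQualityForecast",
    "AirQualityIndex",
    "Concentration",
    "Temperature",
    "Pressure",
    "ChemicalEntity",
)

#: chemical-hierarchy grouping classes and their parent
GROUP_PARENTS = {
    "ElementalMolecularEntity": "ChemicalEntity",
    "OrganicEntity": "ChemicalEntity",
    "InorganicEntity": "ChemicalEntity",
    "Nanoparticle": "ChemicalEntity",
}

#: default hierarchy assignment of the nine use-case species
SPECIES_PARENTS = {
    "NO2": "InorganicEntity",
    "NO": "InorganicEntity",
    "SO2": "InorganicEntity",
    "NH3": "InorganicEntity",
    "CO": "InorganicEntity",
    "O3": "ElementalMolecularEntity",
    "CH4": "OrganicEntity",
    "PM10": "Nanoparticle",
    "PM2.5": "PM10",
}

THING = "Thing"

OBO_XREF = URIRef("http://www.geneontology.org/formats/oboInOwl#hasDbXref")


@dataclass
class OntClass:
    name: str
    parents: list[str] = field(default_factory=list)  # named parents; [] = root
    label: str | None = None
    comment: str | None = None
    xrefs: list[str] = field(default_factory=list)

    @property
    def annotations(self) -> list[str]:
        out = []
        if self.label:
            out.append(self.label)
        if self.comment:
            out.append(self.comment)
        out.extend(self.xrefs)
        return out


@dataclass
class ObjectProperty:
    name: str
    domain: str
    range: str
    exactly: int | None = None  # exact-cardinality constraint on the domain


@dataclass
class DataProperty:
    name: str
    domains: list[str]
    range: str  # xsd datatype local name, e.g. "decimal"


class OntologyModel:
    """Classes, properties and cardinality constraints of the ontology."""

    def __init__(self, base_iri: str = DEFAULT_BASE_IRI):
        self.base_iri = base_iri
        self.classes: dict[str, OntClass] = {}
        self.object_properties: dict[str, ObjectProperty] = {}
        self.data_properties: dict[str, DataProperty] = {}

    # -- construction -------------------------------------------------------

    def add_class(self, cls: OntClass) -> None:
        self.classes[cls.name] = cls

    # -- structure queries ---------------------------------------------------

    def parents(self, name: str) -> list[str]:
        return list(self.classes[name].parents)

    def children(self, name: str) -> list[str]:
        return [c for c, v in self.classes.items() if name in v.parents]

    def ancestors(self, name: str) -> set[str]:
        """Named ancestors (transitive, excluding the class itself)."""
        out: set[str] = set()
        stack = list(self.classes[name].parents)
        while stack:
            p = stack.pop()
            if p in out or p == THING:
                continue
            out.add(p)
            stack.extend(self.classes[p].parents)
        return out

    def descendants(self, name: str) -> set[str]:
        """Subclass closure including the class itself."""
        out = {name}
        stack = [name]
        while stack:
            c = stack.pop()
            for ch in self.children(c):
                if ch not in out:
                    out.add(ch)
                    stack.append(ch)
        return out

    def leaves(self) -> list[str]:
        return [c for c in self.classes if not self.children(c)]

    def roots(self) -> list[str]:
        return [c for c, v in self.classes.items() if not v.parents]

    def depth(self, name: str) -> int:
        """Longest chain of subclass edges from the class up to Thing."""
        ps = self.classes[name].parents
        if not ps:
            return 1  # direct child of Thing
        return 1 + max(self.depth(p) for p in ps)

    # -- IRIs ----------------------------------------------------------------

    def class_iri(self, name: str) -> URIRef:
        return URIRef(self.base_iri + quote(name, safe=""))

    def property_iri(self, name: str) -> URIRef:
        return URIRef(self.base_iri + quote(name, safe=""))

    # -- integrity -----------------------------------------------------------

    def validate(self) -> None:
        """Raise ``ValueError`` on structural defects.

        Checks: parents exist; the subclass graph is acyclic; property
        domains and ranges name existing classes.
        """
        for c, v in self.classes.items():
            for p in v.parents:
                if p not in self.classes:
                    raise ValueError(f"class {c!r} has unknown parent {p!r}")
        # cycle check via depth-first colouring
        state: dict[str, int] = {}

        def visit(c: str) -> None:
            state[c] = 1
            for p in self.classes[c].parents:
                if state.get(p) == 1:
                    raise ValueError(f"subclass cycle through {p!r}")
                if state.get(p) is None:
                    visit(p)
            state[c] = 2

        for c in self.classes:
            if state.get(c) is None:
                visit(c)
        for op in self.object_properties.values():
            for end in (op.domain, op.range):
                if end not in self.classes:
                    raise ValueError(f"property {op.name!r} references unknown class {end!r}")
        for dp in self.data_properties.values():
            for d in dp.domains:
                if d not in self.classes:
                    raise ValueError(f"property {dp.name!r} references unknown class {d!r}")


def build_ontology(
    species: list[str] | tuple[str, ...] | None = None,
    xrefs: dict[str, list[str]] | None = None,
    base_iri: str = DEFAULT_BASE_IRI,
    species_parents: dict[str, str] | None = None,
) -> OntologyModel:
    """Assemble the ontology for a species list (default: the nine-species
    use case).

    ``xrefs`` maps class names to external vocabulary identifiers (e.g.
    ``{"NO2": ["CHEBI:33101"]}``) emitted as cross-reference annotations.
    A species with no entry in ``species_parents`` raises ``ValueError``.
    """
    if species is None:
        species = list(SPECIES_PARENTS)
    xrefs = xrefs or {}
    parent_map = dict(SPECIES_PARENTS)
    if species_parents:
        parent_map.update(species_parents)

    m = OntologyModel(base_iri=base_iri)

    def add(name: str, parents: list[str], comment: str) -> None:
        m.add_class(
            OntClass(
                name=name,
                parents=parents,
                label=name,
                comment=comment,
                xrefs=list(xrefs.get(name, [])),
            )
        )

    add("Simulation", [], "One run of the chemistry-transport model.")
    add("AirQualityForecast", [],
        "The forecast for one municipality at one timestamp.")
    add("AirQualityIndex", [],
        "Categorical air-quality level inferred from a forecast.")
    add("Concentration", [], "A mass concentration of one chemical entity.")
    add("Temperature", [], "Surface air temperature of a forecast, in kelvin.")
    add("Pressure", [], "Surface air pressure of a forecast, in pascal.")
    add("ChemicalEntity", [], "A chemical species tracked by the model.")

    # grouping classes appear only when a species hangs below them
    needed_groups: set[str] = set()
    for s in species:
        p = parent_map.get(s)
        if p is None:
            raise ValueError(f"species {s!r} has no hierarchy assignment")
        while p in GROUP_PARENTS or p in parent_map:
            if p in GROUP_PARENTS:
                needed_groups.add(p)
                break
            p = parent_map[p]
    for g in sorted(needed_groups):
        add(g, [GROUP_PARENTS[g]], f"{g} grouping of chemical entities.")

    for s in species:
        add(s, [parent_map[s]], f"The chemical species {s}.")
    # a species may parent another (PM2.5 under PM10): ensure parents exist
    for s in species:
        p = parent_map[s]
        if p not in m.classes:
            raise ValueError(f"species {s!r} has parent {p!r} outside the ontology")

    m.object_properties = {
        "hasForecast": ObjectProperty("hasForecast", "Simulation", "AirQualityForecast"),
        "hasConcentration": ObjectProperty(
            "hasConcentration", "AirQualityForecast", "Concentration"
        ),
        "hasChemicalEntity": ObjectProperty(
            "hasChemicalEntity", "Concentration", "ChemicalEntity", exactly=1
        ),
        "hasTemperature": ObjectProperty(
            "hasTemperature", "AirQualityForecast", "Temperature", exactly=1
        ),
        "hasPressure": ObjectProperty(
            "hasPressure", "AirQualityForecast", "Pressure", exactly=1
        ),
        "hasAirQualityIndex": ObjectProperty(
            "hasAirQualityIndex", "AirQualityForecast", "AirQualityIndex"
        ),
    }
    m.data_properties = {
        "hasMunicipality": DataProperty("hasMunicipality", ["AirQualityForecast"], "string"),
        "hasTimestamp": DataProperty("hasTimestamp", ["AirQualityForecast"], "decimal"),
        "hasValue": DataProperty(
            "hasValue", ["Concentration", "Temperature", "Pressure"], "double"
        ),
        "hasIndexLabel": DataProperty("hasIndexLabel", ["AirQualityIndex"], "string"),
    }
    m.validate()
    return m


# ---------------------------------------------------------------------------
# OWL serialization (rdflib)


def to_rdflib_graph(model: OntologyModel) -> Graph:
    g = Graph()
    ns = Namespace(model.base_iri)
    g.bind("", ns)
    g.bind("owl", OWL)
    ont = URIRef(model.base_iri.rstrip("#/"))
    g.add((ont, RDF.type, OWL.Ontology))
    for cls in model.classes.values():
        iri = model.class_iri(cls.name)
        g.add((iri, RDF.type, OWL.Class))
        if cls.parents:
            for p in cls.parents:
                g.add((iri, RDFS.subClassOf, model.class_iri(p)))
        else:
            g.add((iri, RDFS.subClassOf, OWL.Thing))
        if cls.label:
            g.add((iri, RDFS.label, Literal(cls.label)))
        if cls.comment:
            g.add((iri, RDFS.comment, Literal(cls.comment)))
        for x in cls.xrefs:
            g.add((iri, OBO_XREF, Literal(x)))
    for op in model.object_properties.values():
        iri = model.property_iri(op.name)
        g.add((iri, RDF.type, OWL.ObjectProperty))
        g.add((iri, RDFS.domain, model.class_iri(op.domain)))
        g.add((iri, RDFS.range, model.class_iri(op.range)))
        if op.exactly is not None:
            r = BNode()
            g.add((model.class_iri(op.domain), RDFS.subClassOf, r))
            g.add((r, RDF.type, OWL.Restriction))
            g.add((r, OWL.onProperty, iri))
            g.add((r, OWL.cardinality, Literal(op.exactly, datatype=XSD.nonNegativeInteger)))
    for dp in model.data_properties.values():
        iri = model.property_iri(dp.name)
        g.add((iri, RDF.type, OWL.DatatypeProperty))
        for d in dp.domains:
            g.add((iri, RDFS.domain, model.class_iri(d)))
        g.add((iri, RDFS.range, URIRef(str(XSD) + dp.range)))
    return g


_FORMATS = {"turtle": "turtle", "ttl": "turtle", "xml": "pretty-xml",
            "rdf/xml": "pretty-xml", "rdfxml": "pretty-xml"}


def serialize_ontology(model: OntologyModel, format: str = "turtle") -> str:
    """OWL document in Turtle or RDF/XML; unknown format raises."""
    fmt = _FORMATS.get(format.lower())
    if fmt is None:
        raise ValueError(f"unknown format {format!r}; use 'turtle' or 'rdf/xml'")
    return to_rdflib_graph(model).serialize(format=fmt)


def parse_ontology(document: str, format: str = "turtle",
                   base_iri: str = DEFAULT_BASE_IRI) -> OntologyModel:
    """Rebuild an :class:`OntologyModel` from a serialized OWL document."""
    fmt = _FORMATS.get(format.lower())
    if fmt is None:
        raise ValueError(f"unknown format {format!r}; use 'turtle' or 'rdf/xml'")
    g = Graph()
    g.parse(data=document, format="turtle" if fmt == "turtle" else "xml")

    def local(iri: URIRef) -> str:
        return unquote(str(iri)[len(base_iri):])

    m = OntologyModel(base_iri=base_iri)
    for s in g.subjects(RDF.type, OWL.Class):
        if isinstance(s, BNode):
            continue
        name = local(s)
        parents = [
            local(o)
            for o in g.objects(s, RDFS.subClassOf)
            if isinstance(o, URIRef) and o != OWL.Thing
        ]
        labels = list(g.objects(s, RDFS.label))
        comments = list(g.objects(s, RDFS.comment))
        xrefs = [str(o) for o in g.objects(s, OBO_XREF)]
        m.add_class(
            OntClass(
                name=name,
                parents=sorted(parents),
                label=str(labels[0]) if labels else None,
                comment=str(comments[0]) if comments else None,
                xrefs=sorted(xrefs),
            )
        )
    # exact cardinalities from restriction nodes
    exactly: dict[str, int] = {}
    for r in g.subjects(RDF.type, OWL.Restriction):
        prop = next(g.objects(r, OWL.onProperty), None)
        card = next(g.objects(r, OWL.cardinality), None)
        if prop is not None and card is not None:
            exactly[local(prop)] = int(card)
    for s in g.subjects(RDF.type, OWL.ObjectProperty):
        name = local(s)
        dom = next(g.objects(s, RDFS.domain), None)
        rng = next(g.objects(s, RDFS.range), None)
        m.object_properties[name] = ObjectProperty(
            name,
            local(dom) if dom is not None else "",
            local(rng) if rng is not None else "",
            exactly.get(name),
        )
    for s in g.subjects(RDF.type, OWL.DatatypeProperty):
        name = local(s)
        doms = sorted(local(d) for d in g.objects(s, RDFS.domain))
        rng = next(g.objects(s, RDFS.range), None)
        m.data_properties[name] = DataProperty(
            name, doms, str(rng).rsplit("#", 1)[-1] if rng is not None else ""
        )
    return m
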