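"""Consistency checks over a generated knowledge graph.

Four pure (read-only) checks, each returning a :class:`ConsistencyReport`
rather than raising, so a full audit can be emitted even when several
checks fail:

* **spatial consistency** -- at one timestamp, every configured
  municipality has exactly one forecast (no gaps, no duplicates);
* **temporal consistency** -- one municipality has exactly one forecast
  per expected timestamp (no gaps, no duplicates);
* **cardinality audit** -- the per-class census matches the closed forms
  implied by the mapping rules (|AirQualityForecast| = H*M,
  |Concentration| = S*H*M, |PM10| = 2*H*M, ...);
* **structural consistency** -- every individual is typed, exact-1
  properties are single-valued, property subjects/objects respect the
  declared domains/ranges, literals carry the declared datatypes.

The same spatial/temporal questions are shipped as SPARQL files (see
``ctmkg/sparql/``) for use against any SPARQL 1.1 endpoint; graph
traversal is the reference path.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from rdflib import Literal, RDF, URIRef
from rdflib.namespace import XSD

from .mapping import KnowledgeGraph
from .ontology import OntologyModel

__all__ = [
    "ConsistencyReport",
    "spatial_consistency",
    "temporal_consistency",
    "cardinality_audit",
    "structural_consistency",
    "expected_census",
    "full_audit",
]


@dataclass
class ConsistencyReport:
    check: str
    passed: bool
    expected: object = None
    observed: object = None
    offending: list = field(default_factory=list)

    def __post_init__(self) -> None:
        # invariant: a report passes exactly when nothing offends
        assert self.passed == (not self.offending)

    def to_dict(self) -> dict:
        def norm(v):
            if isinstance(v, (set, frozenset)):
                return sorted(v)
            return v

        return {
            "check": self.check,
            "passed": self.passed,
            "expected": norm(self.expected),
            "observed": norm(self.observed),
            "offending": [str(x) for x in self.offending],
        }


def _forecast_literals(kg: KnowledgeGraph):
    """Yield (forecast, municipality str, timestamp int) for every forecast."""
    ont = kg.ontology
    mun_p = ont.property_iri("hasMunicipality")
    ts_p = ont.property_iri("hasTimestamp")
    for f in kg.graph.subjects(RDF.type, ont.class_iri("AirQualityForecast")):
        mun = kg.graph.value(f, mun_p)
        ts = kg.graph.value(f, ts_p)
        if mun is not None and ts is not None:
            yield f, str(mun), int(ts)


def spatial_consistency(
    kg: KnowledgeGraph, timestamp: int, municipalities: list[str] | None = None
) -> ConsistencyReport:
    """One forecast per municipality at the given timestamp.

    ``municipalities`` defaults to every municipality literal present in
    the graph.  An absent timestamp yields a failed report (expected set
    entirely missing), not an exception.
    """
    seen = Counter()
    all_muns: set[str] = set()
    for _, mun, ts in _forecast_literals(kg):
        all_muns.add(mun)
        if ts == int(timestamp):
            seen[mun] += 1
    expected = set(municipalities) if municipalities is not None else all_muns
    observed = set(seen)
    missing = sorted(expected - observed)
    extra = sorted(observed - expected)
    dupes = sorted(m for m, c in seen.items() if c > 1)
    offending = (
        [f"missing municipality {m!r}" for m in missing]
        + [f"unexpected municipality {m!r}" for m in extra]
        + [f"duplicate forecast for {m!r}" for m in dupes]
    )
    return ConsistencyReport(
        check="spatial_consistency",
        passed=not offending,
        expected=expected,
        observed=observed,
        offending=offending,
    )


def temporal_consistency(
    kg: KnowledgeGraph, municipality: str, timestamps: list[int] | None = None
) -> ConsistencyReport:
    """One forecast per expected timestamp for the given municipality.

    ``timestamps`` defaults to every timestamp literal present in the
    graph.  An unknown municipality yields a failed report.
    """
    seen = Counter()
    all_ts: set[int] = set()
    for _, mun, ts in _forecast_literals(kg):
        all_ts.add(ts)
        if mun == municipality:
            seen[ts] += 1
    expected = set(int(t) for t in timestamps) if timestamps is not None else all_ts
    observed = set(seen)
    missing = sorted(expected - observed)
    extra = sorted(observed - expected)
    dupes = sorted(t for t, c in seen.items() if c > 1)
    offending = (
        [f"missing timestamp {t}" for t in missing]
        + [f"unexpected timestamp {t}" for t in extra]
        + [f"duplicate forecast at {t}" for t in dupes]
    )
    return ConsistencyReport(
        check="temporal_consistency",
        passed=not offending,
        expected=expected,
        observed=observed,
        offending=offending,
    )


def expected_census(ontology: OntologyModel, h: int, m: int,
                    species: list[str]) -> dict[str, int]:
    """Closed-form per-class individual counts for the default rule set.

    Every leaf species gets H*M chemical-entity individuals; group classes
    accumulate their descendants (PM10 = 2*H*M when PM2.5 is present);
    Concentration and ChemicalEntity get S*H*M; the forecast, temperature
    and pressure classes get H*M each.
    """
    hm = h * m
    s = len(species)
    out = {cls: 0 for cls in ontology.classes}
    out["AirQualityForecast"] = hm
    out["Temperature"] = hm
    out["Pressure"] = hm
    out["Concentration"] = s * hm
    for sp in species:
        for cls in [sp, *ontology.ancestors(sp)]:
            if cls in out:
                out[cls] += hm
    return out


def cardinality_audit(kg: KnowledgeGraph, h: int, m: int, s: int) -> ConsistencyReport:
    """Compare the graph census against the closed forms.

    ``s`` must match the species list used at generation time (the species
    are recovered from the ontology leaf classes under ChemicalEntity).
    """
    ont = kg.ontology
    chem = ont.descendants("ChemicalEntity") - {"ChemicalEntity"}
    # species = chemical classes whose individuals were minted directly;
    # for an empty graph fall back to the ontology's leaf species
    species = sorted(c for c in chem if kg.direct_counts.get(c)) or sorted(
        c for c in chem if not ont.children(c)
    )
    if len(species) != s:
        raise ValueError(
            f"graph carries {len(species)} species classes, audit called with s={s}"
        )
    expected = expected_census(ont, h, m, species)
    observed = kg.census()
    offending = [
        f"{cls}: expected {expected[cls]}, observed {observed.get(cls, 0)}"
        for cls in expected
        if observed.get(cls, 0) != expected[cls]
    ]
    return ConsistencyReport(
        check="cardinality_audit",
        passed=not offending,
        expected=expected,
        observed=observed,
        offending=offending,
    )


_NUMERIC = {XSD.double, XSD.decimal, XSD.float, XSD.integer}


def structural_consistency(kg: KnowledgeGraph,
                           ontology: OntologyModel | None = None) -> ConsistencyReport:
    """Structural stand-in for a description-logic consistency check.

    Verifies: every subject of a data/object property assertion has a type;
    exactly-1 object properties are single-valued; subjects and objects of
    each property are instances of (a subclass of) the declared domain and
    range; literal datatypes match the declaration.
    """
    ont = ontology or kg.ontology
    g = kg.graph
    offending: list[str] = []

    types: dict[URIRef, set[str]] = {}
    base = ont.base_iri
    for s_, _, o_ in g.triples((None, RDF.type, None)):
        if isinstance(o_, URIRef) and str(o_).startswith(base):
            types.setdefault(s_, set()).add(str(o_)[len(base):])

    def conforms(node: URIRef, cls: str) -> bool:
        from urllib.parse import unquote
        node_types = {unquote(t) for t in types.get(node, set())}
        return any(t == cls or cls in ont.ancestors(t) for t in node_types
                   if t in ont.classes)

    for op in ont.object_properties.values():
        p = ont.property_iri(op.name)
        seen: dict[URIRef, set] = {}
        for s_, _, o_ in g.triples((None, p, None)):
            if s_ not in types:
                offending.append(f"untyped subject {s_} of {op.name}")
            elif not conforms(s_, op.domain):
                offending.append(f"domain violation: {s_} for {op.name}")
            if not isinstance(o_, URIRef):
                offending.append(f"non-IRI object on {op.name} at {s_}")
            elif o_ not in types:
                offending.append(f"untyped object {o_} of {op.name}")
            elif not conforms(o_, op.range):
                offending.append(f"range violation: {o_} for {op.name}")
            if op.exactly is not None:
                seen.setdefault(s_, set()).add(o_)
        if op.exactly is not None:
            for s_, objs in seen.items():
                if len(objs) != op.exactly:
                    offending.append(
                        f"cardinality violation: {s_} has {len(objs)} values "
                        f"for exactly-{op.exactly} property {op.name}"
                    )
            # individuals of the domain class missing the property entirely
            for node in types:
                if conforms(node, op.domain) and node not in seen:
                    offending.append(
                        f"cardinality violation: {node} has 0 values for "
                        f"exactly-{op.exactly} property {op.name}"
                    )

    for dp in ont.data_properties.values():
        p = ont.property_iri(dp.name)
        want = URIRef(str(XSD) + dp.range)
        for s_, _, o_ in g.triples((None, p, None)):
            if s_ not in types:
                offending.append(f"untyped subject {s_} of {dp.name}")
            elif not any(conforms(s_, d) for d in dp.domains):
                offending.append(f"domain violation: {s_} for {dp.name}")
            if not isinstance(o_, Literal):
                offending.append(f"non-literal object on {dp.name} at {s_}")
            elif o_.datatype is None:
                offending.append(f"untyped literal {o_!r} on {dp.name} at {s_}")
            elif o_.datatype != want and not (
                want in _NUMERIC and o_.datatype in _NUMERIC
            ):
                offending.append(
                    f"datatype violation on {dp.name} at {s_}: "
                    f"{o_.datatype} != {want}"
                )

    return ConsistencyReport(
        check="structural_consistency",
        passed=not offending,
        expected="conformant graph",
        observed=f"{len(offending)} findings",
        offending=offending,
    )


def full_audit(kg: KnowledgeGraph, h: int, m: int, s: int,
               municipalities: list[str] | None = None,
               timestamps: list[int] | None = None) -> list[ConsistencyReport]:
    """Run every check: spatial at each timestamp's worth is summarized by
    one representative timestamp, temporal by one municipality, plus the
    cardinality audit and the structural check."""
    reports = []
    ts_all = sorted({t for _, _, t in _forecast_literals(kg)})
    muns = sorted({m_ for _, m_, _ in _forecast_literals(kg)})
    if ts_all:
        reports.append(spatial_consistency(kg, ts_all[0], municipalities))
    if muns:
        reports.append(temporal_consistency(kg, muns[0], timestamps))
    reports.append(cardinality_audit(kg, h, m, s))
    reports.append(structural_consistency(kg))
    return reports
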