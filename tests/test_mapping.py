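"""Mapping engine: minted individuals, censuses, IRIs, serialization."""

from urllib.parse import quote

import pytest
from rdflib import Graph, Literal, RDF, URIRef
from rdflib.namespace import XSD

from ctmkg import (
    default_ruleset,
    generate_graph,
    mint_iri,
    read_graph,
    serialize_graph,
    write_graph,
)
from ctmkg.mapping import DEFAULT_DATA_BASE, IdentityRule
from conftest import make_custom_table

NINE = ["NO2", "NO", "O3", "SO2", "CH4", "NH3", "CO", "PM10", "PM2.5"]


def one_row_table(municipality="M001"):
    vals = {s: 10.0 + i for i, s in enumerate(NINE)}
    return make_custom_table([vals], NINE, municipality=municipality)


def brute_force_triples(table, ontology, base=DEFAULT_DATA_BASE):
    """Independent flat-loop generator of the expected triple set."""
    onto = ontology.base_iri
    out = set()

    def iri(kind, *keys):
        return URIRef(base + kind + "/" + "/".join(quote(str(k), safe="") for k in keys))

    for _, row in table.df.iterrows():
        mun, ts = row["municipality"], int(row["timestamp"])
        f = iri("forecast", mun, ts)
        out.add((f, RDF.type, URIRef(onto + "AirQualityForecast")))
        out.add((f, URIRef(onto + "hasMunicipality"), Literal(mun, datatype=XSD.string)))
        out.add((f, URIRef(onto + "hasTimestamp"), Literal(ts, datatype=XSD.decimal)))
        for s in table.species:
            c = iri("concentration", mun, ts, s)
            ch = iri("chemical", mun, ts, s)
            out.add((c, RDF.type, URIRef(onto + "Concentration")))
            out.add((c, URIRef(onto + "hasValue"),
                     Literal(float(row[s]), datatype=XSD.double)))
            out.add((f, URIRef(onto + "hasConcentration"), c))
            out.add((c, URIRef(onto + "hasChemicalEntity"), ch))
            out.add((ch, RDF.type, URIRef(onto + quote(s, safe=""))))
        t = iri("temperature", mun, ts)
        p = iri("pressure", mun, ts)
        out.add((t, RDF.type, URIRef(onto + "Temperature")))
        out.add((t, URIRef(onto + "hasValue"),
                 Literal(float(row["temperature"]), datatype=XSD.double)))
        out.add((f, URIRef(onto + "hasTemperature"), t))
        out.add((p, RDF.type, URIRef(onto + "Pressure")))
        out.add((p, URIRef(onto + "hasValue"),
                 Literal(float(row["pressure"]), datatype=XSD.double)))
        out.add((f, URIRef(onto + "hasPressure"), p))
    return out


class TestDefaultRuleset:
    def test_per_row_individual_count_is_2s_plus_3(self, ontology):
        kg = generate_graph(one_row_table(), default_ruleset(ontology), ontology)
        assert kg.n_individuals == 2 * 9 + 3 == 21

    def test_aqi_materialization_adds_one(self, ontology):
        rules = default_ruleset(ontology, materialize_aqi=True)
        kg = generate_graph(one_row_table(), rules, ontology)
        assert kg.n_individuals == 2 * 9 + 4 == 22
        assert kg.census()["AirQualityIndex"] == 1

    def test_every_concentration_has_one_chemical_entity(self, small_kg):
        g = small_kg.graph
        ont = small_kg.ontology
        chem_p = ont.property_iri("hasChemicalEntity")
        for c in g.subjects(RDF.type, ont.class_iri("Concentration")):
            assert len(list(g.objects(c, chem_p))) == 1

    def test_one_row_census_hand_enumeration(self, ontology):
        kg = generate_graph(one_row_table(), default_ruleset(ontology), ontology)
        census = kg.census()
        assert census["AirQualityForecast"] == 1
        assert census["Concentration"] == 9
        assert census["Temperature"] == 1
        assert census["Pressure"] == 1
        assert census["PM10"] == 2  # PM2.5 individuals are PM10 individuals
        assert census["Nanoparticle"] == 2
        assert census["InorganicEntity"] == 5
        assert census["ChemicalEntity"] == 9

    def test_empty_table_gives_empty_graph(self, ontology):
        import pandas as pd
        from ctmkg import ForecastTable

        cols = ["municipality", "timestamp", *NINE, "temperature", "pressure"]
        empty = ForecastTable(df=pd.DataFrame(columns=cols), species=NINE)
        kg = generate_graph(empty, default_ruleset(ontology), ontology)
        assert kg.n_triples == 0
        assert kg.n_individuals == 0
        assert all(v == 0 for v in kg.census().values())

    @pytest.mark.parametrize("n_rows", [1, 3, 5])
    def test_equivalence_with_brute_force_oracle(self, ontology, n_rows):
        vals = [{s: 5.0 + r + i for i, s in enumerate(NINE)} for r in range(n_rows)]
        table = make_custom_table(vals, NINE)
        kg = generate_graph(table, default_ruleset(ontology), ontology)
        assert set(kg.graph) == brute_force_triples(table, ontology)

    def test_census_closed_forms_small(self, small_kg):
        h, m, s = 4, 6, 9
        census = small_kg.census()
        assert census["AirQualityForecast"] == h * m
        assert census["Concentration"] == s * h * m
        assert census["ChemicalEntity"] == s * h * m
        assert census["PM10"] == 2 * h * m
        assert census["InorganicEntity"] == 5 * h * m
        for leaf in ("NO2", "O3", "CH4", "PM2.5"):
            assert census[leaf] == h * m

    def test_identity_rule_merges_chemical_entities(self, ontology):
        vals = [{s: 1.0 for s in NINE} for _ in range(3)]
        table = make_custom_table(vals, NINE)
        rules = default_ruleset(ontology)
        rules.identity_rules.append(IdentityRule("chemical", ("species",)))
        kg = generate_graph(table, rules, ontology)
        # chemical entities collapse to one per species instead of per row
        assert kg.census()["ChemicalEntity"] == 9
        assert kg.census()["Concentration"] == 27

    def test_missing_column_error_names_rule_and_column(self, ontology):
        table = one_row_table()
        rules = default_ruleset(ontology)
        from ctmkg.mapping import AttributeRule

        rules.attribute_rules.append(
            AttributeRule("forecast", "humidity", "hasMunicipality", "string")
        )
        with pytest.raises(ValueError, match="humidity"):
            generate_graph(table, rules, ontology)

    def test_missing_ontology_class_rejected(self):
        from ctmkg import build_ontology

        bare = build_ontology(species=[])
        del bare.classes["Temperature"]
        with pytest.raises(ValueError, match="Temperature"):
            default_ruleset(bare)

    def test_domain_violation_rejected(self, ontology):
        from ctmkg.mapping import RelationRule

        rules = default_ruleset(ontology)
        # hasTemperature must point at Temperature, not a Concentration
        rules.relation_rules.append(
            RelationRule("forecast", "hasTemperature", "concentration", per="species")
        )
        with pytest.raises(ValueError, match="range violation"):
            generate_graph(one_row_table(), rules, ontology)


class TestMintIri:
    def test_deterministic(self):
        a = mint_iri("http://x/", "forecast", ("M001", 17))
        b = mint_iri("http://x/", "forecast", ("M001", 17))
        assert a == b

    def test_distinct_rows_distinct_iris(self):
        a = mint_iri("http://x/", "forecast", ("M001", 17))
        b = mint_iri("http://x/", "forecast", ("M002", 17))
        c = mint_iri("http://x/", "forecast", ("M001", 18))
        assert len({a, b, c}) == 3

    def test_reserved_characters_percent_encoded(self):
        iri = mint_iri("http://x/", "forecast", ("Molina de Segura", 1))
        assert "Molina%20de%20Segura" in str(iri)
        assert " " not in str(iri)

    def test_empty_keys_rejected(self):
        with pytest.raises(ValueError):
            mint_iri("http://x/", "forecast", ())


class TestWriteGraph:
    def test_write_parse_round_trip(self, small_kg, tmp_path):
        for fmt, ext in [("turtle", "ttl"), ("rdf/xml", "rdf")]:
            path = tmp_path / f"g.{ext}"
            write_graph(small_kg, path, fmt)
            back = read_graph(path, fmt)
            assert set(back) == set(small_kg.graph)

    def test_byte_identical_serialization(self, small_kg, tmp_path):
        p1, p2 = tmp_path / "a.ttl", tmp_path / "b.ttl"
        write_graph(small_kg, p1, "turtle")
        write_graph(small_kg, p2, "turtle")
        assert p1.read_bytes() == p2.read_bytes()

    def test_size_monotone_in_row_count(self, ontology):
        sizes = []
        for h in (1, 2, 4):
            vals = [{s: 1.0 for s in NINE} for _ in range(h)]
            kg = generate_graph(make_custom_table(vals, NINE),
                                default_ruleset(ontology), ontology)
            sizes.append(len(serialize_graph(kg, "turtle")))
        assert sizes[0] < sizes[1] < sizes[2]

    def test_unknown_format_rejected(self, small_kg, tmp_path):
        with pytest.raises(ValueError, match="unknown format"):
            write_graph(small_kg, tmp_path / "x", "json-ld-ish")
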