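import numpy as np
import pandas as pd
import pytest

from ctmkg import (
    DomainSpec,
    FieldSpec,
    ForecastTable,
    build_forecast_table,
    build_ontology,
    default_ruleset,
    generate_graph,
    make_municipalities,
    simulate_fields,
)

DEFAULT_H, DEFAULT_M, DEFAULT_S = 73, 45, 9


@pytest.fixture(scope="session")
def ontology():
    return build_ontology()


@pytest.fixture(scope="session")
def small_domain():
    return DomainSpec(nx=6, ny=6, cell_size=1000.0, n_municipalities=6, seed=3)


@pytest.fixture(scope="session")
def small_fields(small_domain):
    return simulate_fields(small_domain, FieldSpec(hours=4))


@pytest.fixture(scope="session")
def small_municipalities(small_domain):
    return make_municipalities(small_domain)


@pytest.fixture(scope="session")
def small_table(small_fields, small_municipalities):
    return build_forecast_table(small_fields, small_municipalities)


@pytest.fixture(scope="session")
def small_kg(small_table, ontology):
    return generate_graph(small_table, default_ruleset(ontology), ontology)


# --- the use-case-scale fixture: 73 hourly steps, 45 municipalities, 9 species


@pytest.fixture(scope="session")
def default_domain():
    return DomainSpec(seed=1)


@pytest.fixture(scope="session")
def default_fields(default_domain):
    return simulate_fields(default_domain, FieldSpec())


@pytest.fixture(scope="session")
def default_municipalities(default_domain):
    return make_municipalities(default_domain)


@pytest.fixture(scope="session")
def default_table(default_fields, default_municipalities):
    return build_forecast_table(default_fields, default_municipalities)


@pytest.fixture(scope="session")
def default_kg(default_table, ontology):
    return generate_graph(default_table, default_ruleset(ontology), ontology)


def make_custom_table(values_by_row, species, municipality="M001",
                      start_ms=1_703_570_400_000):
    """Hand-built table: one row per dict of species->value, hourly steps."""
    rows = []
    for i, vals in enumerate(values_by_row):
        row = {"municipality": municipality, "timestamp": start_ms + 3_600_000 * i}
        for s in species:
            row[s] = float(vals[s])
        row["temperature"] = 288.0
        row["pressure"] = 101325.0
        rows.append(row)
    df = pd.DataFrame(rows, columns=["municipality", "timestamp", *species,
                                     "temperature", "pressure"])
    df["timestamp"] = df["timestamp"].astype(np.int64)
    return ForecastTable(df=df, species=list(species))
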