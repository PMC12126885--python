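"""Competency questions: banding, superations, index, round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctmkg import (
    ThresholdTable,
    aqi_band,
    aqi_distribution,
    aqi_from_values,
    aqi_index,
    count_superations,
    spatial_snapshot,
    time_series,
)
from ctmkg.queries import AQI_LABELS, _BAND_UPPERS
from conftest import make_custom_table

NINE = ["NO2", "NO", "O3", "SO2", "CH4", "NH3", "CO", "PM10", "PM2.5"]
FIVE = ["PM2.5", "PM10", "NO2", "O3", "SO2"]


def band_oracle(pollutant, value):
    """Independent banding: explicit interval scan on the published table."""
    uppers = _BAND_UPPERS[pollutant]
    lowers = [0.0] + uppers[:-1]
    for lo, up, label in zip(lowers, uppers, AQI_LABELS):
        if lo <= value < up:
            return label
    return "Extremely Poor"


def graph_from_rows(rows, ontology, municipality="M001"):
    from ctmkg import default_ruleset, generate_graph

    table = make_custom_table(rows, NINE, municipality=municipality)
    return generate_graph(table, default_ruleset(ontology), ontology), table


class TestAqiBand:
    @pytest.mark.parametrize("pollutant", FIVE)
    def test_every_band_boundary(self, pollutant):
        uppers = _BAND_UPPERS[pollutant]
        lowers = [0.0] + uppers[:-1]
        for lo, up, label in zip(lowers, uppers, AQI_LABELS):
            assert aqi_band(pollutant, lo) == label  # lower edge included
            mid = (lo + up) / 2
            assert aqi_band(pollutant, mid) == label
        # shared endpoints take the severer band; top and above stay worst
        for up, next_label in zip(uppers[:-1], AQI_LABELS[1:]):
            assert aqi_band(pollutant, up) == next_label
        assert aqi_band(pollutant, uppers[-1]) == "Extremely Poor"
        assert aqi_band(pollutant, uppers[-1] + 500) == "Extremely Poor"

    def test_published_examples(self):
        assert aqi_band("NO2", 100) == "Moderate"  # 90-120 band
        assert aqi_band("PM2.5", 30) == "Poor"  # 25-50 band
        for p in FIVE:
            assert aqi_band(p, 0) == "Good"

    def test_unknown_species_rejected(self):
        with pytest.raises(KeyError, match="CO"):
            aqi_band("CO", 10.0)

    @pytest.mark.parametrize("pollutant", FIVE)
    @settings(derandomize=True, max_examples=50)
    @given(v1=st.floats(0, 1500), delta=st.floats(0, 500))
    def test_monotone_in_value(self, pollutant, v1, delta):
        s1 = AQI_LABELS.index(aqi_band(pollutant, v1))
        s2 = AQI_LABELS.index(aqi_band(pollutant, v1 + delta))
        assert s1 <= s2


class TestAqiIndex:
    def test_all_zero_is_good(self, ontology):
        kg, table = graph_from_rows([{s: 0.0 for s in NINE}], ontology)
        assert aqi_index(kg, "M001", table.timestamps[0]) == "Good"

    def test_worst_pollutant_drives_index(self, ontology):
        vals = {s: 0.0 for s in NINE}
        vals.update({"PM2.5": 5, "PM10": 45, "NO2": 30, "O3": 60, "SO2": 50})
        kg, table = graph_from_rows([vals], ontology)
        assert aqi_index(kg, "M001", table.timestamps[0]) == "Moderate"  # PM10

    def test_thousand_random_vectors_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            vec = {p: float(rng.uniform(0, 1500)) for p in FIVE}
            expected = AQI_LABELS[
                max(AQI_LABELS.index(band_oracle(p, v)) for p, v in vec.items())
            ]
            assert aqi_from_values(vec) == expected

    def test_missing_pollutant_listed(self, ontology):
        with pytest.raises(KeyError, match="SO2"):
            aqi_from_values({"PM2.5": 1, "PM10": 1, "NO2": 1, "O3": 1})


class TestSuperations:
    def test_reaches_or_exceeds_is_inclusive(self, ontology):
        rows = []
        for v in (5.0, 4.9, 6.1):
            r = {s: 0.0 for s in NINE}
            r["PM2.5"] = v
            rows.append(r)
        kg, _ = graph_from_rows(rows, ontology)
        counts = count_superations(kg, "M001")
        assert counts["PM2.5"] == 2  # 5.0 counts, 4.9 does not, 6.1 counts
        assert counts["PM10"] == 0 and counts["NO2"] == 0

    def test_all_below_thresholds(self, ontology):
        kg, _ = graph_from_rows([{s: 0.1 for s in NINE}] * 3, ontology)
        assert all(c == 0 for c in count_superations(kg, "M001").values())

    def test_matches_linear_scan_oracle(self, default_kg, default_table):
        mun = "M007"
        counts = count_superations(default_kg, mun)
        sub = default_table.df[default_table.df["municipality"] == mun]
        for sp, thr in [("PM10", 10.0), ("NO2", 10.0), ("PM2.5", 5.0)]:
            assert counts[sp] == int((sub[sp] >= thr).sum())

    def test_window_restricts_counts(self, default_kg, default_table):
        mun = "M001"
        ts = default_table.timestamps
        window = (ts[10], ts[20])
        counts = count_superations(default_kg, mun, window=window)
        sub = default_table.df[
            (default_table.df["municipality"] == mun)
            & (default_table.df["timestamp"] >= window[0])
            & (default_table.df["timestamp"] <= window[1])
        ]
        assert counts["PM10"] == int((sub["PM10"] >= 10.0).sum())

    def test_monotone_in_threshold(self, default_kg):
        c5 = count_superations(default_kg, "M003",
                               thresholds=ThresholdTable({"PM10": 5.0}))
        c15 = count_superations(default_kg, "M003",
                                thresholds=ThresholdTable({"PM10": 15.0}))
        assert c5["PM10"] >= c15["PM10"]


class TestRoundTrips:
    def test_time_series_matches_table(self, default_kg, default_table):
        mun, sp = "M005", "PM10"
        series = time_series(default_kg, mun, sp)
        assert len(series) == 73
        assert [t for t, _ in series] == default_table.timestamps
        sub = default_table.df[default_table.df["municipality"] == mun]
        expected = dict(zip(sub["timestamp"].astype(int), sub[sp]))
        for t, v in series:
            assert v == pytest.approx(expected[t], rel=1e-9)

    def test_snapshot_matches_table(self, default_kg, default_table):
        ts = default_table.timestamps[6]
        snap = spatial_snapshot(default_kg, ts, "CH4")
        assert len(snap) == 45
        sub = default_table.df[default_table.df["timestamp"] == ts]
        assert sum(snap.values()) == pytest.approx(sub["CH4"].sum(), rel=1e-9)
        for mun, v in snap.items():
            assert v == pytest.approx(
                float(sub[sub["municipality"] == mun]["CH4"].iloc[0]), rel=1e-9
            )

    def test_constant_fixture_gives_constant_series(self, ontology):
        rows = [{s: 3.5 for s in NINE}] * 4
        kg, _ = graph_from_rows(rows, ontology)
        series = time_series(kg, "M001", "NO2")
        assert [v for _, v in series] == [3.5] * 4

    def test_unknown_species_warns_and_empty(self, small_kg):
        with pytest.warns(UserWarning):
            assert time_series(small_kg, "M001", "XENON") == []
        with pytest.warns(UserWarning):
            assert spatial_snapshot(small_kg, 1, "NO2") == {}


class TestAqiDistribution:
    def test_all_zero_fixture_is_all_good(self, ontology):
        kg, _ = graph_from_rows([{s: 0.0 for s in NINE}] * 5, ontology)
        dist = aqi_distribution(kg, "M001")
        assert dist["Good"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self, default_kg):
        dist = aqi_distribution(default_kg, "M002")
        assert sum(dist.values()) == pytest.approx(100.0, abs=1e-9)

    def test_equals_per_timestamp_counting_oracle(self, small_kg, small_table):
        mun = "M002"
        labels = [aqi_index(small_kg, mun, t) for t in small_table.timestamps]
        dist = aqi_distribution(small_kg, mun)
        for lab in set(labels):
            assert dist[lab] == pytest.approx(100.0 * labels.count(lab) / len(labels))

    def test_empty_window_rejected(self, small_kg):
        with pytest.raises(ValueError, match="no timestamps"):
            aqi_distribution(small_kg, "M001", window=(0, 1))


class TestSparqlEquivalence:
    def test_time_series_query_matches_traversal(self, small_kg):
        from rdflib import Literal
        from rdflib.namespace import XSD
        from ctmkg import load_sparql

        q = load_sparql("q3_time_series")
        rows = small_kg.graph.query(
            q,
            initBindings={
                "mun": Literal("M001", datatype=XSD.string),
                "cls": small_kg.ontology.class_iri("PM10"),
            },
        )
        got = sorted((int(r["date"]), float(r["value"])) for r in rows)
        assert got == time_series(small_kg, "M001", "PM10")
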