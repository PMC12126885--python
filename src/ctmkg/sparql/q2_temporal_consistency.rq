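# Temporal consistency: all timestamps forecast for one municipality.
# Bind ?mun to the municipality literal under test (e.g. "Totana").
PREFIX : <https://purl.org/chimere-ontology#>
SELECT ?forecast ?date
WHERE {
  ?forecast a :AirQualityForecast ;
            :hasMunicipality ?municipality ;
            :hasTimestamp ?date .
  FILTER (?municipality = ?mun)
}
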