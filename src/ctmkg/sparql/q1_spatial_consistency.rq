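# Spatial consistency: all municipalities forecast at one timestamp.
# Bind ?ts to the timestamp under test (xsd:decimal epoch milliseconds).
PREFIX : <https://purl.org/chimere-ontology#>
PREFIX xsd: <http://www.w3.org/2001/XMLSchema#>
SELECT ?forecast ?municipality
WHERE {
  ?forecast a :AirQualityForecast ;
            :hasMunicipality ?municipality ;
            :hasTimestamp ?date .
  FILTER (?date = ?ts)
}
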