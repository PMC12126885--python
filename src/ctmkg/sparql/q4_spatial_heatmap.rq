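# Spatial snapshot of one chemical entity at one timestamp (heatmap input).
# Bind ?ts (xsd:decimal epoch milliseconds) and ?cls (species class IRI).
PREFIX : <https://purl.org/chimere-ontology#>
SELECT ?municipality ?value
WHERE {
  ?forecast a :AirQualityForecast ;
            :hasMunicipality ?municipality ;
            :hasTimestamp ?date ;
            :hasConcentration ?conc .
  ?conc :hasValue ?value ;
        :hasChemicalEntity ?chem .
  ?chem a ?cls .
  FILTER (?date = ?ts)
}
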