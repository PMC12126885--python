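# Superations: timestamps where a pollutant reaches or exceeds a threshold.
# Bind ?mun, ?cls (species class IRI) and ?threshold (xsd:double).
PREFIX : <https://purl.org/chimere-ontology#>
SELECT ?date ?value
WHERE {
  ?forecast a :AirQualityForecast ;
            :hasMunicipality ?municipality ;
            :hasTimestamp ?date ;
            :hasConcentration ?conc .
  ?conc :hasValue ?value ;
        :hasChemicalEntity ?chem .
  ?chem a ?cls .
  FILTER (?municipality = ?mun)
  FILTER (?value >= ?threshold)
}
ORDER BY ?date
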