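# Time series of one chemical entity in one municipality.
# Bind ?mun (string literal) and ?cls (the species class IRI).
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
}
ORDER BY ?date
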