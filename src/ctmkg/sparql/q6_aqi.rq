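# Air quality index input: the five index pollutants per timestamp for one
# municipality; banding and worst-band aggregation are applied client-side.
# Bind ?mun (string literal).
PREFIX : <https://purl.org/chimere-ontology#>
SELECT ?date ?cls ?value
WHERE {
  ?forecast a :AirQualityForecast ;
            :hasMunicipality ?municipality ;
            :hasTimestamp ?date ;
            :hasConcentration ?conc .
  ?conc :hasValue ?value ;
        :hasChemicalEntity ?chem .
  ?chem a ?cls .
  FILTER (?municipality = ?mun)
  FILTER (?cls IN (:PM2.5, :PM10, :NO2, :O3, :SO2))
}
ORDER BY ?date
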