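alias,country,state,county,city,zip
"Los Angeles, CA",US,California,Los Angeles County,Los Angeles,
"los angeles",US,California,Los Angeles County,Los Angeles,
"LA, California",US,California,Los Angeles County,Los Angeles,
"Long Beach, CA",US,California,Los Angeles County,Long Beach,
"Glendale, CA",US,California,Los Angeles County,Glendale,
"Pasadena, CA",US,California,Los Angeles County,Pasadena,
"Santa Monica, CA",US,California,Los Angeles County,Santa Monica,
"Pomona, CA",US,California,Los Angeles County,Pomona,
"Torrance, CA",US,California,Los Angeles County,Torrance,
"El Monte, CA",US,California,Los Angeles County,El Monte,
"Downey, CA",US,California,Los Angeles County,Downey,
"Inglewood, CA",US,California,Los Angeles County,Inglewood,
"Burbank, CA",US,California,Los Angeles County,Burbank,
"Compton, CA",US,California,Los Angeles County,Compton,
"Sacramento, CA",US,California,Sacramento County,Sacramento,
"San Diego, CA",US,California,San Diego County,San Diego,
"Houston, TX",US,Texas,Harris County,Houston,
"Austin, TX",US,Texas,Travis County,Austin,
"Miami, FL",US,Florida,Miami-Dade County,Miami,
"Orlando, FL",US,Florida,Orange County,Orlando,
"New York, NY",US,New York,New York County,New York,
"Chicago, IL",US,Illinois,Cook County,Chicago,
"Phoenix, AZ",US,Arizona,Maricopa County,Phoenix,
"Seattle, WA",US,Washington,King County,Seattle,
"Denver, CO",US,Colorado,Denver County,Denver,
"Atlanta, GA",US,Georgia,Fulton County,Atlanta,
"Boston, MA",US,Massachusetts,Suffolk County,Boston,
"Toronto, ON",CA,Ontario,,Toronto,
"London, UK",GB,England,,London,
"Mexico City",MX,CDMX,,Mexico City,
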