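# Stage 3: analyses whose input expression contains a satisfied conjunct
# requiring multiple acquisition types — every required type must have an
# available type at or below it in the class hierarchy.
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX mkv:  <https://mriokit.dev/vocab#>

SELECT DISTINCT ?analysis WHERE {
  ?analysis a mkv:AnalysisSpec ;
            mkv:hasInputConjunct ?c .
  ?c mkv:conjunctSize ?n .
  FILTER(?n > 1)
  FILTER NOT EXISTS {
    ?c mkv:requiresType ?req .
    FILTER NOT EXISTS {
      VALUES ?avail { %AVAILABLE% }
      ?avail rdfs:subClassOf* ?req .
    }
  }
}
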