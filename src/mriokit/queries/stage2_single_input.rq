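# Stage 2: analyses whose input expression contains a satisfied conjunct
# of size 1 — i.e. a single available acquisition type (or a descendant of
# the required type) suffices.
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX mkv:  <https://mriokit.dev/vocab#>

SELECT DISTINCT ?analysis WHERE {
  ?analysis a mkv:AnalysisSpec ;
            mkv:hasInputConjunct ?c .
  ?c mkv:conjunctSize 1 ;
     mkv:requiresType ?req .
  VALUES ?avail { %AVAILABLE% }
  ?avail rdfs:subClassOf* ?req .
}
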