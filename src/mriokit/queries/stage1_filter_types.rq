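# Stage 1: canonicalize the caller-supplied acquisition types.
# Keys are injected as string literals (full IRI strings, labels, or
# synonyms); only keys resolving to a declared class survive the filter.
# The VALUES block is repeated per branch because FILTERs are evaluated
# within their own group and would not see an outer binding.
PREFIX owl:  <http://www.w3.org/2002/07/owl#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX mkv:  <https://mriokit.dev/vocab#>

SELECT DISTINCT ?cls ?key WHERE {
  ?cls a owl:Class .
  {
    VALUES ?key { %KEYS% }
    ?cls a owl:Class .
    FILTER(STR(?cls) = ?key)
  } UNION {
    VALUES ?key { %KEYS% }
    ?cls rdfs:label ?lab .
    FILTER(LCASE(STR(?lab)) = LCASE(?key))
  } UNION {
    VALUES ?key { %KEYS% }
    ?cls mkv:synonym ?syn .
    FILTER(LCASE(STR(?syn)) = LCASE(?key))
  }
}
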