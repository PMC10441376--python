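# mriokit

Ontology-driven tooling for MRI acquisition metadata: classify series
from their scanner settings, discover which analyses a dataset supports,
and bridge DICOM headers to BIDS layouts — all against a bundled,
editable knowledge base of MRI types, parameters, and analyses.

## Who this is for

Neuroimaging researchers and data managers facing heaps of heterogeneous
MR series — scanner exports where `SeriesDescription` is free text and
every site spells "FLAIR" differently — who want a principled,
inspectable answer to three questions:

1. *What kind of scan is this?* (from TR/TE/TI/flip angle/sequence codes)
2. *Which analyses can I run on what I have?* (SIENAX? DeepGRAI? …)
3. *How do these series map onto a BIDS tree with faithful sidecars?*

## The core idea

Each acquisition type is defined by a logical axiom over machine
settings, with OWL-facet interval semantics (strict bounds exclusive):

```
T1w:  TR ∈ (0, 800) ms  ∧  TE ∈ (0, 30) ms  ∧  α = 90°
T2w:  TR > 2000 ms      ∧  TE > 30 ms       ∧  α = 90°
```

Subtypes (T2 FLAIR, T1 SPGR, PD, DWI, fMRI) refine these in a class
hierarchy; the classifier reports the most specific match. Analyses
carry disjunctive-normal-form input expressions over type classes —
SIENAX, for instance, accepts `(T1w ∧ T2-FLAIR) ∨ (T1w)` — and an
analysis is assignable when some conjunct is covered by an available
type *or any of its subtypes*. Assignment runs either natively or as a
three-stage SPARQL chain over the RDF export; the two modes agree
exactly. See `docs/methods.md` for the full model, provenance of every
rule, and known limitations.

## Worked example

```python
>>> import mriokit as mk
>>> kb = mk.build_default_kb()

>>> p = mk.read_bids_sidecar('{"EchoTime": 0.015, "RepetitionTime": 0.5, "FlipAngle": 90}')
>>> r = mk.classify_series(kb, p)
>>> sorted(r.matched_types)
['MRIO:0000366']
>>> kb.term("MRIO:0000366").label
'T1 weighted magnetic resonance image data set'

>>> result = mk.assign_analyses(kb, ["T1w"])
>>> for iri, label in sorted(result.assignments.items()):
...     print(iri, "->", label)
MRIO:0000525 -> SIENAX analysis
MRIOKIT:fast-analysis -> FAST analysis
MRIOKIT:first-analysis -> FIRST analysis
MRIOKIT:freesurfer-analysis -> FreeSurfer analysis

>>> mk.explain_assignment(kb, "MRIO:0000525", ["T1w"]).conjunct
('MRIO:0000366',)
```

A 15 ms echo time and 500 ms repetition time with a 90° flip angle land
inside the T1-weighted axiom, so the series classifies as
MRIO:0000366; with a T1w series available, four analyses become
runnable, SIENAX among them through its single-input conjunct.

The same flows from the shell:

```
mrio simulate --type FLAIR -n 4 --seed 2 --format sidecar -o fixtures/
mrio classify fixtures/                    # JSON: per-series types + summary
mrio assign --types T1w,FLAIR --explain    # runnable analyses + witnesses
mrio organize fixtures/ bids/ --apply      # plan + write a BIDS tree
mrio kb-export -o mrio.ttl                 # canonical Turtle export
mrio kb-validate                           # structural validation report
```

The knowledge base itself is data: dump it with
`mriokit.save_kb(kb, "kb.yaml")`, edit or extend the acquisition rules
(schema in `docs/kb_schema.json`), and pass `--kb kb.yaml` to any
command.

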