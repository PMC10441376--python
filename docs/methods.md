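# Methods

## The model

mriokit operationalizes an OBO-style ontology of MRI acquisition and
analysis as executable rules. Three formal objects carry the science:

**Acquisition-type axioms.** Each MRI acquisition type *T* (T1-weighted,
T2-weighted, T2 FLAIR, proton density, diffusion-weighted, functional,
T1 SPGR) is defined by one or more conjunctions of constraints over a
series' scanner settings — repetition time TR, echo time TE, inversion
time TI, flip angle α, scanning-sequence codes, diffusion fields, and
temporal positions. A series *s* belongs to *T* when some axiom of *T*
is fully satisfied by *s*. Interval bounds use OWL facet semantics with
*exclusive* strict inequalities, exactly as the source axioms are
written:

    T1w:  TR ∈ (0, 800) ms  ∧  TE ∈ (0, 30) ms  ∧  α = 90°
    T2w:  TR > 2000 ms      ∧  TE > 30 ms       ∧  α = 90°

so TR = 800 ms is *not* T1-weighted and TR = 2000 ms is *not*
T2-weighted. The TR intervals (0, 800) and (2000, ∞) are disjoint, which
makes the two base classes provably exclusive; the gap (800, 2000] is
deliberately unclassified territory.

**Subsumption.** Types live in a single-parent class hierarchy
(T2 FLAIR ⊑ T2w, T1 SPGR ⊑ T1w, …). Reasoning is the
reflexive-transitive closure of the explicit parent graph — no
description-logic reasoner is involved, by design. The classifier
reports only the most specific matching types; ancestors are implied
through the reported lineage.

**Analysis input expressions.** Each analysis (SIENAX, SIENA, FAST,
FIRST, FreeSurfer, NeuroSTREAM, DeepGRAI, LPA, C-PAC, NeMo) carries a
disjunctive-normal-form expression over required input types. An
analysis is assignable when some conjunct is covered: every required
type has an available type at or below it in the hierarchy. A FLAIR
series therefore satisfies a T2w requirement (class–instance semantics),
and availability growth or specialization can only add assignments
(monotonicity, verified by property tests).

The assignment procedure runs in two interchangeable modes: native
set evaluation, and a three-stage SPARQL chain over the Turtle export
(stage 1 filters/canonicalizes the supplied types; stage 2 collects
analyses satisfiable through a single required input; stage 3 those
requiring several). The test suite asserts exact agreement between the
modes on the bundled knowledge base and on 1,000 seeded random
knowledge-base/availability pairs.

## Provenance of the bundled rules

Only the T1w and T2w axioms are transcribed from printed facet
expressions (provenance `PAPER`). The named subtypes come with
filled-in rules (provenance `DEFAULT`, surfaced as validation warnings
and overridable via the YAML knowledge-base document):

| type | rule | rationale |
|---|---|---|
| T2 FLAIR | T2w base ∧ TI > 1500 ms ∧ IR ∈ sequence | FLAIR is an inversion-recovery T2w sequence |
| PD | TR > 2000 ∧ TE ∈ (0, 30) ∧ α = 90 | long-TR/short-TE convention |
| DWI | max b > 0 ∨ diffusion gradients present | b value / gradients are the discriminating fields |
| fMRI | EP ∈ sequence ∧ temporal positions > 1 | 4-D echo-planar time series |
| T1 SPGR | GR ∈ sequence ∧ TR < 800 ∧ TE < 30 ∧ α ∈ (0, 45) | spoiled-gradient T1w uses low flip angles |

The DWI disjunction is modelled as two axioms for one type (a type
matches when any of its axioms matches); every individual axiom remains
a pure conjunction. The flip-angle equality for spin-echo T1w/T2w is
compared with an absolute tolerance of 0.5° (scanner rounding); interval
bounds are compared exactly. The α = 90 equality is scoped to the
spin-echo rules only — T1 SPGR, although a T1w subtype, uses its own
low-flip-angle interval, since the two conventions cannot be reconciled
in a single rule.

Missing parameters evaluate to *indeterminate*. The default `strict`
policy counts indeterminate as unsatisfied (refuse to classify on absent
evidence); `lenient` counts it as satisfied. Note that under `lenient` a
nearly empty header matches almost everything — it exists for exploring
incomplete exports, not for production sorting.

## Units and the DICOM↔BIDS bridge

Canonical durations are milliseconds (the DICOM convention and the unit
the repetition-time definition states); BIDS sidecar durations are
interpreted as seconds and converted on read/write through the bridge
table's per-entry scale factors. Only the echo-time entry —
tag (0018,0081) ↔ `EchoTime` ↔ MRIO:0000358 — is the worked bridging
exemplar; the remaining entries are completed from the DICOM data
dictionary and BIDS key names and carry provenance `DEFAULT`. Slice gap
is derived as SpacingBetweenSlices − SliceThickness when both are
present. Multi-echo TE multi-values take the first echo, with a warning.
Plane is read only from an explicit field; deriving it from orientation
cosines is out of scope.

BIDS layout planning is pure (no filesystem mutation; `--apply` writes
sidecars separately). Of the BIDS entities only `run-` is populated,
assigned in input order when a (subject, session, suffix) combination
repeats. Suffix conventions: T1w→anat/T1w, T2w→anat/T2w, FLAIR→anat/FLAIR,
PD→anat/PDw, fMRI→func/bold, DWI→dwi/dwi; subtypes inherit from the
nearest mapped ancestor.

## Synthetic data

The generator draws parameter records uniformly inside a type's axiom
region: each interval is shrunk by a boundary margin (default 0.05 of
the interval width; boundary-exactness tests set it to 0), equalities
are set exactly, and categorical constraints set exactly the required
codes. Open-ended facets are closed at plausible scanner maxima
(TR ≤ 15 000 ms, TE ≤ 500 ms, TI ≤ 3 500 ms, ≤ 400 temporal positions,
b ≤ 3 000 s/mm²). Negative controls violate exactly one indexed
constraint while satisfying the rest; for types with disjunctive rules
the alternative axiom is knocked out as well, so no negative classifies
as its target type. Draws are produced by Python's Mersenne-Twister
`random.Random` seeded per call, giving platform-independent
reproducibility; continuous values are rounded to 4 decimals (scanner
precision, and within the 16-character DICOM decimal-string limit).

What the generator emulates is per-series *header metadata* consistent
with each type's rule — it writes JSON tag maps, minimal MR Part 10
DICOM files, and BIDS sidecars. What it does not emulate: pixel data,
vendor private tags, site-specific string conventions, parameter
correlations within a protocol, or series that straddle rule boundaries
the way heterogeneous clinical archives do. Passing recovery tests
therefore demonstrates the rule engine's correctness and the
readers/writers' fidelity, not classification accuracy on arbitrary
real-world archives.

## Serialization choices

The Turtle export is produced by a canonical writer: no blank nodes
(auxiliary axiom/conjunct/region nodes get minted IRIs), all
collections sorted, floats typed `xsd:double` with `repr` formatting.
This makes export → parse → export a byte-identical fixed point, which
the generic rdflib serializer does not guarantee; rdflib remains the
parser and the SPARQL engine, so every round-trip cross-checks the
writer against an independent implementation. The knowledge base is
also round-trippable through a YAML/JSON document (schema:
`docs/kb_schema.json`) for rule overrides without code changes.

One identifier conflict required a decision: OBI:0003327 is printed for
both *image data set* and *raw image data set*. The bundle assigns it
to *image data set* (first introduction) and gives *raw image data set*
a provisional identifier, recording the clash in its definition, rather
than silently duplicating an IRI. Uberon cross-references for the
86-region Desikan–Killiany table are curated for the well-known
subcortical structures; cortical parcels carry a generic brain
placeholder pending curation (validation enforces the count of 86 and
label uniqueness, not specific identifiers).

## Problem sizes and numerical notes

Property suites run at: 10⁵ random parameter draws for the
T1w/T2w-disjointness sweep; 1,000 draws per type for parameter
recovery; 50 draws per fixture format for round-trip checks (durations
compared at 1e-9 relative tolerance, since millisecond↔second
conversion is inexact in binary floating point); 1,000 random
knowledge-base/availability pairs for assignment semantics. Threshold
recovery uses bisection to 1e-7 on TR/TE sweeps and an exhaustive
integer sweep for the flip angle.

## Known limitations

- Classification is metadata-only; image content never participates.
- The rule table covers the common clinical-routine types; field maps,
  susceptibility-weighted imaging, MR angiography, spectroscopy, and
  most quantitative sequences are absent.
- Subsumption is asserted-hierarchy-only; no inferred equivalences.
- The generalizability of any fixed TR/TE ranges is inherently limited —
  contrast depends on field strength, vendor, and tissue; the rules are
  a reasonable operating point, not physics. Field-strength-specific
  ranges are not modelled.
- BIDS planning covers the `run-` entity only and does not aim for
  bids-validator parity.
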