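"""The MRI ontology term graph and its reasoning/serialization surface.

The knowledge base bundles four kinds of records:

* :class:`TermRecord` — named classes (acquisition parameters, image data
  set types, analyses, atlases) arranged in a single-parent subsumption
  hierarchy;
* :class:`TypeAxiom` — conjunctions of interval/equality/categorical
  constraints over acquisition parameters that define when a series belongs
  to an acquisition type (several axioms for one type act as a disjunction);
* :class:`AnalysisSpec` — analyses with a disjunctive-normal-form input
  expression over acquisition-type CURIEs and declared output data;
* :class:`TermBridge` / :class:`AtlasMap` — the DICOM-tag ↔ BIDS-key ↔ IRI
  bridge and brain-atlas region tables.

Reasoning is deliberately modest: subsumption over the explicit parent
graph (reflexive-transitive closure), not full description logic.
Serialization targets Turtle with a canonical, byte-stable layout so that
``export -> parse -> export`` is a fixed point.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, fields, replace

import yaml
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .errors import (
    AmbiguousLookupError,
    FormatError,
    KBValidationError,
    NotFoundError,
    ResolutionError,
)

# ---------------------------------------------------------------------------
# CURIE <-> IRI machinery
# ---------------------------------------------------------------------------

OBO = "http://purl.obolibrary.org/obo/"
MKT = "https://mriokit.dev/term/"
MKV = "https://mriokit.dev/vocab#"
MKN = "https://mriokit.dev/node/"

#: CURIE prefixes recognized in the knowledge base. ``MRIOKIT`` holds
#: provisional identifiers minted by this toolkit for classes the source
#: ontology names but prints no stable IRI for.
CURIE_PREFIXES = {
    "MRIO": OBO + "MRIO_",
    "OBI": OBO + "OBI_",
    "IAO": OBO + "IAO_",
    "UBERON": OBO + "UBERON_",
    "MRIOKIT": MKT,
}

_CURIE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*):(\S+)$")


def curie_to_iri(curie: str) -> str:
    m = _CURIE_RE.match(curie)
    if not m or m.group(1) not in CURIE_PREFIXES:
        raise ResolutionError(f"unknown CURIE prefix in {curie!r}")
    return CURIE_PREFIXES[m.group(1)] + m.group(2)


def iri_to_curie(iri: str) -> str:
    for prefix, base in CURIE_PREFIXES.items():
        if iri.startswith(base):
            return f"{prefix}:{iri[len(base):]}"
    raise ResolutionError(f"IRI {iri!r} is not in a known namespace")


def is_curie(key: str) -> bool:
    m = _CURIE_RE.match(key)
    return bool(m) and m.group(1) in CURIE_PREFIXES


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

NAMESPACES = ("MRIO", "OBI", "IAO", "UBERON", "PROVISIONAL")
PROVENANCES = ("PAPER", "DEFAULT")
CONSTRAINT_KINDS = (
    "open_interval",
    "half_open",
    "equality",
    "categorical_membership",
    "presence",
)


@dataclass(frozen=True)
class TermRecord:
    """One named class with an optional single parent."""

    iri: str
    label: str
    definition: str = ""
    parent_iri: str | None = None
    namespace: str = "MRIO"
    synonyms: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "synonyms", tuple(sorted(self.synonyms)))


@dataclass(frozen=True)
class Constraint:
    """One atomic condition over a single acquisition parameter.

    Interval kinds use ``low``/``high`` with explicit inclusivity flags;
    the bundled facet bounds are exclusive on both sides, matching the
    OWL facet notation they were transcribed from.  ``equality`` carries a
    single ``value`` and, for numeric parameters, an absolute ``tolerance``.
    ``categorical_membership`` requires every member of ``allowed_values``
    to be present (set-valued parameters) or the observed value to be a
    member (scalar parameters).
    """

    parameter: str
    kind: str
    low: float | None = None
    high: float | None = None
    low_inclusive: bool = False
    high_inclusive: bool = False
    value: object = None
    allowed_values: frozenset | None = None
    tolerance: float = 0.0

    def __post_init__(self):
        if self.allowed_values is not None:
            object.__setattr__(
                self, "allowed_values", frozenset(self.allowed_values)
            )

    def describe(self) -> str:
        if self.kind in ("open_interval", "half_open"):
            parts = []
            if self.low is not None:
                parts.append(f"{'>=' if self.low_inclusive else '>'} {self.low}")
            if self.high is not None:
                parts.append(f"{'<=' if self.high_inclusive else '<'} {self.high}")
            return f"{self.parameter} {' and '.join(parts)}"
        if self.kind == "equality":
            tol = f" (±{self.tolerance})" if self.tolerance else ""
            return f"{self.parameter} = {self.value}{tol}"
        if self.kind == "categorical_membership":
            return f"{self.parameter} includes {sorted(self.allowed_values or ())}"
        return f"{self.parameter} present"


@dataclass(frozen=True)
class TypeAxiom:
    """Conjunction of constraints defining one acquisition type."""

    type_iri: str
    constraints: tuple[Constraint, ...]
    provenance: str = "PAPER"

    def __post_init__(self):
        object.__setattr__(self, "constraints", tuple(self.constraints))


@dataclass(frozen=True)
class AnalysisSpec:
    """An analysis with a DNF input expression over acquisition types."""

    iri: str
    label: str
    input_dnf: tuple[tuple[str, ...], ...]
    outputs: tuple[str, ...] = ()
    software_family: str = ""
    provenance: str = "PAPER"

    def __post_init__(self):
        # conjuncts are sets of required types; store members sorted so
        # document and RDF round-trips are order-stable
        object.__setattr__(
            self, "input_dnf", tuple(tuple(sorted(set(c))) for c in self.input_dnf)
        )
        object.__setattr__(self, "outputs", tuple(self.outputs))


@dataclass(frozen=True)
class TermBridge:
    """One DICOM tag ↔ BIDS key ↔ ontology IRI correspondence."""

    mrio_iri: str
    dicom_tag: tuple[int, int]
    bids_key: str
    unit_dicom: str = ""
    unit_bids: str = ""
    scale_dicom_to_bids: float = 1.0
    provenance: str = "PAPER"

    def __post_init__(self):
        object.__setattr__(self, "dicom_tag", tuple(self.dicom_tag))

    @property
    def tag_string(self) -> str:
        return f"{self.dicom_tag[0]:04X},{self.dicom_tag[1]:04X}"


@dataclass(frozen=True)
class AtlasRegion:
    region_label: str
    anatomy_xref: str


@dataclass(frozen=True)
class AtlasMap:
    atlas_iri: str
    regions: tuple[AtlasRegion, ...]

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))


@dataclass
class KnowledgeBase:
    """Container for the full term graph.

    Collections are stored as tuples so a knowledge base with injected
    defects (duplicate IRIs, dangling parents) can still be constructed and
    then diagnosed by :func:`validate_kb`.
    """

    terms: tuple[TermRecord, ...] = ()
    axioms: tuple[TypeAxiom, ...] = ()
    analyses: tuple[AnalysisSpec, ...] = ()
    bridge: tuple[TermBridge, ...] = ()
    atlases: tuple[AtlasMap, ...] = ()

    def __post_init__(self):
        self.terms = tuple(self.terms)
        self.axioms = tuple(self.axioms)
        self.analyses = tuple(self.analyses)
        self.bridge = tuple(self.bridge)
        self.atlases = tuple(self.atlases)
        self._term_index = None
        self._analysis_index = None

    # -- lookup helpers ----------------------------------------------------

    def _terms_by_iri(self) -> dict[str, TermRecord]:
        if self._term_index is None:
            idx = {}
            for t in self.terms:
                idx.setdefault(t.iri, t)  # first wins; dup reported by validate
            self._term_index = idx
        return self._term_index

    def term(self, iri: str) -> TermRecord:
        try:
            return self._terms_by_iri()[iri]
        except KeyError:
            raise NotFoundError(f"unknown term CURIE {iri!r}") from None

    def has_term(self, iri: str) -> bool:
        return iri in self._terms_by_iri()

    def analysis(self, iri: str) -> AnalysisSpec:
        if self._analysis_index is None:
            self._analysis_index = {a.iri: a for a in self.analyses}
        try:
            return self._analysis_index[iri]
        except KeyError:
            raise NotFoundError(f"unknown analysis CURIE {iri!r}") from None

    def axioms_for(self, type_iri: str) -> tuple[TypeAxiom, ...]:
        return tuple(a for a in self.axioms if a.type_iri == type_iri)

    def axiom_types(self) -> tuple[str, ...]:
        seen = []
        for a in self.axioms:
            if a.type_iri not in seen:
                seen.append(a.type_iri)
        return tuple(seen)


# ---------------------------------------------------------------------------
# Subsumption
# ---------------------------------------------------------------------------

def ancestors(kb: KnowledgeBase, iri: str) -> tuple[str, ...]:
    """Proper ancestors of ``iri``, nearest first. Cycles are truncated."""
    kb.term(iri)
    out, seen = [], {iri}
    cur = kb.term(iri).parent_iri
    while cur is not None and cur not in seen and kb.has_term(cur):
        out.append(cur)
        seen.add(cur)
        cur = kb.term(cur).parent_iri
    return tuple(out)


def subsumes(kb: KnowledgeBase, ancestor: str, descendant: str) -> bool:
    """True iff ``descendant`` is ``ancestor`` or lies below it.

    Reflexive and transitive over the explicit parent graph.
    """
    kb.term(ancestor)
    if ancestor == descendant:
        kb.term(descendant)
        return True
    return ancestor in ancestors(kb, descendant)


# ---------------------------------------------------------------------------
# Lookup
# ---------------------------------------------------------------------------

def _norm_label(s: str) -> str:
    return re.sub(r"\s+", " ", s.strip().lower())


_TAG_KEY_RE = re.compile(r"^\(?\s*([0-9A-Fa-f]{4})\s*,\s*([0-9A-Fa-f]{4})\s*\)?$")


def lookup_term(kb: KnowledgeBase, key: str) -> TermRecord:
    """Resolve a CURIE (case-sensitive), a label/synonym (case-insensitive),
    or a bridge key (DICOM tag string or BIDS sidecar key)."""
    if is_curie(key) and kb.has_term(key):
        return kb.term(key)
    m = _TAG_KEY_RE.match(key)
    if m:
        tag = (int(m.group(1), 16), int(m.group(2), 16))
        for entry in kb.bridge:
            if entry.dicom_tag == tag:
                return kb.term(entry.mrio_iri)
        raise NotFoundError(f"no bridge entry for DICOM tag {key!r}")
    for entry in kb.bridge:
        if entry.bids_key == key:
            return kb.term(entry.mrio_iri)
    norm = _norm_label(key)
    hits = [
        t
        for t in kb.terms
        if _norm_label(t.label) == norm
        or any(_norm_label(s) == norm for s in t.synonyms)
    ]
    if not hits:
        raise NotFoundError(f"no term matching {key!r}")
    if len({t.iri for t in hits}) > 1:
        raise AmbiguousLookupError(key, sorted({t.iri for t in hits}))
    return hits[0]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_kb(kb: KnowledgeBase) -> ValidationReport:
    """Structural validation. Never raises; returns a report."""
    from .ingest import PARAMETER_FIELDS  # local import avoids a cycle

    rep = ValidationReport()
    seen: set[str] = set()
    for t in kb.terms:
        if t.iri in seen:
            rep.errors.append(f"duplicate IRI {t.iri}")
        seen.add(t.iri)
        if t.namespace not in NAMESPACES:
            rep.errors.append(f"{t.iri}: unknown namespace {t.namespace!r}")
    index = {t.iri for t in kb.terms}
    for t in kb.terms:
        if t.parent_iri is not None and t.parent_iri not in index:
            rep.errors.append(f"{t.iri}: dangling parent {t.parent_iri}")
    # cycle detection over the parent graph
    for t in kb.terms:
        slow = t.iri
        trail = set()
        cur = t.iri
        while cur is not None and cur in index:
            if cur in trail:
                rep.errors.append(f"subsumption cycle through {cur}")
                break
            trail.add(cur)
            cur = kb._terms_by_iri()[cur].parent_iri
        del slow
    for ax in kb.axioms:
        if ax.type_iri not in index:
            rep.errors.append(f"axiom for unresolvable type {ax.type_iri}")
        if not ax.constraints:
            rep.errors.append(f"axiom for {ax.type_iri} has no constraints")
        if ax.provenance == "DEFAULT":
            rep.warnings.append(
                f"axiom for {ax.type_iri} has DEFAULT provenance "
                "(not transcribed from a printed facet expression)"
            )
        for c in ax.constraints:
            if c.parameter not in PARAMETER_FIELDS:
                rep.errors.append(
                    f"axiom for {ax.type_iri}: unknown parameter {c.parameter!r}"
                )
            if c.kind not in CONSTRAINT_KINDS:
                rep.errors.append(
                    f"axiom for {ax.type_iri}: unknown constraint kind {c.kind!r}"
                )
            if c.low is not None and c.high is not None and not c.low < c.high:
                rep.errors.append(
                    f"axiom for {ax.type_iri}: empty interval on {c.parameter}"
                )
            if c.kind == "equality" and c.value is None:
                rep.errors.append(
                    f"axiom for {ax.type_iri}: equality without a value"
                )
            if c.kind == "categorical_membership" and not c.allowed_values:
                rep.errors.append(
                    f"axiom for {ax.type_iri}: empty categorical constraint"
                )
    for a in kb.analyses:
        if not a.input_dnf:
            rep.errors.append(f"analysis {a.iri} has an empty input expression")
        for conj in a.input_dnf:
            if not conj:
                rep.errors.append(f"analysis {a.iri} has an empty conjunct")
            for req in conj:
                if req not in index:
                    rep.errors.append(
                        f"analysis {a.iri}: unresolvable input type {req}"
                    )
        if a.provenance == "DEFAULT":
            rep.warnings.append(
                f"analysis {a.iri} input expression has DEFAULT provenance"
            )
    pairs = set()
    for b in kb.bridge:
        key = (b.dicom_tag, b.bids_key)
        if key in pairs:
            rep.errors.append(f"duplicate bridge pair {b.tag_string}/{b.bids_key}")
        pairs.add(key)
        if b.scale_dicom_to_bids <= 0:
            rep.errors.append(f"bridge {b.bids_key}: non-positive unit scale")
        if b.mrio_iri not in index:
            rep.errors.append(f"bridge {b.bids_key}: unresolvable IRI {b.mrio_iri}")
        if b.provenance == "DEFAULT":
            rep.warnings.append(f"bridge entry {b.bids_key} has DEFAULT provenance")
    for atlas in kb.atlases:
        if atlas.atlas_iri not in index:
            rep.errors.append(f"atlas {atlas.atlas_iri} is not a term")
        labels = [r.region_label for r in atlas.regions]
        if len(labels) != len(set(labels)):
            rep.errors.append(f"atlas {atlas.atlas_iri}: duplicate region labels")
        for r in atlas.regions:
            if not r.anatomy_xref:
                rep.errors.append(
                    f"atlas {atlas.atlas_iri}: region {r.region_label!r} "
                    "lacks an anatomy cross-reference"
                )
    return rep


# ---------------------------------------------------------------------------
# Canonical ordering
# ---------------------------------------------------------------------------

def _canonical(kb: KnowledgeBase) -> KnowledgeBase:
    """Return an equal KB with collections in canonical sorted order."""
    return KnowledgeBase(
        terms=tuple(sorted(kb.terms, key=lambda t: t.iri)),
        axioms=tuple(sorted(kb.axioms, key=lambda a: a.type_iri)),
        analyses=tuple(sorted(kb.analyses, key=lambda a: a.iri)),
        bridge=tuple(sorted(kb.bridge, key=lambda b: b.bids_key)),
        atlases=tuple(sorted(kb.atlases, key=lambda a: a.atlas_iri)),
    )


def build_default_kb() -> KnowledgeBase:
    """The bundled knowledge base (deterministic across calls)."""
    from ._bundle import bundled_kb

    return _canonical(bundled_kb())


# ---------------------------------------------------------------------------
# Turtle export / parse
# ---------------------------------------------------------------------------

_TTL_PREFIXES = {
    "IAO": OBO + "IAO_",
    "MRIO": OBO + "MRIO_",
    "MRIOKIT": MKT,
    "OBI": OBO + "OBI_",
    "UBERON": OBO + "UBERON_",
    "mkn": MKN,
    "mkv": MKV,
    "owl": str(OWL),
    "rdf": str(RDF),
    "rdfs": str(RDFS),
    "xsd": "http://www.w3.org/2001/XMLSchema#",
}

_LOCAL_RE = re.compile(r"^[A-Za-z0-9_][A-Za-z0-9_.-]*$")


def _fmt_uri(iri: str) -> str:
    best = None
    for prefix, base in _TTL_PREFIXES.items():
        if iri.startswith(base):
            local = iri[len(base):]
            if _LOCAL_RE.match(local) and not local.endswith("."):
                cand = f"{prefix}:{local}"
                if best is None or len(base) > len(_TTL_PREFIXES[best.split(":")[0]]):
                    best = cand
    return best if best else f"<{iri}>"


def _fmt_obj(obj) -> str:
    if isinstance(obj, str) and obj.startswith("uri:"):
        return _fmt_uri(obj[4:])
    if isinstance(obj, bool):
        return "true" if obj else "false"
    if isinstance(obj, int):
        return str(obj)
    if isinstance(obj, float):
        return f'"{obj!r}"^^xsd:double'
    s = str(obj)
    s = s.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n")
    return f'"{s}"'


def _u(curie_or_iri: str) -> str:
    """Mark a value as a URI object for the canonical writer."""
    iri = curie_to_iri(curie_or_iri) if is_curie(curie_or_iri) else curie_or_iri
    return "uri:" + iri


def _node(kind: str, *parts) -> str:
    local = "-".join([kind, *[str(p).replace(":", "_") for p in parts]])
    return "uri:" + MKN + local


_IAO_DEF = OBO + "IAO_0000115"
_IAO_ABOUT = OBO + "IAO_0000136"


def _kb_triples(kb: KnowledgeBase) -> list[tuple[str, str, object]]:
    tr: list[tuple[str, str, object]] = []
    term_iris = {t.iri for t in kb.terms}

    def add(s, p, o):
        tr.append((s, p, o))

    for t in kb.terms:
        s = _u(t.iri)
        add(s, _u(str(RDF.type)), _u(str(OWL.Class)))
        add(s, _u(str(RDFS.label)), t.label)
        add(s, _u(MKV + "namespace"), t.namespace)
        if t.definition:
            add(s, _u(_IAO_DEF), t.definition)
        if t.parent_iri is not None:
            add(s, _u(str(RDFS.subClassOf)), _u(t.parent_iri))
        for syn in t.synonyms:
            add(s, _u(MKV + "synonym"), syn)

    by_type: dict[str, int] = {}
    for ax in kb.axioms:
        j = by_type.get(ax.type_iri, 0)
        by_type[ax.type_iri] = j + 1
        a = _node("axiom", ax.type_iri, j)
        add(_u(ax.type_iri), _u(MKV + "hasTypeAxiom"), a)
        add(a, _u(str(RDF.type)), _u(MKV + "TypeAxiom"))
        add(a, _u(MKV + "index"), j)
        add(a, _u(MKV + "provenance"), ax.provenance)
        for k, c in enumerate(ax.constraints):
            cn = _node("constraint", ax.type_iri, j, k)
            add(a, _u(MKV + "hasConstraint"), cn)
            add(cn, _u(MKV + "index"), k)
            add(cn, _u(MKV + "parameter"), c.parameter)
            add(cn, _u(MKV + "kind"), c.kind)
            if c.low is not None:
                add(cn, _u(MKV + "low"), float(c.low))
                add(cn, _u(MKV + "lowInclusive"), c.low_inclusive)
            if c.high is not None:
                add(cn, _u(MKV + "high"), float(c.high))
                add(cn, _u(MKV + "highInclusive"), c.high_inclusive)
            if c.value is not None:
                add(cn, _u(MKV + "value"), c.value)
            if c.tolerance:
                add(cn, _u(MKV + "tolerance"), float(c.tolerance))
            for v in sorted(c.allowed_values or ()):
                add(cn, _u(MKV + "allows"), v)

    for an in kb.analyses:
        s = _u(an.iri)
        add(s, _u(str(RDF.type)), _u(MKV + "AnalysisSpec"))
        if an.iri not in term_iris:
            add(s, _u(str(RDFS.label)), an.label)
        if an.software_family:
            add(s, _u(MKV + "softwareFamily"), an.software_family)
        add(s, _u(MKV + "provenance"), an.provenance)
        for i, conj in enumerate(an.input_dnf):
            cn = _node("conjunct", an.iri, i)
            add(s, _u(MKV + "hasInputConjunct"), cn)
            add(cn, _u(MKV + "index"), i)
            add(cn, _u(MKV + "conjunctSize"), len(conj))
            for req in conj:
                add(cn, _u(MKV + "requiresType"), _u(req))
        for i, out in enumerate(an.outputs):
            on = _node("output", an.iri, i)
            add(s, _u(MKV + "hasOutput"), on)
            add(on, _u(MKV + "index"), i)
            add(on, _u(MKV + "outputLabel"), out)

    for b in kb.bridge:
        bn = _node("bridge", b.bids_key)
        add(bn, _u(str(RDF.type)), _u(MKV + "BridgeEntry"))
        add(bn, _u(MKV + "bridgesTerm"), _u(b.mrio_iri))
        add(bn, _u(MKV + "dicomGroup"), b.dicom_tag[0])
        add(bn, _u(MKV + "dicomElement"), b.dicom_tag[1])
        add(bn, _u(MKV + "bidsKey"), b.bids_key)
        add(bn, _u(MKV + "unitDicom"), b.unit_dicom)
        add(bn, _u(MKV + "unitBids"), b.unit_bids)
        add(bn, _u(MKV + "scale"), float(b.scale_dicom_to_bids))
        add(bn, _u(MKV + "provenance"), b.provenance)

    for atlas in kb.atlases:
        s = _u(atlas.atlas_iri)
        add(s, _u(str(RDF.type)), _u(MKV + "AtlasMap"))
        for k, r in enumerate(atlas.regions):
            rn = _node("region", atlas.atlas_iri, k)
            add(s, _u(MKV + "hasRegion"), rn)
            add(rn, _u(MKV + "index"), k)
            add(rn, _u(MKV + "regionLabel"), r.region_label)
            add(rn, _u(MKV + "anatomyXref"), r.anatomy_xref)
            if r.anatomy_xref.startswith("UBERON:"):
                add(s, _u(_IAO_ABOUT), _u(r.anatomy_xref))
    return tr


def export_rdf(kb: KnowledgeBase) -> str:
    """Serialize the KB as canonical Turtle text.

    Subjects, predicates, and objects are emitted in a fixed sort order so
    the serialization is a pure function of KB content; re-parsing with any
    Turtle parser and re-exporting yields byte-identical text.
    """
    report = validate_kb(kb)
    if not report.ok:
        raise KBValidationError(report)
    triples = set(_kb_triples(kb))
    rdf_type = _fmt_uri(str(RDF.type))
    grouped: dict[str, dict[str, set[str]]] = {}
    for s, p, o in triples:
        sf = _fmt_obj(s)
        pf = _fmt_obj(p)
        pf = "a" if pf == rdf_type else pf
        grouped.setdefault(sf, {}).setdefault(pf, set()).add(_fmt_obj(o))
    lines = [
        f"@prefix {p}: <{ns}> ." for p, ns in sorted(_TTL_PREFIXES.items())
    ]
    lines.append("")
    for sf in sorted(grouped):
        preds = grouped[sf]
        keys = sorted(preds, key=lambda k: (k != "a", k))
        body = [f"    {p} {', '.join(sorted(preds[p]))}" for p in keys]
        lines.append(sf + " " + " ;\n".join(body).lstrip() + " .")
    return "\n".join(lines) + "\n"


def _py(lit):
    v = lit.toPython()
    if isinstance(v, str):
        return str(v)
    return v


def parse_rdf(text: str) -> KnowledgeBase:
    """Parse Turtle text produced by :func:`export_rdf` back into a KB."""
    g = Graph()
    try:
        g.parse(data=text, format="turtle")
    except Exception as exc:  # rdflib raises parser-specific errors
        raise FormatError(f"not parseable as Turtle: {exc}") from exc

    def curie(ref) -> str:
        return iri_to_curie(str(ref))

    def one(s, p):
        for o in g.objects(s, URIRef(p)):
            return o
        return None

    terms = []
    for s in g.subjects(RDF.type, OWL.Class):
        terms.append(
            TermRecord(
                iri=curie(s),
                label=str(one(s, str(RDFS.label))),
                definition=str(one(s, _IAO_DEF) or ""),
                parent_iri=(
                    curie(one(s, str(RDFS.subClassOf)))
                    if one(s, str(RDFS.subClassOf)) is not None
                    else None
                ),
                namespace=str(one(s, MKV + "namespace")),
                synonyms=tuple(
                    str(v) for v in g.objects(s, URIRef(MKV + "synonym"))
                ),
            )
        )

    axioms = []
    for t, _, a in g.triples((None, URIRef(MKV + "hasTypeAxiom"), None)):
        cons = []
        for cn in g.objects(a, URIRef(MKV + "hasConstraint")):
            allowed = frozenset(
                str(v) for v in g.objects(cn, URIRef(MKV + "allows"))
            )
            low = one(cn, MKV + "low")
            high = one(cn, MKV + "high")
            tol = one(cn, MKV + "tolerance")
            val = one(cn, MKV + "value")
            cons.append(
                (
                    _py(one(cn, MKV + "index")),
                    Constraint(
                        parameter=str(one(cn, MKV + "parameter")),
                        kind=str(one(cn, MKV + "kind")),
                        low=_py(low) if low is not None else None,
                        high=_py(high) if high is not None else None,
                        low_inclusive=bool(_py(one(cn, MKV + "lowInclusive")))
                        if one(cn, MKV + "lowInclusive") is not None
                        else False,
                        high_inclusive=bool(_py(one(cn, MKV + "highInclusive")))
                        if one(cn, MKV + "highInclusive") is not None
                        else False,
                        value=_py(val) if val is not None else None,
                        allowed_values=allowed or None,
                        tolerance=_py(tol) if tol is not None else 0.0,
                    ),
                )
            )
        cons.sort(key=lambda kv: kv[0])
        axioms.append(
            (
                curie(t),
                _py(one(a, MKV + "index")),
                TypeAxiom(
                    type_iri=curie(t),
                    constraints=tuple(c for _, c in cons),
                    provenance=str(one(a, MKV + "provenance")),
                ),
            )
        )
    axioms.sort(key=lambda kv: (kv[0], kv[1]))

    analyses = []
    for s in g.subjects(RDF.type, URIRef(MKV + "AnalysisSpec")):
        conjuncts = []
        for cn in g.objects(s, URIRef(MKV + "hasInputConjunct")):
            reqs = sorted(
                curie(r) for r in g.objects(cn, URIRef(MKV + "requiresType"))
            )
            conjuncts.append((_py(one(cn, MKV + "index")), tuple(reqs)))
        conjuncts.sort(key=lambda kv: kv[0])
        outs = []
        for on in g.objects(s, URIRef(MKV + "hasOutput")):
            outs.append(
                (_py(one(on, MKV + "index")), str(one(on, MKV + "outputLabel")))
            )
        outs.sort(key=lambda kv: kv[0])
        analyses.append(
            AnalysisSpec(
                iri=curie(s),
                label=str(one(s, str(RDFS.label))),
                input_dnf=tuple(c for _, c in conjuncts),
                outputs=tuple(o for _, o in outs),
                software_family=str(one(s, MKV + "softwareFamily") or ""),
                provenance=str(one(s, MKV + "provenance")),
            )
        )

    bridge = []
    for bn in g.subjects(RDF.type, URIRef(MKV + "BridgeEntry")):
        bridge.append(
            TermBridge(
                mrio_iri=curie(one(bn, MKV + "bridgesTerm")),
                dicom_tag=(
                    _py(one(bn, MKV + "dicomGroup")),
                    _py(one(bn, MKV + "dicomElement")),
                ),
                bids_key=str(one(bn, MKV + "bidsKey")),
                unit_dicom=str(one(bn, MKV + "unitDicom")),
                unit_bids=str(one(bn, MKV + "unitBids")),
                scale_dicom_to_bids=float(_py(one(bn, MKV + "scale"))),
                provenance=str(one(bn, MKV + "provenance")),
            )
        )

    atlases = []
    for s in g.subjects(RDF.type, URIRef(MKV + "AtlasMap")):
        regions = []
        for rn in g.objects(s, URIRef(MKV + "hasRegion")):
            regions.append(
                (
                    _py(one(rn, MKV + "index")),
                    AtlasRegion(
                        region_label=str(one(rn, MKV + "regionLabel")),
                        anatomy_xref=str(one(rn, MKV + "anatomyXref")),
                    ),
                )
            )
        regions.sort(key=lambda kv: kv[0])
        atlases.append(
            AtlasMap(atlas_iri=curie(s), regions=tuple(r for _, r in regions))
        )

    # Constraint equality expects float bounds; normalize integers parsed
    # from typed literals (writer always emits doubles, so this is a no-op
    # for our own output but tolerates hand-written documents).
    axioms2 = []
    for _, _, ax in axioms:
        axioms2.append(
            replace(
                ax,
                constraints=tuple(
                    replace(
                        c,
                        low=float(c.low) if c.low is not None else None,
                        high=float(c.high) if c.high is not None else None,
                        tolerance=float(c.tolerance),
                    )
                    for c in ax.constraints
                ),
            )
        )

    return _canonical(
        KnowledgeBase(
            terms=tuple(terms),
            axioms=tuple(axioms2),
            analyses=tuple(analyses),
            bridge=tuple(bridge),
            atlases=tuple(atlases),
        )
    )


# ---------------------------------------------------------------------------
# Dict / YAML / JSON document form
# ---------------------------------------------------------------------------

def kb_to_dict(kb: KnowledgeBase) -> dict:
    """Plain-document form of the KB (see docs/kb_schema.json)."""
    def term_d(t):
        d = {"iri": t.iri, "label": t.label, "namespace": t.namespace}
        if t.definition:
            d["definition"] = t.definition
        if t.parent_iri:
            d["parent_iri"] = t.parent_iri
        if t.synonyms:
            d["synonyms"] = list(t.synonyms)
        return d

    def con_d(c):
        d = {"parameter": c.parameter, "kind": c.kind}
        if c.low is not None:
            d["low"] = c.low
            d["low_inclusive"] = c.low_inclusive
        if c.high is not None:
            d["high"] = c.high
            d["high_inclusive"] = c.high_inclusive
        if c.value is not None:
            d["value"] = c.value
        if c.allowed_values:
            d["allowed_values"] = sorted(c.allowed_values)
        if c.tolerance:
            d["tolerance"] = c.tolerance
        return d

    return {
        "mriokit_kb": 1,
        "terms": [term_d(t) for t in kb.terms],
        "axioms": [
            {
                "type_iri": a.type_iri,
                "provenance": a.provenance,
                "constraints": [con_d(c) for c in a.constraints],
            }
            for a in kb.axioms
        ],
        "analyses": [
            {
                "iri": a.iri,
                "label": a.label,
                "input_dnf": [list(c) for c in a.input_dnf],
                "outputs": list(a.outputs),
                "software_family": a.software_family,
                "provenance": a.provenance,
            }
            for a in kb.analyses
        ],
        "bridge": [
            {
                "mrio_iri": b.mrio_iri,
                "dicom_tag": b.tag_string,
                "bids_key": b.bids_key,
                "unit_dicom": b.unit_dicom,
                "unit_bids": b.unit_bids,
                "scale_dicom_to_bids": b.scale_dicom_to_bids,
                "provenance": b.provenance,
            }
            for b in kb.bridge
        ],
        "atlases": [
            {
                "atlas_iri": a.atlas_iri,
                "regions": [
                    {"region_label": r.region_label, "anatomy_xref": r.anatomy_xref}
                    for r in a.regions
                ],
            }
            for a in kb.atlases
        ],
    }


def kb_from_dict(doc: dict) -> KnowledgeBase:
    if not isinstance(doc, dict) or doc.get("mriokit_kb") != 1:
        raise FormatError("not a mriokit KB document (missing 'mriokit_kb: 1')")

    def con(d):
        return Constraint(
            parameter=d["parameter"],
            kind=d["kind"],
            low=float(d["low"]) if "low" in d else None,
            high=float(d["high"]) if "high" in d else None,
            low_inclusive=bool(d.get("low_inclusive", False)),
            high_inclusive=bool(d.get("high_inclusive", False)),
            value=d.get("value"),
            allowed_values=frozenset(d["allowed_values"])
            if d.get("allowed_values")
            else None,
            tolerance=float(d.get("tolerance", 0.0)),
        )

    def tag(s):
        m = _TAG_KEY_RE.match(s)
        if not m:
            raise FormatError(f"bad DICOM tag string {s!r}")
        return (int(m.group(1), 16), int(m.group(2), 16))

    return _canonical(
        KnowledgeBase(
            terms=tuple(
                TermRecord(
                    iri=d["iri"],
                    label=d["label"],
                    definition=d.get("definition", ""),
                    parent_iri=d.get("parent_iri"),
                    namespace=d.get("namespace", "MRIO"),
                    synonyms=tuple(d.get("synonyms", ())),
                )
                for d in doc.get("terms", ())
            ),
            axioms=tuple(
                TypeAxiom(
                    type_iri=d["type_iri"],
                    constraints=tuple(con(c) for c in d.get("constraints", ())),
                    provenance=d.get("provenance", "DEFAULT"),
                )
                for d in doc.get("axioms", ())
            ),
            analyses=tuple(
                AnalysisSpec(
                    iri=d["iri"],
                    label=d["label"],
                    input_dnf=tuple(tuple(c) for c in d.get("input_dnf", ())),
                    outputs=tuple(d.get("outputs", ())),
                    software_family=d.get("software_family", ""),
                    provenance=d.get("provenance", "DEFAULT"),
                )
                for d in doc.get("analyses", ())
            ),
            bridge=tuple(
                TermBridge(
                    mrio_iri=d["mrio_iri"],
                    dicom_tag=tag(d["dicom_tag"]),
                    bids_key=d["bids_key"],
                    unit_dicom=d.get("unit_dicom", ""),
                    unit_bids=d.get("unit_bids", ""),
                    scale_dicom_to_bids=float(d.get("scale_dicom_to_bids", 1.0)),
                    provenance=d.get("provenance", "DEFAULT"),
                )
                for d in doc.get("bridge", ())
            ),
            atlases=tuple(
                AtlasMap(
                    atlas_iri=d["atlas_iri"],
                    regions=tuple(
                        AtlasRegion(r["region_label"], r["anatomy_xref"])
                        for r in d.get("regions", ())
                    ),
                )
                for d in doc.get("atlases", ())
            ),
        )
    )


def load_kb(path) -> KnowledgeBase:
    """Load a KB from a YAML or JSON document on disk."""
    text = open(path, encoding="utf-8").read()
    try:
        doc = yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return kb_from_dict(doc)


def save_kb(kb: KnowledgeBase, path) -> None:
    p = str(path)
    doc = kb_to_dict(kb)
    with open(p, "w", encoding="utf-8") as fh:
        if p.endswith(".json"):
            json.dump(doc, fh, indent=2, sort_keys=False)
            fh.write("\n")
        else:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
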