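"""Automated analysis assignment from available acquisition types.

An analysis is assignable when some conjunct of its disjunctive-normal-form
input expression is fully covered: every required type has an available
type at or below it in the class hierarchy (a T2 FLAIR series satisfies a
requirement for a T2-weighted data set, because the requirement names a
class and the series instantiates a subclass).

Two equivalent execution modes are provided:

* :func:`assign_analyses` — native evaluation over the in-memory KB;
* :func:`graph_query_mode` — the same three-stage procedure run as SPARQL
  queries over the Turtle export (stage 1 filters/canonicalizes the
  available types, stage 2 collects analyses satisfiable through a single
  required input, stage 3 those requiring several).  The two modes are
  cross-checked against each other in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from rdflib import Graph

from .errors import NotFoundError, ResolutionError
from .knowledge_base import (
    AnalysisSpec,
    KnowledgeBase,
    _norm_label,
    curie_to_iri,
    export_rdf,
    iri_to_curie,
    is_curie,
    subsumes,
)


@dataclass(frozen=True)
class Explanation:
    analysis_iri: str
    assignable: bool
    conjunct: tuple[str, ...] = ()
    witnesses: dict[str, str] = field(default_factory=dict)
    satisfied_conjuncts: tuple[tuple[str, ...], ...] = ()
    missing: dict[tuple[str, ...], tuple[str, ...]] = field(default_factory=dict)


@dataclass
class AssignmentResult:
    assignments: dict[str, str]  # analysis CURIE -> label
    explanations: dict[str, Explanation]
    warnings: list[str] = field(default_factory=list)

    def __eq__(self, other):
        if not isinstance(other, AssignmentResult):
            return NotImplemented
        return (
            self.assignments == other.assignments
            and self.explanations == other.explanations
            and sorted(self.warnings) == sorted(other.warnings)
        )


# ---------------------------------------------------------------------------
# Availability canonicalization (stage 1)
# ---------------------------------------------------------------------------

def _resolve_type_key(kb: KnowledgeBase, key: str) -> str | None:
    """Resolve a CURIE, label, or synonym to a term CURIE; None if unknown.

    Mirrors the stage-1 SPARQL filter exactly: bridge keys deliberately do
    not resolve here.
    """
    if is_curie(key) and kb.has_term(key):
        return key
    norm = _norm_label(key)
    for t in kb.terms:
        if _norm_label(t.label) == norm or any(
            _norm_label(s) == norm for s in t.synonyms
        ):
            return t.iri
    return None


def _canonical_available(kb, available) -> tuple[list[str], list[str]]:
    resolved, warnings = set(), []
    for key in available:
        iri = _resolve_type_key(kb, str(key))
        if iri is None:
            warnings.append(f"dropping unknown type {key!r}")
        else:
            resolved.add(iri)
    return sorted(resolved), warnings


# ---------------------------------------------------------------------------
# Native mode
# ---------------------------------------------------------------------------

def satisfied_conjuncts(
    kb: KnowledgeBase,
    analysis: AnalysisSpec,
    available,
) -> list[tuple[str, ...]]:
    """All conjuncts of the analysis input expression covered by
    ``available`` (a set of type CURIEs), in declaration order."""
    avail = sorted(set(available))
    for a in avail:
        kb.term(a)  # unresolvable CURIE -> ResolutionError
    out = []
    for conj in analysis.input_dnf:
        if all(any(subsumes(kb, req, a) for a in avail) for req in conj):
            out.append(conj)
    return out


def _explanation_for(kb, analysis, avail) -> Explanation:
    sat = satisfied_conjuncts(kb, analysis, avail)
    if not sat:
        missing = {}
        for conj in analysis.input_dnf:
            gaps = tuple(
                req
                for req in conj
                if not any(subsumes(kb, req, a) for a in avail)
            )
            missing[conj] = gaps
        return Explanation(analysis.iri, assignable=False, missing=missing)
    # prefer the smallest satisfied conjunct; ties resolved by spec order
    best = min(sat, key=lambda c: (len(c), analysis.input_dnf.index(c)))
    witnesses = {
        req: next(a for a in avail if subsumes(kb, req, a)) for req in best
    }
    return Explanation(
        analysis.iri,
        assignable=True,
        conjunct=best,
        witnesses=witnesses,
        satisfied_conjuncts=tuple(sat),
    )


def assign_analyses(kb: KnowledgeBase, available) -> AssignmentResult:
    """Return every analysis whose input expression is satisfiable.

    ``available`` may mix CURIEs, labels, and synonyms; unresolvable
    entries are dropped with a warning rather than failing the call.
    """
    avail, warnings = _canonical_available(kb, available)
    assignments, explanations = {}, {}
    for analysis in kb.analyses:
        exp = _explanation_for(kb, analysis, avail)
        if exp.assignable:
            assignments[analysis.iri] = analysis.label
            explanations[analysis.iri] = exp
    return AssignmentResult(assignments, explanations, warnings)


def explain_assignment(kb: KnowledgeBase, analysis_key: str, available) -> Explanation:
    """Why an analysis is (or is not) assignable for the availability."""
    try:
        analysis = kb.analysis(analysis_key)
    except NotFoundError:
        iri = _resolve_type_key(kb, analysis_key)
        if iri is None:
            raise ResolutionError(f"unknown analysis {analysis_key!r}") from None
        analysis = kb.analysis(iri)
    avail, _ = _canonical_available(kb, available)
    return _explanation_for(kb, analysis, avail)


# ---------------------------------------------------------------------------
# Graph-query mode
# ---------------------------------------------------------------------------

def _load_query(name: str) -> str:
    return (
        resources.files("mriokit").joinpath("queries", name).read_text()
    )


def _sparql_literal(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


_GRAPH_CACHE: dict[int, tuple[KnowledgeBase, Graph]] = {}


def _graph_for(kb: KnowledgeBase) -> Graph:
    cached = _GRAPH_CACHE.get(id(kb))
    if cached is not None and cached[0] is kb:
        return cached[1]
    g = Graph()
    g.parse(data=export_rdf(kb), format="turtle")
    _GRAPH_CACHE.clear()
    _GRAPH_CACHE[id(kb)] = (kb, g)
    return g


def graph_query_mode(kb: KnowledgeBase, available) -> AssignmentResult:
    """Three-stage assignment executed as SPARQL over the RDF export."""
    g = _graph_for(kb)
    keys = []
    for key in available:
        key = str(key)
        if is_curie(key):
            try:
                keys.append((key, curie_to_iri(key)))
                continue
            except ResolutionError:
                pass
        keys.append((key, key))
    if keys:
        values = " ".join(_sparql_literal(k) for _, k in keys)
        q1 = _load_query("stage1_filter_types.rq").replace("%KEYS%", values)
        rows = list(g.query(q1))
        resolved_iris = sorted({str(r[0]) for r in rows})
        matched_keys = {str(r[1]) for r in rows}
    else:
        resolved_iris, matched_keys = [], set()
    warnings = [
        f"dropping unknown type {orig!r}"
        for orig, injected in keys
        if injected not in matched_keys
    ]
    avail = [iri_to_curie(i) for i in resolved_iris]

    assigned: set[str] = set()
    if avail:
        values = " ".join(f"<{curie_to_iri(a)}>" for a in avail)
        for qname in ("stage2_single_input.rq", "stage3_multi_input.rq"):
            q = _load_query(qname).replace("%AVAILABLE%", values)
            for row in g.query(q):
                assigned.add(iri_to_curie(str(row[0])))

    assignments, explanations = {}, {}
    for analysis in kb.analyses:  # preserve native ordering
        if analysis.iri in assigned:
            assignments[analysis.iri] = analysis.label
            explanations[analysis.iri] = _explanation_for(kb, analysis, avail)
    return AssignmentResult(assignments, explanations, warnings)
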