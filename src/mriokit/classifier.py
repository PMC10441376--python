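"""Rule evaluation: assigning acquisition types to parameter records.

Each acquisition type is defined by one or more :class:`TypeAxiom`
conjunctions of constraints; a type matches a series when any of its
axioms is fully satisfied.  Interval bounds follow OWL facet semantics —
the bundled bounds are exclusive exactly as printed, so e.g. a repetition
time of 800 ms falls outside the T1-weighted interval (0, 800).

Missing parameters evaluate to *indeterminate*.  The ``strict`` policy
(default) counts indeterminate as unsatisfied — a conservative refusal to
classify on absent evidence — while ``lenient`` counts it as satisfied.

The classifier reports the most specific matching types: when a subtype
matches (e.g. T2 FLAIR), its ancestors are implied through the reported
lineage and never listed alongside it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import EmptyInputError, SchemaError
from .ingest import PARAMETER_FIELDS, AcquisitionParameters
from .knowledge_base import Constraint, KnowledgeBase, TypeAxiom, ancestors

POLICIES = ("strict", "lenient")


@dataclass(frozen=True)
class ConstraintOutcome:
    parameter: str
    satisfied: bool | None  # None = indeterminate (parameter absent)
    observed: object
    bound: str


@dataclass(frozen=True)
class MatchResult:
    type_iri: str
    matched: bool
    outcomes: tuple[ConstraintOutcome, ...]


@dataclass(frozen=True)
class ClassificationResult:
    series_id: str
    matched_types: frozenset[str]
    lineage: dict[str, tuple[str, ...]]
    policy: str
    details: tuple[MatchResult, ...] = ()


def _observe(params: AcquisitionParameters, parameter: str):
    """Return (present, value-for-comparison, raw observed)."""
    if parameter not in PARAMETER_FIELDS:
        raise SchemaError(f"axiom references unknown parameter {parameter!r}")
    raw = getattr(params, parameter)
    if raw is None:
        return False, None, None
    if parameter == "scanning_sequence":
        if not raw:
            return False, None, raw  # empty code set = tag absent
        return True, raw, raw
    if parameter == "b_values":
        if len(raw) == 0:
            return False, None, raw
        return True, max(raw), raw  # interval constraints apply to max(b)
    return True, raw, raw


def _check(c: Constraint, value) -> bool:
    if c.kind in ("open_interval", "half_open"):
        v = float(value)
        if c.low is not None:
            if v < c.low or (v == c.low and not c.low_inclusive):
                return False
        if c.high is not None:
            if v > c.high or (v == c.high and not c.high_inclusive):
                return False
        return True
    if c.kind == "equality":
        if isinstance(c.value, bool) or isinstance(value, bool):
            return bool(value) is bool(c.value)
        if isinstance(c.value, (int, float)):
            return abs(float(value) - float(c.value)) <= c.tolerance
        return value == c.value
    if c.kind == "categorical_membership":
        allowed = c.allowed_values or frozenset()
        if isinstance(value, (set, frozenset)):
            return allowed <= value
        return value in allowed
    if c.kind == "presence":
        return True  # reaching here means the parameter was present
    raise SchemaError(f"unknown constraint kind {c.kind!r}")


def evaluate_axiom(
    axiom: TypeAxiom,
    params: AcquisitionParameters,
    policy: str = "strict",
) -> MatchResult:
    """Evaluate every constraint of one axiom against one series."""
    if policy not in POLICIES:
        raise SchemaError(f"unknown policy {policy!r}")
    outcomes = []
    for c in axiom.constraints:
        present, value, raw = _observe(params, c.parameter)
        if not present:
            satisfied: bool | None = None
        else:
            satisfied = _check(c, value)
        outcomes.append(
            ConstraintOutcome(
                parameter=c.parameter,
                satisfied=satisfied,
                observed=raw,
                bound=c.describe(),
            )
        )
    if policy == "strict":
        matched = all(o.satisfied is True for o in outcomes)
    else:
        matched = all(o.satisfied is not False for o in outcomes)
    return MatchResult(axiom.type_iri, matched, tuple(outcomes))


def classify_series(
    kb: KnowledgeBase,
    params: AcquisitionParameters,
    policy: str = "strict",
    series_id: str | None = None,
) -> ClassificationResult:
    """Assign the most specific matching acquisition types to one series."""
    details = tuple(evaluate_axiom(ax, params, policy) for ax in kb.axioms)
    matched = {d.type_iri for d in details if d.matched}
    anc = {t: ancestors(kb, t) for t in matched}
    most_specific = frozenset(
        t for t in matched if not any(t in anc[o] for o in matched if o != t)
    )
    return ClassificationResult(
        series_id=series_id or params.series_id or "series",
        matched_types=most_specific,
        lineage={t: anc[t] for t in most_specific},
        policy=policy,
        details=details,
    )


def classify_dataset(
    kb: KnowledgeBase,
    series: list[AcquisitionParameters],
    policy: str = "strict",
) -> tuple[list[ClassificationResult], dict[str, int]]:
    """Classify every series in order and tally matches per type.

    A series matching no axiom is counted under ``"unclassified"``.
    """
    if not series:
        raise EmptyInputError("cannot classify an empty dataset")
    results = [
        classify_series(kb, p, policy, series_id=p.series_id or f"series-{i}")
        for i, p in enumerate(series)
    ]
    counts: Counter[str] = Counter()
    for r in results:
        if r.matched_types:
            counts.update(r.matched_types)
        else:
            counts["unclassified"] += 1
    return results, dict(counts)
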