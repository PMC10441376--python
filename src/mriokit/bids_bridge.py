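"""DICOM ↔ BIDS bridging and BIDS-style dataset organization.

The bridge table in the knowledge base gives every acquisition parameter a
stable ontology IRI connecting its DICOM tag (e.g. (0018,0081)) with its
BIDS sidecar key (e.g. ``EchoTime``), including the unit convention on each
side.  On top of that, this module plans — without touching the
filesystem — how a set of classified series maps onto a BIDS layout:
``sub-<label>[/ses-<label>]/<datatype>/..._<suffix>.nii.gz`` with sidecars
carrying converted values plus an ``MRIOAnnotations`` block, and derivative
metadata for assigned analyses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .assigner import AssignmentResult
from .classifier import ClassificationResult
from .errors import CollisionError, NoConventionError, NotFoundError
from .ingest import FIELD_BY_IRI, AcquisitionParameters
from .knowledge_base import KnowledgeBase, TermBridge, build_default_kb

#: datatype directory and filename suffix per acquisition data-set type
SUFFIX_BY_TYPE = {
    "MRIO:0000366": ("anat", "T1w"),
    "MRIO:0000367": ("anat", "T2w"),
    "MRIO:0000511": ("anat", "FLAIR"),
    "MRIOKIT:pd-mri-data-set": ("anat", "PDw"),
    "MRIOKIT:fmri-data-set": ("func", "bold"),
    "MRIOKIT:dwi-mri-data-set": ("dwi", "dwi"),
}

_LABEL_RE = re.compile(r"^[a-zA-Z0-9]+$")


def dicom_tag_to_bids_key(
    kb: KnowledgeBase, tag: tuple[int, int] | str
) -> tuple[str, str]:
    """Map a DICOM tag to its BIDS sidecar key and bridging IRI."""
    if isinstance(tag, str):
        from .ingest import _normalize_tag

        tag = _normalize_tag(tag)
    tag = (int(tag[0]), int(tag[1]))
    for entry in kb.bridge:
        if entry.dicom_tag == tag:
            return entry.bids_key, entry.mrio_iri
    hint = "acquisition parameters live in groups 0018/0020"
    raise NotFoundError(
        f"no bridge entry for tag ({tag[0]:04X},{tag[1]:04X}); {hint}"
    )


def bids_key_to_dicom_tag(
    kb: KnowledgeBase, key: str
) -> tuple[tuple[int, int], str]:
    """Inverse of :func:`dicom_tag_to_bids_key`."""
    for entry in kb.bridge:
        if entry.bids_key == key:
            return entry.dicom_tag, entry.mrio_iri
    raise NotFoundError(f"no bridge entry for BIDS key {key!r}")


def suffix_for_type(kb: KnowledgeBase, type_iri: str) -> tuple[str, str]:
    """BIDS (datatype directory, filename suffix) for an acquisition type.

    Subtypes inherit the convention of their nearest mapped ancestor
    (T1 SPGR files as T1w).
    """
    kb.term(type_iri)
    cur: str | None = type_iri
    while cur is not None:
        if cur in SUFFIX_BY_TYPE:
            return SUFFIX_BY_TYPE[cur]
        cur = kb.term(cur).parent_iri if kb.has_term(cur) else None
    raise NoConventionError(f"no BIDS naming convention for {type_iri}")


@dataclass(frozen=True)
class BidsEntry:
    series_id: str
    subject: str
    session: str | None
    datatype: str
    suffix: str
    target_path: str
    sidecar: dict


@dataclass
class BidsPlan:
    entries: list[BidsEntry] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def paths(self) -> list[str]:
        return [e.target_path for e in self.entries]


def _sidecar_for(
    kb: KnowledgeBase, params: AcquisitionParameters, type_iri: str
) -> dict:
    """BIDS sidecar content: bridged keys in BIDS units + annotations."""
    by_field: dict[str, TermBridge] = {}
    for entry in kb.bridge:
        f = FIELD_BY_IRI.get(entry.mrio_iri)
        if f:
            by_field[f] = entry
    doc: dict = {}
    used: dict[str, str] = {}
    for fieldname, entry in by_field.items():
        if fieldname == "_spacing_mm":
            continue
        value = getattr(params, fieldname, None)
        if value is None or (isinstance(value, frozenset) and not value):
            continue
        if fieldname in ("tr_ms", "te_ms", "ti_ms"):
            doc[entry.bids_key] = value * entry.scale_dicom_to_bids
        elif fieldname == "scanning_sequence":
            doc[entry.bids_key] = sorted(value)
        elif fieldname == "b_values":
            doc[entry.bids_key] = list(value)
        elif fieldname == "has_diffusion_gradients":
            if value:
                doc[entry.bids_key] = "DIRECTIONAL"
        elif fieldname == "acquisition_matrix":
            doc[entry.bids_key] = list(value)
        else:
            doc[entry.bids_key] = value
        if entry.bids_key in doc:
            used[entry.bids_key] = entry.mrio_iri
    if params.slice_gap_mm is not None and params.slice_thickness_mm is not None:
        doc["SpacingBetweenSlices"] = (
            params.slice_thickness_mm + params.slice_gap_mm
        )
        used["SpacingBetweenSlices"] = "MRIOKIT:spacing-between-slices"
    type_term = kb.term(type_iri)
    doc["MRIOAnnotations"] = {
        "TypeIRI": type_iri,
        "TypeLabel": type_term.label,
        "Parameters": dict(sorted(used.items())),
    }
    return doc


def organize_to_bids(
    kb: KnowledgeBase,
    classified: list[tuple[AcquisitionParameters, ClassificationResult]],
    subjects,
    skip_unclassified: bool = False,
) -> BidsPlan:
    """Plan a BIDS layout for classified series (pure; no filesystem I/O).

    ``subjects`` is either a single subject label applied to every series
    or a mapping ``series_id -> (subject, session-or-None)``.  Duplicate
    (subject, session, suffix) combinations receive ``run-`` entities in
    input order.
    """
    def assignment(series_id: str) -> tuple[str, str | None]:
        if isinstance(subjects, str):
            return subjects, None
        sub = subjects[series_id]
        return (sub, None) if isinstance(sub, str) else (sub[0], sub[1])

    plan = BidsPlan()
    staged = []
    for params, result in classified:
        if not result.matched_types:
            if skip_unclassified:
                plan.skipped.append(result.series_id)
                continue
            raise NoConventionError(
                f"series {result.series_id!r} is unclassified; "
                "classify or skip it explicitly"
            )
        type_iri = sorted(result.matched_types)[0]
        datatype, suffix = suffix_for_type(kb, type_iri)
        subject, session = assignment(result.series_id)
        for label in (subject, session):
            if label is not None and not _LABEL_RE.match(label):
                raise NoConventionError(
                    f"BIDS label {label!r} must be alphanumeric"
                )
        staged.append((params, result, type_iri, datatype, suffix, subject, session))

    groups: dict[tuple, int] = {}
    for item in staged:
        key = (item[5], item[6], item[4])
        groups[key] = groups.get(key, 0) + 1
    counters: dict[tuple, int] = {}
    seen_paths: dict[str, str] = {}
    for params, result, type_iri, datatype, suffix, subject, session in staged:
        key = (subject, session, suffix)
        run = None
        if groups[key] > 1:
            counters[key] = counters.get(key, 0) + 1
            run = counters[key]
        stem = f"sub-{subject}"
        dirpart = f"sub-{subject}"
        if session:
            stem += f"_ses-{session}"
            dirpart += f"/ses-{session}"
        if run is not None:
            stem += f"_run-{run}"
        path = f"{dirpart}/{datatype}/{stem}_{suffix}.nii.gz"
        if path in seen_paths:
            raise CollisionError(
                f"target {path} claimed by both {seen_paths[path]!r} "
                f"and {result.series_id!r}"
            )
        seen_paths[path] = result.series_id
        plan.entries.append(
            BidsEntry(
                series_id=result.series_id,
                subject=subject,
                session=session,
                datatype=datatype,
                suffix=suffix,
                target_path=path,
                sidecar=_sidecar_for(kb, params, type_iri),
            )
        )
    return plan


def dataset_description_stub(name: str = "mriokit organized dataset") -> dict:
    return {"Name": name, "BIDSVersion": "1.8.0", "GeneratedBy": [{"Name": "mriokit"}]}


def annotate_derivatives(
    kb: KnowledgeBase, assignment: AssignmentResult
) -> list[dict]:
    """Derivative metadata JSON objects, one per assigned analysis."""
    out = []
    for iri, label in assignment.assignments.items():
        spec = kb.analysis(iri)
        exp = assignment.explanations.get(iri)
        out.append(
            {
                "AnalysisIRI": iri,
                "Label": label,
                "SoftwareFamily": spec.software_family,
                "SatisfiedInputs": list(exp.conjunct) if exp else [],
                "InputWitnesses": dict(exp.witnesses) if exp else {},
                "Outputs": list(spec.outputs),
            }
        )
    return out


def default_kb() -> KnowledgeBase:
    return build_default_kb()
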