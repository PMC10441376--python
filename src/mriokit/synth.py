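"""Seeded generation of synthetic acquisition metadata.

The generator draws parameter records inside a type's axiom region —
uniformly within each interval constraint, kept off the boundaries by a
configurable margin — or deliberately outside it (one violated constraint
at a time) for negative controls.  Draws can be written as JSON tag maps,
minimal DICOM Part 10 files, or BIDS sidecars, and re-read by the ingest
module.

Open-ended facets are capped at physiologically plausible maxima so that
uniform sampling is proper: TR ≤ 15 000 ms, TE ≤ 500 ms, TI ≤ 3 500 ms,
temporal positions ≤ 400, b values ≤ 3 000 s/mm².  Sampled continuous
values are rounded to 4 decimals (scanner-like precision, and within the
16-character DICOM decimal-string limit).

Randomness comes from :class:`random.Random` seeded per call, so draws
are identical across platforms for a given seed.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path

import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .classifier import evaluate_axiom
from .errors import NotFoundError, SchemaError
from .ingest import AcquisitionParameters
from .knowledge_base import (
    Constraint,
    KnowledgeBase,
    TypeAxiom,
    build_default_kb,
    lookup_term,
)

#: caps closing the open-ended facet intervals, in canonical units
UPPER_CAPS = {
    "tr_ms": 15000.0,
    "te_ms": 500.0,
    "ti_ms": 3500.0,
    "flip_deg": 180.0,
    "n_temporal_positions": 400.0,
    "echo_train_length": 64.0,
    "b_values": 3000.0,
}

_INT_PARAMS = ("n_temporal_positions", "echo_train_length")

_MR_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.4"


@dataclass(frozen=True)
class SynthSpec:
    """What to generate: a type, how many draws, and how close to bounds."""

    type_iri: str
    n: int = 1
    seed: int = 0
    boundary_margin: float = 0.05
    violate: int | None = None

    def __post_init__(self):
        if self.n < 1:
            raise SchemaError("n must be >= 1")
        if not 0 <= self.boundary_margin <= 1:
            raise SchemaError("boundary_margin must lie in [0, 1]")


def _axioms_for_spec(kb: KnowledgeBase, spec: SynthSpec) -> tuple[str, tuple[TypeAxiom, ...]]:
    term = lookup_term(kb, spec.type_iri)
    axioms = kb.axioms_for(term.iri)
    if not axioms:
        raise NotFoundError(f"type {term.iri} has no bundled acquisition rule")
    return term.iri, axioms


def flat_constraints(kb: KnowledgeBase, type_iri: str) -> tuple[Constraint, ...]:
    """All constraints of a type's axioms, flattened in declaration order.

    This is the index space for :class:`SynthSpec.violate`.
    """
    term = lookup_term(kb, type_iri)
    cons: list[Constraint] = []
    for ax in kb.axioms_for(term.iri):
        cons.extend(ax.constraints)
    if not cons:
        raise NotFoundError(f"type {term.iri} has no bundled acquisition rule")
    return tuple(cons)


def _interval(c: Constraint) -> tuple[float, float]:
    low = c.low if c.low is not None else 0.0
    high = c.high if c.high is not None else UPPER_CAPS.get(c.parameter, low + 1000.0)
    return low, high


def _sample_constraint(rng: random.Random, c: Constraint, margin: float, kw: dict):
    p = c.parameter
    if c.kind in ("open_interval", "half_open"):
        low, high = _interval(c)
        width = high - low
        lo2 = low + margin * width
        hi2 = high - margin * width
        if p in _INT_PARAMS:
            lo_i = max(int(lo2) + 1, int(low) + (0 if c.low_inclusive else 1))
            hi_i = max(lo_i, int(hi2))
            kw[p] = rng.randint(lo_i, hi_i)
        elif p == "b_values":
            kw[p] = (0.0, round(rng.uniform(max(lo2, 100.0), hi2), 1))
        else:
            kw[p] = round(rng.uniform(lo2, hi2), 4)
    elif c.kind == "equality":
        if isinstance(c.value, bool):
            kw[p] = c.value
        else:
            kw[p] = float(c.value)
    elif c.kind == "categorical_membership":
        if p == "scanning_sequence":
            kw[p] = frozenset(kw.get(p, frozenset())) | frozenset(c.allowed_values)
        else:
            kw[p] = sorted(c.allowed_values)[0]
    elif c.kind == "presence":
        if p == "b_values":
            kw[p] = (0.0, 1000.0)
        else:
            kw[p] = 1.0


def _violate_constraint(rng: random.Random, c: Constraint, kw: dict):
    p = c.parameter
    if c.kind in ("open_interval", "half_open"):
        if c.high is not None:
            # at or beyond the (exclusive) upper bound
            val = c.high + rng.uniform(0.0, 0.5 * max(c.high, 10.0))
        else:
            low = c.low if c.low is not None else 0.0
            val = rng.uniform(max(0.25 * low, 0.0001), low) if low > 0 else 0.0001
            if p == "b_values":
                kw[p] = (0.0,)  # present, but max b = 0 violates max(b) > 0
                return
        if p in _INT_PARAMS:
            kw[p] = max(1, int(val))
            if c.high is None and kw[p] > (c.low or 0):
                kw[p] = max(1, int(c.low or 1))
        elif p == "b_values":
            kw[p] = (0.0, round(val, 1))
        else:
            kw[p] = round(val, 4)
    elif c.kind == "equality":
        if isinstance(c.value, bool):
            kw[p] = not c.value
        else:
            delta = c.tolerance + rng.uniform(0.5, 25.0)
            val = float(c.value) + rng.choice((-1.0, 1.0)) * delta
            if p == "flip_deg":
                val = min(max(val, 1.0), 180.0)
                if abs(val - float(c.value)) <= c.tolerance:
                    val = float(c.value) - delta
            kw[p] = round(val, 4)
    elif c.kind == "categorical_membership":
        spare = [s for s in ("SE", "GR", "RM") if s not in c.allowed_values]
        if p == "scanning_sequence":
            kw[p] = frozenset({spare[0]})
        else:
            kw[p] = spare[0]
    elif c.kind == "presence":
        kw[p] = None


def sample_params(
    spec: SynthSpec, kb: KnowledgeBase | None = None
) -> list[AcquisitionParameters]:
    """Draw ``spec.n`` records inside the type's axiom region.

    Every draw satisfies every constraint of every axiom bundled for the
    type (so a DWI draw carries both a positive b value and diffusion
    gradients).  Identical spec → identical draws.
    """
    kb = kb or build_default_kb()
    type_iri, axioms = _axioms_for_spec(kb, spec)
    syns = lookup_term(kb, type_iri).synonyms
    short = (min(syns, key=len) if syns else type_iri.split(":")[-1]).replace(" ", "-")
    rng = random.Random(spec.seed)
    out = []
    for i in range(spec.n):
        kw: dict = {"source": "SYNTHETIC"}
        for ax in axioms:
            for c in ax.constraints:
                _sample_constraint(rng, c, spec.boundary_margin, kw)
        kw["series_id"] = f"{short}-{spec.seed}-{i:04d}"
        out.append(AcquisitionParameters(**kw))
    return out


def sample_negative(
    spec: SynthSpec, kb: KnowledgeBase | None = None
) -> list[AcquisitionParameters]:
    """Draws violating exactly one constraint (``spec.violate``) while
    satisfying the rest; none classifies as the target type.

    The index refers to :func:`flat_constraints` of the type.  Because a
    type may carry several (disjunctive) axioms, any alternative axiom
    that would still match after the violation has one of its own
    constraints violated as well.
    """
    kb = kb or build_default_kb()
    type_iri, axioms = _axioms_for_spec(kb, spec)
    cons = flat_constraints(kb, type_iri)
    if spec.violate is None or not 0 <= spec.violate < len(cons):
        raise SchemaError(
            f"violate must index one of {len(cons)} constraints"
        )
    target = cons[spec.violate]
    rng = random.Random(spec.seed)
    out = []
    for i in range(spec.n):
        kw: dict = {"source": "SYNTHETIC"}
        for ax in axioms:
            for c in ax.constraints:
                _sample_constraint(rng, c, spec.boundary_margin, kw)
        _violate_constraint(rng, target, kw)
        # knock out any alternative axiom of the same type that still matches
        for _ in range(3):
            trial = AcquisitionParameters(
                **{k: v for k, v in kw.items() if v is not None or k == "violate"}
            )
            live = [
                ax
                for ax in axioms
                if evaluate_axiom(ax, trial, "strict").matched
            ]
            if not live:
                break
            for ax in live:
                alt = next(
                    (c for c in ax.constraints if c.parameter != target.parameter),
                    ax.constraints[0],
                )
                _violate_constraint(rng, alt, kw)
        kw = {k: v for k, v in kw.items() if v is not None}
        kw["series_id"] = f"neg{spec.violate}-{spec.seed}-{i:04d}"
        out.append(AcquisitionParameters(**kw))
    return out


# ---------------------------------------------------------------------------
# Fixture writers
# ---------------------------------------------------------------------------

def _tagmap_doc(p: AcquisitionParameters) -> dict:
    doc: dict = {"0008,0060": "MR"}
    if p.series_id:
        doc["0008,103E"] = p.series_id
    if p.tr_ms is not None:
        doc["0018,0080"] = p.tr_ms
    if p.te_ms is not None:
        doc["0018,0081"] = p.te_ms
    if p.ti_ms is not None:
        doc["0018,0082"] = p.ti_ms
    if p.flip_deg is not None:
        doc["0018,1314"] = p.flip_deg
    if p.scanning_sequence:
        doc["0018,0020"] = "\\".join(sorted(p.scanning_sequence))
    if p.slice_thickness_mm is not None:
        doc["0018,0050"] = p.slice_thickness_mm
        if p.slice_gap_mm is not None:
            doc["0018,0088"] = p.slice_thickness_mm + p.slice_gap_mm
    if p.echo_train_length is not None:
        doc["0018,0091"] = p.echo_train_length
    if p.n_temporal_positions is not None:
        doc["0020,0105"] = p.n_temporal_positions
    if p.b_values is not None:
        doc["0018,9087"] = list(p.b_values)
    doc["0018,9075"] = "DIRECTIONAL" if p.has_diffusion_gradients else "NONE"
    if p.fov_mm is not None:
        doc["0018,1100"] = p.fov_mm
    if p.phase_fov_pct is not None:
        doc["0018,0094"] = p.phase_fov_pct
    if p.phase_encoding_direction is not None:
        doc["0018,1312"] = p.phase_encoding_direction
    if p.acquisition_matrix is not None:
        doc["0018,1310"] = [p.acquisition_matrix[0], 0, 0, p.acquisition_matrix[1]]
    if p.matrix_size is not None:
        doc["0028,0010"] = p.matrix_size[0]
        doc["0028,0011"] = p.matrix_size[1]
        doc["0020,1002"] = p.matrix_size[2]
    return doc


def write_synthetic_sidecar(p: AcquisitionParameters, kb: KnowledgeBase | None = None) -> dict:
    """BIDS sidecar content for a synthetic draw (durations in seconds)."""
    kb = kb or build_default_kb()
    scale = {b.bids_key: b.scale_dicom_to_bids for b in kb.bridge}
    doc: dict = {}
    if p.series_id:
        doc["SeriesDescription"] = p.series_id
    if p.tr_ms is not None:
        doc["RepetitionTime"] = p.tr_ms * scale["RepetitionTime"]
    if p.te_ms is not None:
        doc["EchoTime"] = p.te_ms * scale["EchoTime"]
    if p.ti_ms is not None:
        doc["InversionTime"] = p.ti_ms * scale["InversionTime"]
    if p.flip_deg is not None:
        doc["FlipAngle"] = p.flip_deg
    if p.scanning_sequence:
        doc["ScanningSequence"] = sorted(p.scanning_sequence)
    if p.slice_thickness_mm is not None:
        doc["SliceThickness"] = p.slice_thickness_mm
        if p.slice_gap_mm is not None:
            doc["SpacingBetweenSlices"] = p.slice_thickness_mm + p.slice_gap_mm
    if p.echo_train_length is not None:
        doc["EchoTrainLength"] = p.echo_train_length
    if p.n_temporal_positions is not None:
        doc["NumberOfTemporalPositions"] = p.n_temporal_positions
    if p.b_values is not None:
        doc["DiffusionBValue"] = list(p.b_values)
    doc["DiffusionDirectionality"] = (
        "DIRECTIONAL" if p.has_diffusion_gradients else "NONE"
    )
    if p.fov_mm is not None:
        doc["FieldOfView"] = p.fov_mm
    if p.phase_fov_pct is not None:
        doc["PercentPhaseFieldOfView"] = p.phase_fov_pct
    if p.phase_encoding_direction is not None:
        doc["InPlanePhaseEncodingDirectionDICOM"] = p.phase_encoding_direction
    if p.acquisition_matrix is not None:
        doc["AcquisitionMatrix"] = list(p.acquisition_matrix)
    if p.plane is not None:
        doc["Plane"] = p.plane
    return doc


def _dicom_dataset(p: AcquisitionParameters) -> pydicom.dataset.FileDataset:
    sid = p.series_id or "synthetic"
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _MR_IMAGE_STORAGE
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[sid])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.dataset.FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _MR_IMAGE_STORAGE
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=[sid, "series"])
    ds.Modality = "MR"
    ds.SeriesDescription = sid

    def add(tag, vr, value):
        ds.add_new(tag, vr, value)

    if p.tr_ms is not None:
        add((0x0018, 0x0080), "DS", str(p.tr_ms))
    if p.te_ms is not None:
        add((0x0018, 0x0081), "DS", str(p.te_ms))
    if p.ti_ms is not None:
        add((0x0018, 0x0082), "DS", str(p.ti_ms))
    if p.flip_deg is not None:
        add((0x0018, 0x1314), "DS", str(p.flip_deg))
    if p.scanning_sequence:
        add((0x0018, 0x0020), "CS", sorted(p.scanning_sequence))
    if p.slice_thickness_mm is not None:
        add((0x0018, 0x0050), "DS", str(p.slice_thickness_mm))
        if p.slice_gap_mm is not None:
            add(
                (0x0018, 0x0088),
                "DS",
                str(p.slice_thickness_mm + p.slice_gap_mm),
            )
    if p.echo_train_length is not None:
        add((0x0018, 0x0091), "IS", str(p.echo_train_length))
    if p.n_temporal_positions is not None:
        add((0x0020, 0x0105), "IS", str(p.n_temporal_positions))
    if p.b_values is not None:
        add((0x0018, 0x9087), "FD", list(p.b_values))
    add((0x0018, 0x9075), "CS", "DIRECTIONAL" if p.has_diffusion_gradients else "NONE")
    if p.fov_mm is not None:
        add((0x0018, 0x1100), "DS", str(p.fov_mm))
    if p.phase_fov_pct is not None:
        add((0x0018, 0x0094), "DS", str(p.phase_fov_pct))
    if p.phase_encoding_direction is not None:
        add((0x0018, 0x1312), "CS", p.phase_encoding_direction)
    if p.acquisition_matrix is not None:
        add(
            (0x0018, 0x1310),
            "US",
            [p.acquisition_matrix[0], 0, 0, p.acquisition_matrix[1]],
        )
    if p.matrix_size is not None:
        add((0x0028, 0x0010), "US", p.matrix_size[0])
        add((0x0028, 0x0011), "US", p.matrix_size[1])
        add((0x0020, 0x1002), "IS", str(p.matrix_size[2]))
    return ds


FIXTURE_FORMATS = ("tagmap", "dicom", "sidecar")


def write_fixtures(
    params: list[AcquisitionParameters],
    fmt: str,
    out_dir,
    kb: KnowledgeBase | None = None,
) -> list[Path]:
    """Write draws to disk; returns the paths written (empty list for an
    empty input).  Files re-read through the ingest module reproduce the
    draw up to declared unit conversions."""
    if fmt not in FIXTURE_FORMATS:
        raise SchemaError(f"format must be one of {FIXTURE_FORMATS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, p in enumerate(params):
        stem = p.series_id or f"series-{i:04d}"
        try:
            if fmt == "tagmap":
                path = out / f"{stem}_tagmap.json"
                path.write_text(json.dumps(_tagmap_doc(p), indent=1) + "\n")
            elif fmt == "sidecar":
                path = out / f"{stem}.json"
                path.write_text(
                    json.dumps(write_synthetic_sidecar(p, kb), indent=1) + "\n"
                )
            else:
                path = out / f"{stem}.dcm"
                pydicom.dcmwrite(str(path), _dicom_dataset(p), enforce_file_format=True)
        except OSError as exc:
            raise SchemaError(f"cannot write fixture {stem!r}: {exc}") from exc
        paths.append(path)
    return paths
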