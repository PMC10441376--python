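"""Reading acquisition metadata into a canonical parameter record.

Two dialects feed the same record: DICOM headers (tags, durations in
milliseconds) and BIDS sidecar JSON (string keys, durations in seconds).
The DICOM-tag ↔ BIDS-key correspondence lives in the knowledge base's
bridge table; this module only knows how to map bridged ontology terms
onto fields of :class:`AcquisitionParameters` and how to convert units.

Absent metadata stays absent — readers never invent defaults; it is the
classifier's missing-parameter policy that decides what absence means.
"""

from __future__ import annotations

import json
import logging
import math
import warnings as _warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import pydicom

from .errors import EmptyInputError, FormatError, InvariantError, ModalityError
from .knowledge_base import KnowledgeBase, build_default_kb

log = logging.getLogger(__name__)

SCANNING_SEQUENCE_CODES = ("SE", "GR", "EP", "IR", "RM")
PLANES = ("axial", "sagittal", "coronal")

#: ontology term → AcquisitionParameters field for every bridged parameter
FIELD_BY_IRI = {
    "MRIO:0000358": "te_ms",
    "MRIO:0000357": "tr_ms",
    "MRIO:0000653": "ti_ms",
    "MRIO:0000630": "flip_deg",
    "MRIOKIT:scanning-sequence": "scanning_sequence",
    "MRIO:0000362": "slice_thickness_mm",
    "MRIOKIT:spacing-between-slices": "_spacing_mm",  # feeds slice_gap_mm
    "MRIO:0000359": "echo_train_length",
    "MRIO:0000687": "n_temporal_positions",
    "MRIO:0000655": "b_values",
    "MRIO:0000690": "has_diffusion_gradients",
    "MRIO:0000360": "fov_mm",
    "MRIO:0000365": "phase_encoding_direction",
    "MRIO:0000361": "phase_fov_pct",
    "MRIO:0000364": "acquisition_matrix",
}

_DURATION_FIELDS = ("tr_ms", "te_ms", "ti_ms")
_INT_FIELDS = ("echo_train_length", "n_temporal_positions")


@dataclass(frozen=True)
class AcquisitionParameters:
    """One series' harmonized scanner settings in canonical units.

    Durations are milliseconds, the flip angle is degrees, geometry is
    millimetres, and diffusion b values are s/mm².  ``None`` means the
    source carried no value for the parameter.
    """

    tr_ms: float | None = None
    te_ms: float | None = None
    ti_ms: float | None = None
    flip_deg: float | None = None
    fov_mm: float | None = None
    phase_fov_pct: float | None = None
    slice_thickness_mm: float | None = None
    slice_gap_mm: float | None = None
    echo_train_length: int | None = None
    scanning_sequence: frozenset[str] = frozenset()
    acquisition_matrix: tuple[int, int] | None = None
    matrix_size: tuple[int, int, int] | None = None
    phase_encoding_direction: str | None = None
    plane: str | None = None
    b_values: tuple[float, ...] | None = None
    has_diffusion_gradients: bool = False
    n_temporal_positions: int | None = None
    source: str = "SYNTHETIC"
    series_id: str | None = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "scanning_sequence", frozenset(self.scanning_sequence)
        )
        if self.b_values is not None:
            object.__setattr__(self, "b_values", tuple(self.b_values))
        if self.acquisition_matrix is not None:
            object.__setattr__(
                self, "acquisition_matrix", tuple(self.acquisition_matrix)
            )
        if self.matrix_size is not None:
            object.__setattr__(self, "matrix_size", tuple(self.matrix_size))
        for name in _DURATION_FIELDS:
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise InvariantError(f"{name} must be positive, got {v}")
        if self.flip_deg is not None and not 0 < self.flip_deg <= 180:
            raise InvariantError(
                f"flip_deg must lie in (0, 180], got {self.flip_deg}"
            )
        if self.b_values is not None and any(b < 0 for b in self.b_values):
            raise InvariantError("diffusion b values must be non-negative")
        if self.n_temporal_positions is not None and self.n_temporal_positions < 1:
            raise InvariantError("n_temporal_positions must be >= 1")


PARAMETER_FIELDS = tuple(
    f.name for f in fields(AcquisitionParameters) if f.name not in ("source", "series_id")
)

_NUMERIC_FIELDS = (
    "tr_ms",
    "te_ms",
    "ti_ms",
    "flip_deg",
    "fov_mm",
    "phase_fov_pct",
    "slice_thickness_mm",
    "slice_gap_mm",
    "echo_train_length",
    "n_temporal_positions",
)


def params_equal(
    a: AcquisitionParameters,
    b: AcquisitionParameters,
    rel_tol: float = 1e-9,
) -> bool:
    """Field-wise equality with relative tolerance on continuous values.

    Unit conversions (DICOM milliseconds ↔ BIDS seconds) are not exact in
    binary floating point, so round-trip comparisons allow ``rel_tol``.
    """
    for name in PARAMETER_FIELDS:
        va, vb = getattr(a, name), getattr(b, name)
        if isinstance(va, float) and isinstance(vb, float):
            if not math.isclose(va, vb, rel_tol=rel_tol, abs_tol=0.0):
                return False
        elif name == "b_values" and va is not None and vb is not None:
            if len(va) != len(vb) or any(
                not math.isclose(x, y, rel_tol=rel_tol, abs_tol=1e-12)
                for x, y in zip(va, vb)
            ):
                return False
        elif va != vb:
            return False
    return True


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def _normalize_tag(key) -> tuple[int, int]:
    if isinstance(key, tuple) and len(key) == 2:
        return (int(key[0]), int(key[1]))
    if isinstance(key, int):
        return (key >> 16, key & 0xFFFF)
    s = str(key).strip().strip("()").replace(" ", "")
    if "," in s:
        g, e = s.split(",")
    elif len(s) == 8:
        g, e = s[:4], s[4:]
    else:
        raise FormatError(f"cannot interpret DICOM tag key {key!r}")
    try:
        return (int(g, 16), int(e, 16))
    except ValueError as exc:
        raise FormatError(f"cannot interpret DICOM tag key {key!r}") from exc


def _to_float(v) -> float:
    try:
        return float(v)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"expected a number, got {v!r}") from exc


def _first_echo(v):
    """Multi-echo series carry TE as a multi-value; take the first echo."""
    if isinstance(v, (list, tuple)) and v:
        _warnings.warn(
            "multi-echo TE encountered; using the first echo for "
            "classification",
            stacklevel=3,
        )
        return v[0]
    if isinstance(v, str) and "\\" in v:
        return _first_echo(v.split("\\"))
    return v


def _split_codes(v) -> frozenset[str]:
    if isinstance(v, (list, tuple, set, frozenset)):
        return frozenset(str(x).strip() for x in v if str(x).strip())
    return frozenset(s.strip() for s in str(v).split("\\") if s.strip())


def read_dicom_params(header) -> AcquisitionParameters:
    """Extract acquisition parameters from a DICOM source.

    ``header`` may be a tag→value mapping (keys like ``(0x0018, 0x0081)``
    or ``"0018,0081"``), a :class:`pydicom.dataset.Dataset`, or a path to a
    DICOM Part 10 file (or to a JSON tag map).  DICOM stores durations in
    milliseconds, which is the canonical unit, so no conversion happens.
    """
    if isinstance(header, pydicom.dataset.Dataset):
        tagmap = {
            (el.tag.group, el.tag.element): el.value
            for el in header
            if el.tag.group != 0x7FE0
        }
    elif isinstance(header, (str, Path)):
        p = Path(header)
        if not p.exists():
            raise FormatError(f"no such file: {p}")
        if p.suffix.lower() == ".json":
            try:
                raw = json.loads(p.read_text())
            except json.JSONDecodeError as exc:
                raise FormatError(f"{p}: invalid JSON tag map: {exc}") from exc
            return read_dicom_params(raw)
        try:
            ds = pydicom.dcmread(str(p), stop_before_pixels=True)
        except Exception as exc:
            raise FormatError(f"{p}: not a readable DICOM file: {exc}") from exc
        return read_dicom_params(ds)
    elif isinstance(header, dict):
        tagmap = {}
        for k, v in header.items():
            if str(k).startswith("_"):
                continue
            tagmap[_normalize_tag(k)] = v
    else:
        raise FormatError(
            f"cannot read DICOM parameters from {type(header).__name__}"
        )

    modality = tagmap.get((0x0008, 0x0060))
    if modality is not None and str(modality).strip() != "MR":
        raise ModalityError(f"not an MR series (modality {modality!r})")

    def get(g, e):
        return tagmap.get((g, e))

    kw: dict = {"source": "DICOM"}
    if get(0x0018, 0x0080) is not None:
        kw["tr_ms"] = _to_float(get(0x0018, 0x0080))
    if get(0x0018, 0x0081) is not None:
        kw["te_ms"] = _to_float(_first_echo(get(0x0018, 0x0081)))
    if get(0x0018, 0x0082) is not None:
        kw["ti_ms"] = _to_float(get(0x0018, 0x0082))
    if get(0x0018, 0x1314) is not None:
        kw["flip_deg"] = _to_float(get(0x0018, 0x1314))
    if get(0x0018, 0x0020) is not None:
        kw["scanning_sequence"] = _split_codes(get(0x0018, 0x0020))
    thickness = get(0x0018, 0x0050)
    if thickness is not None:
        kw["slice_thickness_mm"] = _to_float(thickness)
    spacing = get(0x0018, 0x0088)
    if spacing is not None and thickness is not None:
        # slice gap is not stored directly; derive from centre spacing
        kw["slice_gap_mm"] = _to_float(spacing) - _to_float(thickness)
    if get(0x0018, 0x0091) is not None:
        kw["echo_train_length"] = int(_to_float(get(0x0018, 0x0091)))
    if get(0x0020, 0x0105) is not None:
        kw["n_temporal_positions"] = int(_to_float(get(0x0020, 0x0105)))
    bval = get(0x0018, 0x9087)
    if bval is not None:
        if isinstance(bval, (list, tuple)):
            kw["b_values"] = tuple(_to_float(b) for b in bval)
        else:
            kw["b_values"] = (_to_float(bval),)
    directionality = get(0x0018, 0x9075)
    if directionality is not None:
        kw["has_diffusion_gradients"] = (
            str(directionality).strip().upper() not in ("", "NONE")
        )
    if get(0x0018, 0x1100) is not None:
        kw["fov_mm"] = _to_float(get(0x0018, 0x1100))
    if get(0x0018, 0x0094) is not None:
        kw["phase_fov_pct"] = _to_float(get(0x0018, 0x0094))
    if get(0x0018, 0x1312) is not None:
        kw["phase_encoding_direction"] = str(get(0x0018, 0x1312)).strip()
    acqm = get(0x0018, 0x1310)
    if acqm is not None:
        vals = [int(_to_float(v)) for v in (
            acqm if isinstance(acqm, (list, tuple)) else [acqm]
        )]
        nz = [v for v in vals if v] or vals
        kw["acquisition_matrix"] = (nz[0], nz[-1])
    rows, cols = get(0x0028, 0x0010), get(0x0028, 0x0011)
    nslices = get(0x0020, 0x1002)
    if rows is not None and cols is not None and nslices is not None:
        kw["matrix_size"] = (
            int(_to_float(rows)),
            int(_to_float(cols)),
            int(_to_float(nslices)),
        )
    if get(0x0008, 0x103E) is not None:
        kw["series_id"] = str(get(0x0008, 0x103E))
    return AcquisitionParameters(**kw)


# ---------------------------------------------------------------------------
# BIDS sidecar
# ---------------------------------------------------------------------------

def read_bids_sidecar(source, kb: KnowledgeBase | None = None) -> AcquisitionParameters:
    """Read a BIDS sidecar (JSON text, dict, or path to a .json file).

    BIDS stores durations in seconds; the bridge table's unit scales
    convert them to the canonical milliseconds.  Unknown keys are ignored
    with a logged notice.
    """
    if kb is None:
        kb = build_default_kb()
    if isinstance(source, dict):
        doc = source
    else:
        text = source
        p = Path(str(source))
        if isinstance(source, (str, Path)) and str(source).endswith(".json"):
            if not p.exists():
                raise FormatError(f"no such file: {p}")
            text = p.read_text()
        try:
            doc = json.loads(text)
        except (json.JSONDecodeError, TypeError) as exc:
            raise FormatError(f"invalid sidecar JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise FormatError("sidecar JSON must be an object")

    by_key = {b.bids_key: b for b in kb.bridge}
    kw: dict = {"source": "BIDS"}
    spacing = None
    for key, raw in doc.items():
        if key == "SeriesDescription":
            kw["series_id"] = str(raw)
            continue
        if key == "Plane" and str(raw) in PLANES:
            kw["plane"] = str(raw)
            continue
        entry = by_key.get(key)
        if entry is None:
            log.info("ignoring unknown sidecar key %r", key)
            continue
        fieldname = FIELD_BY_IRI[entry.mrio_iri]
        if fieldname in _DURATION_FIELDS:
            v = _to_float(raw)
            if v <= 0:
                raise InvariantError(f"{key} must be positive, got {raw}")
            kw[fieldname] = v / entry.scale_dicom_to_bids
        elif fieldname == "scanning_sequence":
            kw[fieldname] = _split_codes(raw)
        elif fieldname == "b_values":
            vals = raw if isinstance(raw, (list, tuple)) else [raw]
            kw[fieldname] = tuple(_to_float(b) for b in vals)
        elif fieldname == "has_diffusion_gradients":
            kw[fieldname] = str(raw).strip().upper() not in ("", "NONE")
        elif fieldname == "acquisition_matrix":
            vals = [int(_to_float(v)) for v in (
                raw if isinstance(raw, (list, tuple)) else [raw]
            )]
            nz = [v for v in vals if v] or vals
            kw[fieldname] = (nz[0], nz[-1])
        elif fieldname == "_spacing_mm":
            spacing = _to_float(raw)
        elif fieldname in _INT_FIELDS:
            kw[fieldname] = int(_to_float(raw))
        elif fieldname == "phase_encoding_direction":
            kw[fieldname] = str(raw)
        else:
            kw[fieldname] = _to_float(raw)
    if spacing is not None and kw.get("slice_thickness_mm") is not None:
        kw["slice_gap_mm"] = spacing - kw["slice_thickness_mm"]
    return AcquisitionParameters(**kw)


# ---------------------------------------------------------------------------
# Dataset profiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RangeProfile:
    parameter: str
    n_series: int
    min: float
    max: float
    distinct_values: int


def profile_dataset(series: list[AcquisitionParameters]) -> list[RangeProfile]:
    """Per-parameter value ranges over a dataset.

    One profile per numeric parameter present in at least one series,
    computed over present values only; diffusion b values are flattened.
    """
    if not series:
        raise EmptyInputError("cannot profile an empty dataset")
    profiles = []
    for name in _NUMERIC_FIELDS:
        values = [getattr(s, name) for s in series if getattr(s, name) is not None]
        if values:
            profiles.append(
                RangeProfile(
                    parameter=name,
                    n_series=len(values),
                    min=min(values),
                    max=max(values),
                    distinct_values=len(set(values)),
                )
            )
    b_all, b_n = [], 0
    for s in series:
        if s.b_values is not None:
            b_all.extend(s.b_values)
            b_n += 1
    if b_all:
        profiles.append(
            RangeProfile(
                parameter="b_values",
                n_series=b_n,
                min=min(b_all),
                max=max(b_all),
                distinct_values=len(set(b_all)),
            )
        )
    return profiles


def profiles_to_csv(profiles: list[RangeProfile]) -> str:
    lines = ["parameter,n_series,min,max,distinct_values"]
    for p in profiles:
        lines.append(
            f"{p.parameter},{p.n_series},{p.min!r},{p.max!r},{p.distinct_values}"
        )
    return "\n".join(lines) + "\n"
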