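"""Reading DICOM headers and BIDS sidecars into canonical parameters."""

import json

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mriokit.errors import (
    EmptyInputError,
    FormatError,
    InvariantError,
    ModalityError,
)
from mriokit.ingest import (
    AcquisitionParameters,
    params_equal,
    profile_dataset,
    read_bids_sidecar,
    read_dicom_params,
)
from mriokit.synth import SynthSpec, sample_params, write_synthetic_sidecar


class TestDicomReader:
    def test_basic_tags(self):
        p = read_dicom_params(
            {"(0018,0081)": "15", "(0018,0080)": "500", "(0018,1314)": "90"}
        )
        assert (p.te_ms, p.tr_ms, p.flip_deg) == (15.0, 500.0, 90.0)
        assert p.source == "DICOM"

    def test_empty_header_all_absent(self):
        p = read_dicom_params({})
        assert p.tr_ms is None and p.te_ms is None and p.flip_deg is None
        assert p.scanning_sequence == frozenset()
        assert p.b_values is None

    def test_multivalued_scanning_sequence_splits_on_backslash(self):
        p = read_dicom_params({"0018,0020": "IR\\SE"})
        assert p.scanning_sequence == frozenset({"IR", "SE"})

    def test_non_mr_modality_rejected(self):
        with pytest.raises(ModalityError):
            read_dicom_params({"0008,0060": "CT"})

    def test_slice_gap_derived_from_spacing(self):
        p = read_dicom_params({"0018,0050": "3.0", "0018,0088": "3.5"})
        assert p.slice_gap_mm == pytest.approx(0.5)

    def test_spacing_without_thickness_leaves_gap_absent(self):
        assert read_dicom_params({"0018,0088": "3.5"}).slice_gap_mm is None

    def test_multi_echo_takes_first_with_warning(self):
        with pytest.warns(UserWarning, match="multi-echo"):
            p = read_dicom_params({"0018,0081": "12\\80"})
        assert p.te_ms == 12.0

    def test_unparseable_input_raises_format_error(self):
        with pytest.raises(FormatError):
            read_dicom_params({"not-a-tag": 1})
        with pytest.raises(FormatError):
            read_dicom_params(42)

    def test_tag_key_spellings_agree(self):
        variants = [
            {(0x0018, 0x0080): 500},
            {"0018,0080": 500},
            {"(0018, 0080)": 500},
            {"00180080": 500},
        ]
        assert all(read_dicom_params(v).tr_ms == 500.0 for v in variants)


class TestBidsReader:
    def test_seconds_converted_to_milliseconds(self):
        p = read_bids_sidecar(
            '{"EchoTime": 0.015, "RepetitionTime": 0.5, "FlipAngle": 90}'
        )
        assert (p.te_ms, p.tr_ms, p.flip_deg) == (15.0, 500.0, 90.0)
        assert p.source == "BIDS"

    def test_empty_object_all_absent(self):
        p = read_bids_sidecar("{}")
        assert p.tr_ms is None and p.b_values is None

    def test_negative_duration_rejected(self):
        with pytest.raises(InvariantError):
            read_bids_sidecar('{"EchoTime": -1}')

    def test_malformed_json_rejected(self):
        with pytest.raises(FormatError):
            read_bids_sidecar("{not json")

    def test_unknown_keys_ignored(self):
        p = read_bids_sidecar('{"Manufacturer": "X", "EchoTime": 0.01}')
        assert p.te_ms == pytest.approx(10.0)


class TestReaderAgreement:
    @pytest.mark.parametrize(
        "type_key", ["T1w", "T2w", "FLAIR", "DWI", "fMRI", "PD", "T1 SPGR"]
    )
    def test_dicom_and_sidecar_readers_agree(self, kb, type_key):
        """A synthetic series written to both dialects reads back equal."""
        for draw in sample_params(SynthSpec(type_key, n=5, seed=11), kb):
            from mriokit.synth import _tagmap_doc

            via_dicom = read_dicom_params(_tagmap_doc(draw))
            via_bids = read_bids_sidecar(
                json.dumps(write_synthetic_sidecar(draw, kb)), kb
            )
            assert params_equal(via_dicom, via_bids)
            assert params_equal(draw, via_bids)

    def test_sidecar_roundtrip_duration_precision(self, kb):
        p = AcquisitionParameters(tr_ms=512.1234, te_ms=14.8321, ti_ms=2500.5)
        back = read_bids_sidecar(json.dumps(write_synthetic_sidecar(p, kb)), kb)
        for a, b in [
            (p.tr_ms, back.tr_ms),
            (p.te_ms, back.te_ms),
            (p.ti_ms, back.ti_ms),
        ]:
            assert abs(a - b) / a < 1e-9


class TestInvariants:
    @pytest.mark.parametrize(
        "kw",
        [
            {"tr_ms": 0.0},
            {"te_ms": -3.0},
            {"flip_deg": 181.0},
            {"flip_deg": 0.0},
            {"b_values": (-1.0,)},
            {"n_temporal_positions": 0},
        ],
    )
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(InvariantError):
            AcquisitionParameters(**kw)


class TestProfiling:
    def test_min_max_over_two_series(self):
        series = [
            AcquisitionParameters(tr_ms=500.0),
            AcquisitionParameters(tr_ms=700.0),
        ]
        (profile,) = [p for p in profile_dataset(series) if p.parameter == "tr_ms"]
        assert (profile.min, profile.max, profile.n_series) == (500.0, 700.0, 2)

    def test_single_series_min_equals_max(self):
        series = [AcquisitionParameters(tr_ms=500.0, te_ms=15.0, flip_deg=90.0)]
        for p in profile_dataset(series):
            assert p.min == p.max
            assert p.distinct_values == 1

    def test_absent_fields_excluded(self):
        series = [AcquisitionParameters(tr_ms=500.0)]
        assert {p.parameter for p in profile_dataset(series)} == {"tr_ms"}

    def test_empty_dataset_rejected(self):
        with pytest.raises(EmptyInputError):
            profile_dataset([])

    def test_synthetic_t1w_profile_inside_printed_interval(self, kb):
        draws = sample_params(SynthSpec("T1w", n=100, seed=3), kb)
        tr = next(p for p in profile_dataset(draws) if p.parameter == "tr_ms")
        assert 0.0 < tr.min and tr.max < 800.0
        te = next(p for p in profile_dataset(draws) if p.parameter == "te_ms")
        assert 0.0 < te.min and te.max < 30.0

    @given(
        values=st.lists(
            st.floats(min_value=0.1, max_value=1e4, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    def test_profile_equals_brute_force_scan(self, values):
        series = [AcquisitionParameters(tr_ms=v) for v in values]
        profile = next(
            p for p in profile_dataset(series) if p.parameter == "tr_ms"
        )
        assert profile.min == min(values)
        assert profile.max == max(values)
        assert profile.distinct_values == len(set(values))
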