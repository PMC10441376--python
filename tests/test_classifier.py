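"""Axiom evaluation and most-specific type assignment."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mriokit.classifier import classify_dataset, classify_series, evaluate_axiom
from mriokit.errors import EmptyInputError, SchemaError
from mriokit.ingest import AcquisitionParameters
from mriokit.knowledge_base import Constraint, TypeAxiom

T1W = "MRIO:0000366"
T2W = "MRIO:0000367"
FLAIR = "MRIO:0000511"


def _t1w_axiom(kb):
    (ax,) = kb.axioms_for(T1W)
    return ax


class TestEvaluateAxiom:
    def test_t1w_worked_example_matches(self, kb):
        p = AcquisitionParameters(tr_ms=500.0, te_ms=15.0, flip_deg=90.0)
        assert evaluate_axiom(_t1w_axiom(kb), p).matched

    def test_exclusive_upper_bound_at_800(self, kb):
        p = AcquisitionParameters(tr_ms=800.0, te_ms=15.0, flip_deg=90.0)
        result = evaluate_axiom(_t1w_axiom(kb), p)
        assert not result.matched
        tr = next(o for o in result.outcomes if o.parameter == "tr_ms")
        assert tr.satisfied is False

    def test_missing_te_is_indeterminate(self, kb):
        p = AcquisitionParameters(tr_ms=500.0, flip_deg=90.0)
        strict = evaluate_axiom(_t1w_axiom(kb), p, "strict")
        assert not strict.matched
        te = next(o for o in strict.outcomes if o.parameter == "te_ms")
        assert te.satisfied is None
        lenient = evaluate_axiom(_t1w_axiom(kb), p, "lenient")
        assert lenient.matched

    def test_unknown_parameter_is_schema_error(self):
        axiom = TypeAxiom(T1W, (Constraint("bogus_param", "presence"),))
        with pytest.raises(SchemaError):
            evaluate_axiom(axiom, AcquisitionParameters())

    def test_unknown_policy_rejected(self, kb):
        with pytest.raises(SchemaError):
            evaluate_axiom(_t1w_axiom(kb), AcquisitionParameters(), "fuzzy")


class TestClassifySeries:
    def test_t2w_worked_example(self, kb):
        r = classify_series(
            kb, AcquisitionParameters(tr_ms=3000.0, te_ms=80.0, flip_deg=90.0)
        )
        assert r.matched_types == {T2W}

    def test_gap_between_intervals_unclassified(self, kb):
        r = classify_series(
            kb, AcquisitionParameters(tr_ms=1200.0, te_ms=20.0, flip_deg=90.0)
        )
        assert r.matched_types == frozenset()

    def test_flair_most_specific_with_lineage(self, kb):
        r = classify_series(
            kb,
            AcquisitionParameters(
                tr_ms=9000.0,
                te_ms=120.0,
                flip_deg=90.0,
                ti_ms=2500.0,
                scanning_sequence={"IR", "SE"},
            ),
        )
        assert r.matched_types == {FLAIR}
        assert T2W in r.lineage[FLAIR]

    def test_flip_angle_tolerance_half_degree(self, kb):
        base = dict(tr_ms=500.0, te_ms=15.0)
        assert classify_series(
            kb, AcquisitionParameters(flip_deg=90.4, **base)
        ).matched_types == {T1W}
        assert (
            classify_series(
                kb, AcquisitionParameters(flip_deg=90.6, **base)
            ).matched_types
            == frozenset()
        )

    def test_boundary_exactness_on_printed_bounds(self, kb):
        """The T1w predicate flips exactly at the printed TR bounds."""
        def t1w(tr):
            p = AcquisitionParameters(tr_ms=tr, te_ms=15.0, flip_deg=90.0)
            return T1W in classify_series(kb, p).matched_types

        eps = 1e-9
        assert t1w(eps)  # just above the exclusive lower bound
        assert t1w(800.0 - 1e-6)
        assert not t1w(800.0)
        assert not t1w(800.0 + 1e-6)

    def test_t1w_t2w_axioms_disjoint_on_random_sweep(self, kb):
        """No parameter record satisfies both printed axioms (TR intervals
        (0,800) and (2000,inf) are disjoint); checked on 10^5 draws."""
        (t1,) = kb.axioms_for(T1W)
        (t2,) = kb.axioms_for(T2W)
        rng = random.Random(0)
        for _ in range(100_000):
            p = AcquisitionParameters(
                tr_ms=rng.uniform(1e-3, 20000.0),
                te_ms=rng.uniform(1e-3, 500.0),
                flip_deg=rng.uniform(1.0, 180.0),
            )
            assert not (
                evaluate_axiom(t1, p).matched and evaluate_axiom(t2, p).matched
            )

    @given(
        tr=st.floats(1e-3, 20000.0),
        te=st.floats(1e-3, 500.0),
        flip=st.floats(1.0, 180.0),
    )
    def test_determinism(self, kb, tr, te, flip):
        p = AcquisitionParameters(tr_ms=tr, te_ms=te, flip_deg=flip)
        first = classify_series(kb, p)
        second = classify_series(kb, p)
        assert first.matched_types == second.matched_types
        assert first.lineage == second.lineage


class TestClassifyDataset:
    def test_summary_counts_match_brute_tally(self, kb):
        from mriokit.synth import SynthSpec, sample_params

        series = sample_params(SynthSpec("T1w", n=10, seed=1), kb)
        series += sample_params(SynthSpec("T2w", n=5, seed=2), kb)
        results, summary = classify_dataset(kb, series)
        assert summary == {T1W: 10, T2W: 5}
        # order preserved
        assert [r.series_id for r in results] == [s.series_id for s in series]

    def test_unclassifiable_series_counted(self, kb):
        _, summary = classify_dataset(
            kb, [AcquisitionParameters(tr_ms=1200.0, te_ms=20.0, flip_deg=90.0)]
        )
        assert summary == {"unclassified": 1}

    def test_empty_dataset_rejected(self, kb):
        with pytest.raises(EmptyInputError):
            classify_dataset(kb, [])

    def test_classification_stable_through_dicom_roundtrip(self, kb, tmp_path):
        from mriokit.ingest import read_dicom_params
        from mriokit.synth import SynthSpec, sample_params, write_fixtures

        series = sample_params(SynthSpec("FLAIR", n=3, seed=9), kb)
        series += sample_params(SynthSpec("DWI", n=3, seed=9), kb)
        paths = write_fixtures(series, "dicom", tmp_path, kb)
        reread = [read_dicom_params(str(p)) for p in paths]
        _, before = classify_dataset(kb, series)
        _, after = classify_dataset(kb, reread)
        assert before == after
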