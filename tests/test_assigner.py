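"""Analysis assignment: DNF satisfaction, subsumption, query modes."""

import random

import pytest

from mriokit.assigner import (
    assign_analyses,
    explain_assignment,
    graph_query_mode,
    satisfied_conjuncts,
)
from mriokit.errors import NotFoundError, ResolutionError
from tests.conftest import make_random_kb

T1W = "MRIO:0000366"
T2W = "MRIO:0000367"
FLAIR = "MRIO:0000511"
SPGR = "MRIO:0000680"
SIENAX = "MRIO:0000525"


def _brute_force_assign(kb, avail):
    """Independent oracle: direct DNF satisfaction with subsumption."""
    from mriokit.knowledge_base import subsumes

    out = set()
    for analysis in kb.analyses:
        for conj in analysis.input_dnf:
            if all(any(subsumes(kb, req, a) for a in avail) for req in conj):
                out.add(analysis.iri)
                break
    return out


class TestSatisfiedConjuncts:
    def test_sienax_singleton_with_t1w(self, kb):
        sienax = kb.analysis(SIENAX)
        assert satisfied_conjuncts(kb, sienax, {T1W}) == [(T1W,)]

    def test_sienax_nothing_with_flair_alone(self, kb):
        assert satisfied_conjuncts(kb, kb.analysis(SIENAX), {FLAIR}) == []

    def test_sienax_both_conjuncts_with_t1w_and_flair(self, kb):
        sat = satisfied_conjuncts(kb, kb.analysis(SIENAX), {T1W, FLAIR})
        assert sat == [(T1W, FLAIR), (T1W,)]

    def test_unknown_available_curie_raises(self, kb):
        with pytest.raises(NotFoundError):
            satisfied_conjuncts(kb, kb.analysis(SIENAX), {"MRIO:9999999"})


class TestAssignAnalyses:
    def test_t1w_yields_sienax(self, kb):
        result = assign_analyses(kb, {T1W})
        assert SIENAX in result.assignments
        assert result.assignments[SIENAX] == "SIENAX analysis"

    def test_empty_availability_yields_nothing(self, kb):
        assert assign_analyses(kb, set()).assignments == {}

    def test_flair_yields_flair_and_t2w_analyses(self, kb):
        result = assign_analyses(kb, {FLAIR})
        assert "MRIOKIT:neurostream-analysis" in result.assignments
        assert "MRIOKIT:deepgrai-analysis" in result.assignments
        # FLAIR is a T2w subtype, so T2w-input analyses apply via subsumption
        assert "MRIOKIT:lpa-analysis" in result.assignments
        assert SIENAX not in result.assignments

    def test_specialized_type_satisfies_required_ancestor(self, kb):
        assert SIENAX in assign_analyses(kb, {SPGR}).assignments

    def test_labels_resolve_like_curies(self, kb):
        assert assign_analyses(kb, ["T1w"]).assignments == assign_analyses(
            kb, [T1W]
        ).assignments

    def test_unknown_inputs_warn_but_do_not_fail(self, kb):
        result = assign_analyses(kb, ["garbage", "more garbage"])
        assert result.assignments == {}
        assert len(result.warnings) == 2

    def test_matches_brute_force_on_bundle(self, kb):
        pool = [T1W, T2W, FLAIR, SPGR, "MRIOKIT:dwi-mri-data-set",
                "MRIOKIT:fmri-data-set", "MRIOKIT:pd-mri-data-set",
                "MRIOKIT:t1w-followup-data-set"]
        rng = random.Random(7)
        for _ in range(50):
            avail = set(rng.sample(pool, rng.randint(0, len(pool))))
            assert set(assign_analyses(kb, avail).assignments) == \
                _brute_force_assign(kb, sorted(avail))


class TestExplain:
    def test_sienax_witness_with_t1w(self, kb):
        exp = explain_assignment(kb, SIENAX, {T1W})
        assert exp.assignable
        assert exp.conjunct == (T1W,)
        assert exp.witnesses == {T1W: T1W}

    def test_smallest_conjunct_preferred(self, kb):
        exp = explain_assignment(kb, SIENAX, {T1W, FLAIR})
        assert exp.conjunct == (T1W,)
        assert len(exp.satisfied_conjuncts) == 2

    def test_not_assignable_lists_missing_types(self, kb):
        exp = explain_assignment(kb, SIENAX, set())
        assert not exp.assignable
        assert exp.missing[(T1W, FLAIR)] == (T1W, FLAIR)
        assert exp.missing[(T1W,)] == (T1W,)

    def test_deepgrai_from_flair(self, kb):
        exp = explain_assignment(kb, "MRIOKIT:deepgrai-analysis", {FLAIR})
        assert exp.conjunct == (FLAIR,)

    def test_label_resolution_and_unknown(self, kb):
        assert explain_assignment(kb, "SIENAX analysis", {T1W}).assignable
        with pytest.raises(ResolutionError):
            explain_assignment(kb, "no-such-analysis", {T1W})


class TestGraphQueryMode:
    @pytest.mark.parametrize(
        "avail",
        [
            [T1W],
            [],
            ["T1w", "FLAIR"],
            [FLAIR],
            ["T1 SPGR"],
            ["MRIOKIT:dwi-mri-data-set", "fMRI"],
            ["T1w", "nonsense"],
        ],
    )
    def test_agrees_with_native_mode(self, kb, avail):
        assert graph_query_mode(kb, avail) == assign_analyses(kb, avail)

    def test_full_availability_agrees(self, kb):
        every_type = list(kb.axiom_types()) + ["MRIOKIT:t1w-followup-data-set"]
        g = graph_query_mode(kb, every_type)
        n = assign_analyses(kb, every_type)
        assert g == n
        assert set(n.assignments) == {a.iri for a in kb.analyses}


class TestProperties:
    def test_monotone_in_availability_and_stage_decomposition(self, kb):
        """On random KBs: three-stage result equals brute-force DNF
        satisfaction, and growing availability never loses analyses."""
        rng = random.Random(2024)
        for _ in range(100):
            rkb, type_iris = make_random_kb(rng)
            small = set(rng.sample(type_iris, rng.randint(0, 4)))
            big = small | set(rng.sample(type_iris, rng.randint(0, 5)))
            a_small = set(assign_analyses(rkb, small).assignments)
            a_big = set(assign_analyses(rkb, big).assignments)
            assert a_small == _brute_force_assign(rkb, sorted(small))
            assert a_small <= a_big

    def test_monotone_under_specialization(self, kb):
        """Swapping an available type for a descendant keeps assignments."""
        from mriokit.knowledge_base import subsumes

        rng = random.Random(99)
        children = {}
        for t in kb.terms:
            if t.parent_iri:
                children.setdefault(t.parent_iri, []).append(t.iri)
        pool = kb.axiom_types()
        for _ in range(50):
            avail = set(rng.sample(pool, rng.randint(1, len(pool))))
            target = next((a for a in sorted(avail) if a in children), None)
            if target is None:
                continue
            child = rng.choice(children[target])
            specialized = (avail - {target}) | {child}
            assert subsumes(kb, target, child)
            before = set(assign_analyses(kb, avail).assignments)
            after = set(assign_analyses(kb, specialized).assignments)
            assert before <= after
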