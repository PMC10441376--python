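"""Term graph: bundled content, validation, subsumption, lookup, RDF."""

import networkx as nx
import pytest

from mriokit.errors import (
    AmbiguousLookupError,
    KBValidationError,
    NotFoundError,
)
from mriokit.knowledge_base import (
    AnalysisSpec,
    KnowledgeBase,
    TermRecord,
    ancestors,
    build_default_kb,
    export_rdf,
    kb_from_dict,
    kb_to_dict,
    lookup_term,
    parse_rdf,
    subsumes,
    validate_kb,
)


class TestBundle:
    def test_deterministic_across_calls(self, kb):
        assert build_default_kb() == kb

    @pytest.mark.parametrize(
        "iri,label",
        [
            ("MRIO:0000358", "echo time"),
            ("MRIO:0000357", "repetition time"),
            ("MRIO:0000653", "inversion time"),
            ("MRIO:0000630", "flip angle"),
            ("MRIO:0000366", "T1 weighted magnetic resonance image data set"),
            ("MRIO:0000367", "T2 weighted magnetic resonance image data set"),
            ("MRIO:0000525", "SIENAX analysis"),
        ],
    )
    def test_bundled_labels(self, kb, iri, label):
        assert kb.term(iri).label == label

    def test_flair_is_subtype_of_t2w(self, kb):
        assert kb.term("MRIO:0000511").parent_iri == "MRIO:0000367"

    def test_atlas_has_86_unique_regions(self, kb):
        atlas = next(a for a in kb.atlases if a.atlas_iri == "MRIO:0000649")
        labels = [r.region_label for r in atlas.regions]
        assert len(labels) == 86
        assert len(set(labels)) == 86
        assert all(r.anatomy_xref for r in atlas.regions)

    def test_printed_t1w_axiom_constants(self, kb):
        (axiom,) = kb.axioms_for("MRIO:0000366")
        by_param = {c.parameter: c for c in axiom.constraints}
        tr, te, flip = by_param["tr_ms"], by_param["te_ms"], by_param["flip_deg"]
        assert (tr.low, tr.high, tr.low_inclusive, tr.high_inclusive) == (
            0.0,
            800.0,
            False,
            False,
        )
        assert (te.low, te.high) == (0.0, 30.0)
        assert flip.value == 90.0
        assert axiom.provenance == "PAPER"


class TestValidation:
    def test_bundle_is_valid(self, kb):
        report = validate_kb(kb)
        assert report.errors == []

    def test_defaulted_subtype_axioms_warn(self, kb):
        report = validate_kb(kb)
        defaulted = [a.type_iri for a in kb.axioms if a.provenance == "DEFAULT"]
        assert defaulted  # FLAIR, PD, DWI, fMRI, SPGR rules are filled in
        for iri in defaulted:
            assert any(iri in w for w in report.warnings)

    def test_duplicate_iri_reported(self):
        bad = KnowledgeBase(
            terms=(
                TermRecord("MRIO:0000001", "a"),
                TermRecord("MRIO:0000001", "b"),
            )
        )
        report = validate_kb(bad)
        assert sum("duplicate IRI" in e for e in report.errors) == 1

    def test_dangling_parent_reported(self):
        bad = KnowledgeBase(
            terms=(TermRecord("MRIO:0000001", "a", parent_iri="MRIO:0000099"),)
        )
        assert any("dangling parent" in e for e in validate_kb(bad).errors)

    def test_unresolvable_analysis_input_reported(self):
        bad = KnowledgeBase(
            terms=(TermRecord("MRIO:0000001", "a"),),
            analyses=(
                AnalysisSpec(
                    "MRIO:0000001", "a", input_dnf=(("MRIO:0000099",),)
                ),
            ),
        )
        errors = validate_kb(bad).errors
        assert sum("unresolvable input" in e for e in errors) == 1

    def test_cycle_reported(self):
        bad = KnowledgeBase(
            terms=(
                TermRecord("MRIO:0000001", "a", parent_iri="MRIO:0000002"),
                TermRecord("MRIO:0000002", "b", parent_iri="MRIO:0000001"),
            )
        )
        assert any("cycle" in e for e in validate_kb(bad).errors)


class TestSubsumption:
    def test_reflexive(self, kb):
        assert subsumes(kb, "MRIO:0000366", "MRIO:0000366")

    def test_flair_below_t2w_not_t1w(self, kb):
        assert subsumes(kb, "MRIO:0000367", "MRIO:0000511")
        assert not subsumes(kb, "MRIO:0000366", "MRIO:0000511")
        assert not subsumes(kb, "MRIO:0000511", "MRIO:0000367")

    def test_unknown_curie_raises(self, kb):
        with pytest.raises(NotFoundError, match="MRIO:9999999"):
            subsumes(kb, "MRIO:9999999", "MRIO:0000366")

    def test_matches_exhaustive_reachability(self, kb):
        """Parent-chain walking equals graph reachability on every pair."""
        g = nx.DiGraph()
        for t in kb.terms:
            g.add_node(t.iri)
            if t.parent_iri:
                g.add_edge(t.iri, t.parent_iri)  # child -> parent
        iris = [t.iri for t in kb.terms]
        closure = {n: nx.descendants(g, n) | {n} for n in iris}
        for desc in iris:
            for anc in iris:
                assert subsumes(kb, anc, desc) == (anc in closure[desc])

    def test_ancestors_ordered_nearest_first(self, kb):
        assert ancestors(kb, "MRIO:0000511")[:2] == (
            "MRIO:0000367",
            "OBI:0003334",
        )


class TestLookup:
    def test_curie(self, kb):
        assert lookup_term(kb, "MRIO:0000357").label == "repetition time"

    def test_label_case_insensitive(self, kb):
        assert lookup_term(kb, "Echo Time").iri == "MRIO:0000358"

    def test_bids_key_via_bridge(self, kb):
        assert lookup_term(kb, "EchoTime").iri == "MRIO:0000358"

    def test_dicom_tag_via_bridge(self, kb):
        assert lookup_term(kb, "(0018,0081)").iri == "MRIO:0000358"

    def test_missing_key(self, kb):
        with pytest.raises(NotFoundError):
            lookup_term(kb, "no-such-term")

    def test_ambiguous_label(self):
        dup = KnowledgeBase(
            terms=(
                TermRecord("MRIO:0000001", "Same Label"),
                TermRecord("MRIO:0000002", "same label"),
            )
        )
        with pytest.raises(AmbiguousLookupError):
            lookup_term(dup, "same  LABEL")


class TestRdf:
    def test_contains_printed_curies(self, kb):
        text = export_rdf(kb)
        for curie in ("MRIO:0000366", "MRIO:0000358", "MRIO:0000525"):
            assert curie in text

    def test_roundtrip_equality(self, kb):
        assert parse_rdf(export_rdf(kb)) == kb

    def test_export_is_serialization_fixed_point(self, kb):
        text = export_rdf(kb)
        assert export_rdf(parse_rdf(text)) == text

    def test_invalid_kb_refused_with_report(self):
        bad = KnowledgeBase(
            terms=(TermRecord("MRIO:0000001", "a", parent_iri="MRIO:0000099"),)
        )
        with pytest.raises(KBValidationError) as exc:
            export_rdf(bad)
        assert exc.value.report.errors

    def test_triple_count_matches_per_record_tally(self, kb):
        """Independent tally: sum each record's expected contribution."""
        from rdflib import Graph

        expected = 0
        analysis_iris = {a.iri for a in kb.analyses}
        for t in kb.terms:
            expected += 3  # type, label, namespace
            expected += bool(t.definition) + bool(t.parent_iri) + len(t.synonyms)
        for ax in kb.axioms:
            expected += 4  # hasTypeAxiom, type, index, provenance
            for c in ax.constraints:
                expected += 4  # hasConstraint, index, parameter, kind
                expected += 2 * (c.low is not None) + 2 * (c.high is not None)
                expected += (c.value is not None) + bool(c.tolerance)
                expected += len(c.allowed_values or ())
        for a in kb.analyses:
            expected += 2 + bool(a.software_family)  # type, provenance
            expected += a.iri not in {t.iri for t in kb.terms}  # label
            for conj in a.input_dnf:
                expected += 3 + len(conj)
            expected += 3 * len(a.outputs)
        expected += 9 * len(kb.bridge)
        for atlas in kb.atlases:
            expected += 1  # type
            expected += 4 * len(atlas.regions)
            expected += len(
                {
                    r.anatomy_xref
                    for r in atlas.regions
                    if r.anatomy_xref.startswith("UBERON:")
                }
            )  # one is-about triple per distinct anatomy term
        del analysis_iris
        g = Graph()
        g.parse(data=export_rdf(kb), format="turtle")
        assert len(g) == expected


class TestDocumentForm:
    def test_dict_roundtrip(self, kb):
        assert kb_from_dict(kb_to_dict(kb)) == kb

    def test_yaml_file_roundtrip(self, kb, tmp_path):
        from mriokit.knowledge_base import load_kb, save_kb

        path = tmp_path / "kb.yaml"
        save_kb(kb, path)
        assert load_kb(path) == kb
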