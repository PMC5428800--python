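"""Model compilation, the bundled IRF-GRN roster, and model file I/O."""
import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irfgrn.model import (
    AP1_PARTNERS,
    ETS_PARTNERS,
    PROGRAMME_A_GENES,
    PROGRAMME_B_GENES,
    InteractionRecord,
    ModelFormatError,
    PetriNetModel,
    Place,
    Transition,
    compile_interactions,
    default_roster,
    export_graphml,
    read_interactions,
    read_model,
    validate_model,
    write_interactions,
    write_model,
)
from irfgrn.synthetic import generate_random_small_net


class TestDefaultModel:
    def test_roster_counts(self, default_model):
        groups = {g: default_model.places_in_group(g) for g in
                  ("IRF1", "IRF4", "IRF8", "AP1", "ETS")}
        assert len(groups["ETS"]) == 11
        assert {p.id for p in groups["ETS"]} == set(ETS_PARTNERS)
        assert len(groups["AP1"]) == 4
        assert {p.id for p in groups["AP1"]} == set(AP1_PARTNERS)
        dna = [p for p in default_model.places if p.klass == "dna_element"]
        assert {p.id for p in dna} == {"AICE", "ISRE", "EICE"}
        genes = [p for p in default_model.places if p.klass == "output_gene"]
        assert len(genes) == len(PROGRAMME_A_GENES) + len(PROGRAMME_B_GENES) == 23
        processes = [p for p in default_model.places
                     if p.klass == "process_output"]
        assert len(processes) == 6

    def test_validates_cleanly(self, default_model):
        report = validate_model(default_model)
        assert report.errors == []
        assert report.warnings == []

    def test_every_ets_member_partners_irf8_at_isre(self, default_model):
        binding = [
            t for t in default_model.transitions
            if "IRF8" in t.activating_inputs and t.outputs == ("ISRE",)
        ]
        partners = {set(t.activating_inputs).difference({"IRF8"}).pop()
                    for t in binding}
        assert partners == set(ETS_PARTNERS)


class TestCompile:
    roster = [
        Place("IRF4", klass="transcription_factor", entry_group="IRF4",
              is_entry=True),
        *[Place(g, klass="transcription_factor", entry_group="ETS",
                is_entry=True) for g in ETS_PARTNERS],
        Place("EICE", klass="dna_element"),
        Place("Th2", klass="process_output", is_output=True),
    ]

    def test_family_expansion_counts(self):
        rec = InteractionRecord("IRF4", "ETS", "and", "EICE", ("Th2",))
        model = compile_interactions([rec], self.roster)
        binding = [t for t in model.transitions if t.outputs == ("EICE",)]
        assert len(binding) == len(ETS_PARTNERS)
        assert all("IRF4" in t.activating_inputs for t in binding)
        assert [t.outputs for t in model.transitions].count(("Th2",)) == 1

    def test_or_expansion_equals_union_of_single_partner_records(self):
        joint = compile_interactions(
            [InteractionRecord("IRF4", "ELF1", "or", "EICE", ("Th2",))],
            self.roster)
        split = compile_interactions(
            [InteractionRecord("IRF4", None, "or", "EICE", ("Th2",)),
             InteractionRecord("ELF1", None, "or", "EICE", ("Th2",))],
            self.roster)
        assert joint == split

    def test_sub_threshold_evidence_dropped_and_logged(self, caplog):
        records = [
            InteractionRecord("IRF4", "ELF1", "and", "EICE", ("Th2",)),
            InteractionRecord("IRF4", "ELF4", "and", "EICE", ("Th2",),
                              evidence_count=1),
        ]
        with caplog.at_level(logging.WARNING, logger="irfgrn.model"):
            model = compile_interactions(records, self.roster)
        assert not any("ELF4" in t.activating_inputs for t in model.transitions)
        assert sum("dropping" in r.message for r in caplog.records) == 1

    def test_deterministic(self):
        rec = [InteractionRecord("IRF4", "ETS", "and", "EICE", ("Th2",))]
        assert compile_interactions(rec, self.roster) == \
            compile_interactions(rec, self.roster)

    @pytest.mark.parametrize("records,roster,match", [
        ([InteractionRecord("NOPE", None, "or", None, ("Th2",))],
         roster, "NOPE"),
        ([InteractionRecord("IRF4", None, "or", None, ("MISSING",))],
         roster, "MISSING"),
        ([], roster, "empty record"),
        ([InteractionRecord("IRF4", None, "or", None, ("Th2",))], [], "roster"),
    ])
    def test_hard_errors(self, records, roster, match):
        with pytest.raises(ValueError, match=match):
            compile_interactions(records, roster)

    def test_inhibition_attaches_to_target_transitions(self):
        roster = self.roster + [
            Place("IL10R", klass="transcription_factor", is_entry=True)]
        records = [
            InteractionRecord("IRF4", "ELF1", "and", "EICE", ("Th2",)),
            InteractionRecord("IL10R", None, "inhibition", None, ("Th2",)),
        ]
        model = compile_interactions(records, roster)
        feeding = [t for t in model.transitions if "Th2" in t.outputs]
        assert all(t.inhibitory_inputs == ("IL10R",) for t in feeding)


class TestTypes:
    def test_entry_place_must_be_transcription_factor(self):
        with pytest.raises(ValueError, match="transcription factors"):
            Place("X", klass="dna_element", is_entry=True)

    def test_transition_input_lists_disjoint(self):
        with pytest.raises(ValueError, match="both activating and inhibitory"):
            Transition("t", ("A",), ("A",), ("B",))

    def test_gate_error_names_allowed_gates(self):
        with pytest.raises(ValueError, match="and, or, inhibition"):
            InteractionRecord("A", "B", "xor", None, ("C",))

    def test_duplicate_place_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PetriNetModel([Place("A"), Place("A")], [])


class TestValidate:
    def test_unknown_place_reference_is_error(self):
        model = PetriNetModel(
            [Place("A", is_entry=True)],
            [Transition("t1", ("A",), (), ("GHOST",))])
        report = validate_model(model)
        assert len(report.errors) == 1
        assert "t1" in report.errors[0] and "GHOST" in report.errors[0]

    def test_isolated_output_place_is_warning(self):
        model = PetriNetModel(
            [Place("A", is_entry=True),
             Place("OUT", klass="output_gene", is_output=True)], [])
        report = validate_model(model)
        assert report.ok
        assert any("OUT" in w for w in report.warnings)


class TestIO:
    def test_roundtrip_default_model(self, default_model, tmp_path):
        path = tmp_path / "model.tsv"
        write_model(default_model, path)
        assert read_model(path) == default_model

    def test_write_is_canonical(self, default_model, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_model(default_model, p1)
        write_model(read_model(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(n_places=st.integers(2, 14), n_transitions=st.integers(1, 20),
           seed=st.integers(0, 10_000))
    def test_roundtrip_random_models(self, n_places, n_transitions, seed,
                                     tmp_path_factory):
        model = generate_random_small_net(n_places, n_transitions, seed)
        path = tmp_path_factory.mktemp("rt") / "m.tsv"
        write_model(model, path)
        assert read_model(path) == model

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#PLACES\nA\tA\ttranscription_factor\tnone\t1\n")
        with pytest.raises(ModelFormatError, match="line 2"):
            read_model(path)

    def test_duplicate_id_rejected_on_read(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "#PLACES\n"
            "A\tA\ttranscription_factor\tnone\t1\t0\n"
            "A\tA\ttranscription_factor\tnone\t1\t0\n")
        with pytest.raises(ModelFormatError, match="duplicate"):
            read_model(path)

    def test_interaction_table_roundtrip_and_gate_error(self, tmp_path):
        records = [InteractionRecord("IRF4", "ETS", "and", "EICE",
                                     ("Th2",), 3)]
        path = tmp_path / "records.tsv"
        write_interactions(records, path)
        assert read_interactions(path) == records
        bad = tmp_path / "bad.tsv"
        bad.write_text("IRF4\tETS\txor\t-\tTh2\t2\n")
        with pytest.raises(ModelFormatError, match="and, or, inhibition"):
            read_interactions(bad)

    def test_graphml_export_is_wellformed_xml(self, default_model, tmp_path):
        lxml_etree = pytest.importorskip("lxml.etree")
        path = tmp_path / "model.graphml"
        export_graphml(default_model, path)
        tree = lxml_etree.parse(str(path))
        ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
        nodes = tree.findall(".//g:node", ns)
        edges = tree.findall(".//g:edge", ns)
        n_expected = len(default_model.places) + len(default_model.transitions)
        assert len(nodes) == n_expected
        assert len(edges) > 0
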