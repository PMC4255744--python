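"""Action identification, descriptor extraction and the full translation."""

import pytest

from conftest import BSA_NOTE, BSA_RECONSTITUTE, TCA_TEXT
from protoact.extract import (
    identify_actions,
    infer_carry_forward,
    protocol_to_dict,
    protocol_to_json,
    translate_protocol,
)
from protoact.textproc import normalize_text, split_sentences
from protoact.units import Quantity


def _step(protocol, label):
    return next(s for s in protocol.steps if s.action_label == label)


class TestIdentify:
    def test_two_actions(self, catalog):
        sentences = split_sentences(
            normalize_text("Adjust to 10% TCA. Incubate at 30°C overnight.")
        )
        instances, unmatched = identify_actions(sentences, catalog)
        assert [i.action_label for i in instances] == ["adjust", "incubate"]
        assert unmatched == []

    def test_multi_action_sentence_copies(self, catalog):
        sentences = split_sentences("Mix and incubate for 5 min.")
        instances, _ = identify_actions(sentences, catalog)
        assert [i.action_label for i in instances] == ["mix", "incubate"]
        assert all(i.sentence_copy == "Mix and incubate for 5 min." for i in instances)
        assert [i.step_index for i in instances] == [1, 2]

    def test_unmatched_sentence(self, catalog):
        sentences = split_sentences("This is important.")
        instances, unmatched = identify_actions(sentences, catalog)
        assert instances == [] and unmatched == [0]


@pytest.fixture(scope="module")
def protocol(catalog, config):
    return translate_protocol(TCA_TEXT, catalog, config)


class TestWorkedExample:

    def test_actions(self, protocol):
        assert [s.action_id for s in protocol.steps] == ["EXACT2_000089", "EXACT2_000049"]

    def test_adjust_entity_linked(self, protocol):
        adjust = _step(protocol, "adjust")
        entity = adjust.first_value("biochemical_entity")
        assert entity.value == "Trichloroacetic acid"
        assert entity.entity_id == ("NCBI Pubchem", "6421")

    def test_adjust_concentration(self, protocol):
        adjust = _step(protocol, "adjust")
        assert adjust.first_value("concentration").value == Quantity(10.0, "%")

    def test_incubate_temperature_with_uo_id(self, protocol):
        incubate = _step(protocol, "incubate")
        temp = incubate.first_value("temperature")
        assert temp.value == Quantity(30.0, "°C")
        assert temp.unit_id == "UO:0000027"
        assert temp.provenance == "extracted"

    def test_incubate_period_default(self, protocol):
        period = _step(protocol, "incubate").first_value("period")
        assert period.value == Quantity(16.0, "hour")
        assert period.provenance == "default"

    def test_incubate_missing_essentials(self, protocol):
        assert set(_step(protocol, "incubate").missing_essential) == {
            "biochemical_entity", "condition",
        }

    def test_descriptor_kinds_within_action_spec(self, protocol, catalog):
        for step in protocol.steps:
            action = catalog.get(step.action_id)
            allowed = set(action.essential_kinds) | set(action.optional_kinds)
            assert step.kinds() <= allowed

    def test_missing_disjoint_from_present(self, protocol):
        for step in protocol.steps:
            assert not set(step.missing_essential) & step.kinds()


class TestBsaExample:
    def test_reconstitute_concentration(self, catalog, config):
        protocol = translate_protocol(BSA_RECONSTITUTE, catalog, config)
        conc = _step(protocol, "reconstitute").first_value("concentration")
        assert conc.value == Quantity(100.0, "μg/mL")

    def test_note_sentence_volumes(self, units):
        from protoact.textproc import Sentence, find_quantities

        ms = find_quantities(Sentence(0, BSA_NOTE, (0, len(BSA_NOTE))), units)
        assert {(m.magnitude, m.unit_symbol) for m in ms} == {(20.0, "μL"), (100.0, "mL")}


class TestCarryForward:
    def test_entity_inherited(self, catalog, config):
        text = "Vortex the yeast growth culture.\nIncubate at 30°C overnight."
        protocol = translate_protocol(text, catalog, config, carry_forward=True)
        incubate = _step(protocol, "incubate")
        entity = incubate.first_value("biochemical_entity")
        assert entity.value == "yeast growth culture"
        assert entity.provenance == "inferred"
        assert "biochemical_entity" not in incubate.missing_essential

    def test_nothing_to_inherit(self, catalog, config):
        text = "Wait for 5 min.\nIncubate at 30°C overnight."
        protocol = translate_protocol(text, catalog, config, carry_forward=True)
        assert "biochemical_entity" in _step(protocol, "incubate").missing_essential

    def test_disabled_is_identity(self, catalog, config):
        text = "Vortex the yeast growth culture.\nIncubate at 30°C overnight."
        protocol = translate_protocol(text, catalog, config)
        untouched = infer_carry_forward(protocol, enabled=False)
        assert protocol_to_dict(untouched) == protocol_to_dict(protocol)


class TestTranslate:
    def test_empty_text(self, catalog, config):
        protocol = translate_protocol("", catalog, config)
        assert protocol.steps == [] and protocol.unmatched_sentences == []

    def test_deterministic(self, catalog, config):
        a = protocol_to_json(translate_protocol(TCA_TEXT, catalog, config))
        b = protocol_to_json(translate_protocol(TCA_TEXT, catalog, config))
        assert a == b

    def test_goal_capture(self, catalog, config):
        protocol = translate_protocol(
            "Centrifuge the cell suspension in order to check the pH.", catalog, config
        )
        assert protocol.steps[0].first_value("goal").value == "check the pH"

    def test_goal_clause_verb_not_an_action(self, catalog, config):
        protocol = translate_protocol(
            "Centrifuge the cell suspension to pellet cells.", catalog, config
        )
        assert [s.action_label for s in protocol.steps] == ["centrifuge"]
        assert protocol.steps[0].first_value("goal").value == "pellet cells"

    def test_condition_capture(self, catalog, config):
        protocol = translate_protocol(
            "Wash the ethanol under sterile conditions.", catalog, config
        )
        assert protocol.steps[0].first_value("condition").value == "sterile conditions"

    def test_unmatched_kept_as_note(self, catalog, config):
        protocol = translate_protocol(
            "Mix the ethanol for 5 min.\nDo not smoke.", catalog, config
        )
        assert protocol.unmatched_sentences == [1]
        assert any("Do not smoke." in n for n in protocol.steps[0].notes)

    def test_json_shape(self, catalog, config):
        doc = protocol_to_dict(translate_protocol(TCA_TEXT, catalog, config))
        assert set(doc) == {"title", "provenance", "steps", "unmatched"}
        step = doc["steps"][0]
        assert {"step_index", "action", "descriptors", "missing_essential",
                "source_sentence", "notes"} <= set(step)
        d = step["descriptors"][0]
        assert {"kind", "relation", "value", "unit", "unit_id", "entity_id",
                "provenance", "essential"} == set(d)
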