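"""Completeness reporting and user-in-the-loop correction."""

import pytest

from conftest import TCA_TEXT
from protoact.extract import translate_protocol
from protoact.validate import (
    AnswerError,
    IntegrityError,
    apply_user_answers,
    check_completeness,
    record_update_suggestions,
)


@pytest.fixture()
def tca_protocol(catalog, config):
    return translate_protocol(TCA_TEXT, catalog, config)


class TestCheck:
    def test_incomplete_report(self, tca_protocol, catalog):
        report = check_completeness(tca_protocol, catalog)
        assert report.status == "incomplete"
        by_label = {s.action_label: s for s in report.steps}
        assert by_label["adjust"].ok
        assert set(by_label["incubate"].missing_essential) == {
            "biochemical_entity", "condition",
        }

    def test_complete_protocol(self, catalog, config):
        protocol = translate_protocol(
            "Mix the ethanol for 5 min at 30°C.", catalog, config
        )
        assert check_completeness(protocol, catalog).status == "complete"

    def test_unknown_action_is_integrity_error(self, tca_protocol, catalog):
        tca_protocol.steps[0].action_id = "EXACT2_999999"
        with pytest.raises(IntegrityError):
            check_completeness(tca_protocol, catalog)

    def test_unmatched_does_not_block_complete(self, catalog, config):
        protocol = translate_protocol(
            "Mix the ethanol for 5 min.\nThis step is critical.", catalog, config
        )
        report = check_completeness(protocol, catalog)
        assert report.unmatched_sentences == [1]
        assert report.status == "complete"

    def test_report_text_mentions_missing(self, tca_protocol, catalog):
        text = check_completeness(tca_protocol, catalog).to_text()
        assert "incomplete" in text and "condition" in text


class TestAnswers:
    def test_answers_shrink_missing(self, tca_protocol, catalog):
        answers = {
            (2, "biochemical_entity"): "bFGF/EGF stock",
            (2, "condition"): "with shaking",
        }
        fixed = apply_user_answers(tca_protocol, answers, catalog)
        report = check_completeness(fixed, catalog)
        assert report.status == "complete"
        entity = fixed.steps[1].first_value("biochemical_entity")
        assert entity.provenance == "user"

    def test_empty_answers_identity(self, tca_protocol, catalog):
        from protoact.extract import protocol_to_dict

        same = apply_user_answers(tca_protocol, {}, catalog)
        assert protocol_to_dict(same) == protocol_to_dict(tca_protocol)

    def test_disallowed_kind_rejected(self, tca_protocol, catalog):
        with pytest.raises(AnswerError, match="speed"):
            apply_user_answers(tca_protocol, {(2, "speed"): "500 rpm"}, catalog)

    def test_quantity_answer_parsed(self, tca_protocol, catalog):
        fixed = apply_user_answers(
            tca_protocol, {(2, "temperature"): "37 °C"}, catalog
        )
        # user answer coexists with the extracted value; extracted is kept
        kinds = [d.provenance for d in fixed.steps[1].descriptors if d.kind == "temperature"]
        assert "extracted" in kinds and "user" in kinds

    def test_answers_never_remove_extracted(self, tca_protocol, catalog):
        before = {
            (s.step_index, d.kind, str(d.value))
            for s in tca_protocol.steps
            for d in s.descriptors
            if d.provenance == "extracted"
        }
        fixed = apply_user_answers(
            tca_protocol,
            {(2, "biochemical_entity"): "stock", (2, "condition"): "dark"},
            catalog,
        )
        after = {
            (s.step_index, d.kind, str(d.value))
            for s in fixed.steps
            for d in s.descriptors
            if d.provenance == "extracted"
        }
        assert before <= after

    def test_inferred_requires_confirmation(self, catalog, config):
        text = "Vortex the yeast growth culture.\nIncubate at 30°C overnight."
        protocol = translate_protocol(text, catalog, config, carry_forward=True)
        protocol = apply_user_answers(
            protocol, {(2, "condition"): "with shaking"}, catalog
        )
        report = check_completeness(protocol, catalog)
        assert report.status == "incomplete"
        assert report.steps[1].unconfirmed_inferred == ["biochemical_entity"]
        confirmed = apply_user_answers(
            protocol, {(2, "biochemical_entity"): "confirm"}, catalog
        )
        assert check_completeness(confirmed, catalog).status == "complete"


class TestSuggestions:
    def test_new_synonym(self, tca_protocol, catalog):
        (s,) = record_update_suggestions(tca_protocol, {"spin": "centrifuge"}, catalog)
        assert s.kind == "new_synonym" and s.verb == "spin"
        assert catalog.get(s.action_id).label == "centrifuge"

    def test_no_corrections(self, tca_protocol, catalog):
        assert record_update_suggestions(tca_protocol, {}, catalog) == []

    def test_known_verb_is_noop(self, tca_protocol, catalog):
        (s,) = record_update_suggestions(tca_protocol, {"mix": "mix"}, catalog)
        assert s.kind == "noop"
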