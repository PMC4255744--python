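"""Petri-net compilation, firing semantics and export."""

import xml.etree.ElementTree as ET

import pytest

from conftest import TCA_TEXT
from protoact.extract import translate_protocol
from protoact.petri import (
    NetError,
    compile_net,
    enabled_transitions,
    export_net,
    fire,
    import_net_json,
    simulate_run,
)
from protoact.validate import apply_user_answers


@pytest.fixture()
def complete_protocol(catalog, config):
    text = (
        "Mix the ethanol for 5 min.\n"
        "Vortex the cell suspension at 25°C.\n"
        "Centrifuge the cell suspension for 10 min."
    )
    return translate_protocol(text, catalog, config)


@pytest.fixture()
def tca_protocol(catalog, config):
    return translate_protocol(TCA_TEXT, catalog, config)


class TestCompile:
    def test_structure(self, complete_protocol, catalog):
        net = compile_net(complete_protocol, catalog)
        assert len(net.transitions) == 3
        seq = [p for p in net.places if p.role == "sequencing"]
        assert len(seq) == 4  # P0..P3
        assert net.initial_marking["P0"] == 1
        # every transition has at least one input arc
        for t in net.transitions:
            assert net.inputs(t.id)

    def test_descriptor_places_marked_iff_value_present(self, tca_protocol, catalog):
        net = compile_net(tca_protocol, catalog)
        cond = {p.id: p for p in net.places if p.role == "descriptor_condition"}
        # incubate (step 2): temperature & period present, entity & condition not
        assert net.initial_marking["D2_temperature"] == 1
        assert net.initial_marking["D2_period"] == 1
        assert net.initial_marking["D2_biochemical_entity"] == 0
        assert net.initial_marking["D2_condition"] == 0
        assert cond["D2_biochemical_entity"].label.endswith("?")

    def test_place_labels_carry_values(self, complete_protocol, catalog):
        net = compile_net(complete_protocol, catalog)
        labels = {p.label for p in net.places}
        assert "biochemical_entity: ethanol" in labels

    def test_empty_protocol_rejected(self, catalog, config):
        from protoact.extract import StructuredProtocol

        with pytest.raises(NetError, match="empty"):
            compile_net(StructuredProtocol(), catalog)

    def test_bipartite(self, complete_protocol, catalog):
        net = compile_net(complete_protocol, catalog)
        pids = {p.id for p in net.places}
        for a in net.arcs:
            assert (a.source in pids) != (a.target in pids)


class TestFiring:
    def test_initially_only_first_enabled(self, complete_protocol, catalog):
        net = compile_net(complete_protocol, catalog)
        assert enabled_transitions(net, net.initial_marking) == ["T1"]

    def test_unmarked_essential_disables(self, tca_protocol, catalog):
        net = compile_net(tca_protocol, catalog)
        m = fire(net, net.initial_marking, "T1")  # adjust fires
        assert enabled_transitions(net, m) == []  # incubate blocked

    def test_fire_moves_sequencing_token(self, complete_protocol, catalog):
        net = compile_net(complete_protocol, catalog)
        m = fire(net, net.initial_marking, "T1")
        assert m["P0"] == 0 and m["P1"] == 1

    def test_self_loop_conserves_descriptor_tokens(self, complete_protocol, catalog):
        net = compile_net(complete_protocol, catalog)
        m = dict(net.initial_marking)
        for t in ("T1", "T2", "T3"):
            m = fire(net, m, t)
            for p in net.places:
                if p.role == "descriptor_condition":
                    assert m[p.id] == net.initial_marking[p.id]

    def test_firing_disabled_is_error(self, complete_protocol, catalog):
        net = compile_net(complete_protocol, catalog)
        with pytest.raises(NetError, match="not enabled"):
            fire(net, net.initial_marking, "T2")


class TestSimulate:
    def test_complete_protocol_runs_through(self, complete_protocol, catalog):
        net = compile_net(complete_protocol, catalog)
        fired, completed, stuck = simulate_run(net)
        assert completed and stuck is None
        assert fired == ["T1", "T2", "T3"]  # firing order equals step order

    def test_incomplete_protocol_deadlocks(self, tca_protocol, catalog):
        net = compile_net(tca_protocol, catalog)
        fired, completed, stuck = simulate_run(net)
        assert not completed
        assert fired == ["T1"] and stuck == 2

    def test_empty_start_marking_stuck_at_first(self, complete_protocol, catalog):
        net = compile_net(complete_protocol, catalog)
        m = dict(net.initial_marking)
        m["P0"] = 0
        fired, completed, stuck = simulate_run(net, m)
        assert fired == [] and not completed and stuck == 1

    def test_user_answers_unlock_the_run(self, tca_protocol, catalog):
        fixed = apply_user_answers(
            tca_protocol,
            {(2, "biochemical_entity"): "stock", (2, "condition"): "dark"},
            catalog,
        )
        net = compile_net(fixed, catalog)
        _, completed, _ = simulate_run(net)
        assert completed


class TestExport:
    def test_pnml_parses(self, complete_protocol, catalog):
        net = compile_net(complete_protocol, catalog)
        root = ET.fromstring(export_net(net, "pnml"))
        assert root.tag.endswith("pnml")
        ns = "{http://www.pnml.org/version-2009/grammar/pnml}"
        places = root.findall(f".//{ns}place")
        transitions = root.findall(f".//{ns}transition")
        assert len(places) == len(net.places)
        assert len(transitions) == len(net.transitions)

    def test_dot_bipartite_shapes(self, complete_protocol, catalog):
        net = compile_net(complete_protocol, catalog)
        dot = export_net(net, "dot")
        assert "shape=circle" in dot and "shape=square" in dot

    def test_json_round_trip(self, complete_protocol, catalog):
        net = compile_net(complete_protocol, catalog)
        assert import_net_json(export_net(net, "json")) == net

    def test_unknown_format(self, complete_protocol, catalog):
        net = compile_net(complete_protocol, catalog)
        with pytest.raises(NetError, match="format"):
            export_net(net, "svg")
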