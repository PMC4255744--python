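"""Compile structured protocols into place/transition Petri nets.

A protocol becomes a linear workflow net: each step's action is a
*transition* (active node, drawn as a square), sequencing *places* (passive
nodes, circles) chain the transitions start→…→end, and every essential
descriptor of a step contributes a *condition place* connected to the
step's transition by a pair of self-loop arcs, so the condition is read but
never consumed.  The initial marking puts one token on the start place and
one token on each condition place whose descriptor value is actually
recorded (extracted, default, user-supplied, or user-confirmed).

Simulating the net then answers the executability question directly: the
run completes iff every step's essential conditions hold — a step whose
condition place is unmarked is a deadlock, the Petri-net face of "this
protocol cannot be reproduced as written".

Exports: PNML (ISO/IEC 15909-2 place/transition net), Graphviz DOT
(circles/squares), and JSON (round-trippable).
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .catalog import ActionCatalog
from .extract import StructuredProtocol
from .units import Quantity

__all__ = [
    "Place",
    "Transition",
    "Arc",
    "ProtocolNet",
    "NetError",
    "compile_net",
    "enabled_transitions",
    "fire",
    "simulate_run",
    "export_net",
    "import_net_json",
]


class NetError(ValueError):
    pass


@dataclass(frozen=True)
class Place:
    id: str
    label: str
    role: str = "sequencing"  # sequencing | descriptor_condition
    step_index: int | None = None  # set when role == descriptor_condition
    kind: str | None = None


@dataclass(frozen=True)
class Transition:
    id: str
    label: str  # action label
    step_index: int


@dataclass(frozen=True)
class Arc:
    source: str
    target: str
    weight: int = 1


Marking = dict  # place id -> token count


@dataclass
class ProtocolNet:
    places: list[Place] = field(default_factory=list)
    transitions: list[Transition] = field(default_factory=list)
    arcs: list[Arc] = field(default_factory=list)
    initial_marking: Marking = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        pids = {p.id for p in self.places}
        tids = {t.id for t in self.transitions}
        if len(pids) != len(self.places) or len(tids) != len(self.transitions):
            raise NetError("duplicate node ids")
        if pids & tids:
            raise NetError("place and transition ids overlap")
        for a in self.arcs:
            ok = (a.source in pids and a.target in tids) or (
                a.source in tids and a.target in pids
            )
            if not ok:
                raise NetError(f"arc {a.source}->{a.target} is not place<->transition")
            if a.weight < 1:
                raise NetError(f"arc {a.source}->{a.target} has weight {a.weight}")
        for count in self.initial_marking.values():
            if count < 0:
                raise NetError("negative token count in initial marking")

    def inputs(self, transition_id: str) -> list[Arc]:
        return [a for a in self.arcs if a.target == transition_id]

    def outputs(self, transition_id: str) -> list[Arc]:
        return [a for a in self.arcs if a.source == transition_id]


def compile_net(protocol: StructuredProtocol, catalog: ActionCatalog) -> ProtocolNet:
    """Compile a structured protocol into its workflow Petri net.

    Per step i: transition ``T_i``; sequencing places ``P_0 … P_n`` with
    arcs ``P_{i-1} -> T_i -> P_i``; per essential descriptor kind k a
    condition place ``D_i_k`` with self-loop arcs, marked iff the value is
    recorded.  Optional descriptors never gate firing and are omitted.
    """
    if not protocol.steps:
        raise NetError("cannot compile an empty protocol")
    places: list[Place] = [Place("P0", "start")]
    transitions: list[Transition] = []
    arcs: list[Arc] = []
    marking: Marking = {"P0": 1}
    chain = 0  # index of the newest sequencing place
    for step in protocol.steps:
        i = step.step_index
        action = catalog.get(step.action_id)
        if action is None:
            raise NetError(f"step {i}: unknown action {step.action_id}")
        tid = f"T{i}"
        transitions.append(Transition(tid, action.label, i))
        prev, nxt = f"P{chain}", f"P{chain + 1}"
        chain += 1
        places.append(Place(nxt, f"after step {i}"))
        marking[nxt] = 0
        arcs.append(Arc(prev, tid))
        arcs.append(Arc(tid, nxt))
        satisfied = {
            d.kind
            for d in step.descriptors
            if d.provenance in ("extracted", "default", "user")
        }
        for kind in action.essential_kinds:
            pid = f"D{i}_{kind}"
            value = step.first_value(kind)
            if value is not None and value.provenance in ("extracted", "default", "user"):
                if isinstance(value.value, Quantity):
                    label = f"{kind}: {value.value}"
                else:
                    label = f"{kind}: {value.value}"
            else:
                label = f"{kind}: ?"
            places.append(
                Place(pid, label, role="descriptor_condition", step_index=i, kind=kind)
            )
            # self-loop: the condition is read, not consumed
            arcs.append(Arc(pid, tid))
            arcs.append(Arc(tid, pid))
            marking[pid] = 1 if kind in satisfied else 0
    return ProtocolNet(places, transitions, arcs, marking)


def enabled_transitions(net: ProtocolNet, marking: Marking) -> list[str]:
    """Transitions whose every input place holds at least the arc weight."""
    enabled = []
    for t in net.transitions:
        if all(marking.get(a.source, 0) >= a.weight for a in net.inputs(t.id)):
            enabled.append(t.id)
    return enabled


def fire(net: ProtocolNet, marking: Marking, transition_id: str) -> Marking:
    """Fire one transition: consume on input arcs, produce on output arcs."""
    if transition_id not in {t.id for t in net.transitions}:
        raise NetError(f"unknown transition {transition_id}")
    if transition_id not in enabled_transitions(net, marking):
        raise NetError(f"transition {transition_id} is not enabled")
    out = dict(marking)
    for a in net.inputs(transition_id):
        out[a.source] = out.get(a.source, 0) - a.weight
    for a in net.outputs(transition_id):
        out[a.target] = out.get(a.target, 0) + a.weight
    return out


def simulate_run(
    net: ProtocolNet, marking: Marking | None = None
) -> tuple[list[str], bool, int | None]:
    """Run the net to quiescence.

    The compiled nets are linear chains, so at most one transition is
    enabled at a time; we fire it repeatedly.  Returns the fired sequence,
    whether every transition fired, and the step index of the first
    unfired transition otherwise (the deadlocked step).
    """
    marking = dict(net.initial_marking if marking is None else marking)
    fired: list[str] = []
    fired_set: set[str] = set()
    while True:
        enabled = [t for t in enabled_transitions(net, marking) if t not in fired_set]
        if not enabled:
            break
        tid = enabled[0]
        marking = fire(net, marking, tid)
        fired.append(tid)
        fired_set.add(tid)
    completed = len(fired) == len(net.transitions)
    stuck_step = None
    if not completed:
        stuck_step = min(t.step_index for t in net.transitions if t.id not in fired_set)
    return fired, completed, stuck_step


def export_net(net: ProtocolNet, format: str) -> str:
    """Serialize the net as ``pnml``, ``dot`` or ``json``."""
    fmt = format.lower()
    if fmt == "json":
        return json.dumps(
            {
                "places": [
                    {
                        "id": p.id,
                        "label": p.label,
                        "role": p.role,
                        "step_index": p.step_index,
                        "kind": p.kind,
                    }
                    for p in net.places
                ],
                "transitions": [
                    {"id": t.id, "label": t.label, "step_index": t.step_index}
                    for t in net.transitions
                ],
                "arcs": [
                    {"source": a.source, "target": a.target, "weight": a.weight}
                    for a in net.arcs
                ],
                "initial_marking": dict(net.initial_marking),
            },
            indent=2,
            ensure_ascii=False,
        )
    if fmt == "dot":
        lines = ["digraph protocol {", "  rankdir=LR;"]
        for p in net.places:
            tokens = net.initial_marking.get(p.id, 0)
            dot = " ●" * tokens
            lines.append(
                f'  "{p.id}" [shape=circle, label="{p.label}{dot}"];'
            )
        for t in net.transitions:
            lines.append(f'  "{t.id}" [shape=square, label="{t.label}"];')
        for a in net.arcs:
            w = f' [label="{a.weight}"]' if a.weight != 1 else ""
            lines.append(f'  "{a.source}" -> "{a.target}"{w};')
        lines.append("}")
        return "\n".join(lines)
    if fmt == "pnml":
        pnml = ET.Element("pnml", xmlns="http://www.pnml.org/version-2009/grammar/pnml")
        netel = ET.SubElement(
            pnml,
            "net",
            id="protocol-net",
            type="http://www.pnml.org/version-2009/grammar/ptnet",
        )
        page = ET.SubElement(netel, "page", id="page0")
        for p in net.places:
            pe = ET.SubElement(page, "place", id=p.id)
            ET.SubElement(ET.SubElement(pe, "name"), "text").text = p.label
            tokens = net.initial_marking.get(p.id, 0)
            if tokens:
                ET.SubElement(
                    ET.SubElement(pe, "initialMarking"), "text"
                ).text = str(tokens)
        for t in net.transitions:
            te = ET.SubElement(page, "transition", id=t.id)
            ET.SubElement(ET.SubElement(te, "name"), "text").text = t.label
        for i, a in enumerate(net.arcs):
            ae = ET.SubElement(
                page, "arc", id=f"a{i}", source=a.source, target=a.target
            )
            if a.weight != 1:
                ET.SubElement(
                    ET.SubElement(ae, "inscription"), "text"
                ).text = str(a.weight)
        ET.indent(pnml)
        return ET.tostring(pnml, encoding="unicode", xml_declaration=True)
    raise NetError(f"unknown export format {format!r} (use pnml, dot or json)")


def import_net_json(text: str) -> ProtocolNet:
    """Inverse of ``export_net(net, 'json')``."""
    doc = json.loads(text)
    return ProtocolNet(
        places=[
            Place(
                id=p["id"],
                label=p["label"],
                role=p.get("role", "sequencing"),
                step_index=p.get("step_index"),
                kind=p.get("kind"),
            )
            for p in doc["places"]
        ],
        transitions=[
            Transition(t["id"], t["label"], t["step_index"]) for t in doc["transitions"]
        ],
        arcs=[Arc(a["source"], a["target"], a.get("weight", 1)) for a in doc["arcs"]],
        initial_marking=dict(doc["initial_marking"]),
    )
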