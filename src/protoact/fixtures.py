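"""Seeded synthetic protocols with ground truth, and recovery scoring.

Real annotated protocol corpora are not redistributable, so every pipeline
stage is exercised against generated protocols whose intended parse is
known by construction.  Sentences are drawn from the template

    <Verb> the <entity> [at <T>°C | at RT] [for <n> min | for <n> h |
    overnight] [in the <equipment>] [under sterile conditions]
    [in order to <goal>].

using verbs from the action catalog, entities and equipment from the lab
config, and default tokens (RT, overnight) that the translator must resolve
through the defaults table.  The grammar deliberately stays inside the
clue-table coverage, so a correct pipeline recovers the ground truth
exactly; an ``adversarial`` flag adds out-of-grammar sentences (negations,
unknown verbs) that must degrade gracefully into unmatched notes.

The verb pool is restricted to actions whose essential descriptor set is
exactly {biochemical_entity}: the entity slot is always emitted, so
generated protocols are complete by construction, and incompleteness for
workflow tests is induced by deleting values afterwards.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

from .catalog import ActionCatalog, load_catalog
from .extract import StructuredProtocol
from .labconfig import LabConfig, load_lab_config
from .units import Quantity

__all__ = [
    "SentenceTruth",
    "GroundTruth",
    "generate_protocol",
    "score_recovery",
]


@dataclass(frozen=True)
class SentenceTruth:
    sentence_index: int
    action_id: str | None  # None for adversarial, action-free sentences
    descriptors: tuple[tuple[str, object, str | None], ...] = ()  # (kind, value, unit)
    default_tokens: tuple[str, ...] = ()
    entity_ids: tuple[tuple[str, str], ...] = ()


@dataclass
class GroundTruth:
    sentences: list[SentenceTruth] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "sentence_index": s.sentence_index,
                    "action_id": s.action_id,
                    "descriptors": [
                        {"kind": k, "value": v, "unit": u} for k, v, u in s.descriptors
                    ],
                    "default_tokens": list(s.default_tokens),
                    "entity_ids": [list(e) for e in s.entity_ids],
                }
                for s in self.sentences
            ],
            indent=2,
            ensure_ascii=False,
        )


_TEMPERATURES = [4, 16, 25, 30, 37, 42, 65, 95]
_GOALS = [
    "check the pH",
    "preserve the sample",
    "obtain a clear lysate",
    "prepare for the next step",
    "stabilize the suspension",
]
_ADVERSARIAL = [
    "Do not smoke in the laboratory.",
    "Cogitate on the expected outcome.",
    "This step is critical for reproducibility.",
]

# entities/equipment whose names would trip the clue table (embedded numbers
# or unit-like tokens) are excluded from the template pools
_HAZARD_SURFACES = ("%", "/")


def _pools(catalog: ActionCatalog, config: LabConfig):
    verbs = [
        a
        for a in catalog.actions
        if set(a.essential_kinds) == {"biochemical_entity"} and "-" not in a.label
    ]
    entities = [
        r
        for r in config.entities
        if not any(h in r.name for h in _HAZARD_SURFACES) and not any(c.isdigit() for c in r.name)
    ]
    equipment = [
        r
        for r in config.equipment
        if not any(c.isdigit() for c in r.name)
    ]
    return verbs, entities, equipment


def generate_protocol(
    seed: int,
    n_steps: int,
    catalog: ActionCatalog | None = None,
    config: LabConfig | None = None,
    adversarial: bool = False,
) -> tuple[str, GroundTruth]:
    """Generate a seeded synthetic protocol and its intended parse."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    catalog = catalog or load_catalog()
    config = config or load_lab_config()
    rng = random.Random(seed)
    verbs, entities, equipment = _pools(catalog, config)

    lines: list[str] = []
    truths: list[SentenceTruth] = []
    for _ in range(n_steps):
        action = rng.choice(verbs)
        entity = rng.choice(entities)
        parts = [f"{action.label.capitalize()} the {entity.name}"]
        descriptors: list[tuple[str, object, str | None]] = [
            ("biochemical_entity", entity.name, None)
        ]
        default_tokens: list[str] = []
        entity_ids = []
        if entity.id_source:
            entity_ids.append((entity.id_source, entity.id_value))

        if rng.random() < 0.7:  # temperature slot
            if rng.random() < 0.3:
                parts.append("at RT")
                descriptors.append(("temperature", 22.0, "°C"))
                default_tokens.append("RT")
            else:
                t = rng.choice(_TEMPERATURES)
                parts.append(f"at {t}°C")
                descriptors.append(("temperature", float(t), "°C"))
        if rng.random() < 0.7:  # period slot
            roll = rng.random()
            if roll < 0.3:
                parts.append("overnight")
                descriptors.append(("period", 16.0, "hour"))
                default_tokens.append("overnight")
            elif roll < 0.7:
                n = rng.randint(1, 60)
                parts.append(f"for {n} min")
                descriptors.append(("period", float(n), "min"))
            else:
                n = rng.randint(1, 24)
                parts.append(f"for {n} h")
                descriptors.append(("period", float(n), "h"))
        if rng.random() < 0.4:  # equipment slot
            eq = rng.choice(equipment)
            parts.append(f"in the {eq.name}")
            descriptors.append(("equipment", eq.name, None))
        if rng.random() < 0.3:  # condition slot
            parts.append("under sterile conditions")
            descriptors.append(("condition", "sterile conditions", None))
        if rng.random() < 0.3:  # goal slot (always last)
            goal = rng.choice(_GOALS)
            parts.append(f"in order to {goal}")
            descriptors.append(("goal", goal, None))

        lines.append(" ".join(parts) + ".")
        truths.append(
            SentenceTruth(
                sentence_index=len(lines) - 1,
                action_id=action.id,
                descriptors=tuple(descriptors),
                default_tokens=tuple(default_tokens),
                entity_ids=tuple(entity_ids),
            )
        )

    if adversarial:
        for text in rng.sample(_ADVERSARIAL, k=min(2, len(_ADVERSARIAL))):
            lines.append(text)
            truths.append(SentenceTruth(sentence_index=len(lines) - 1, action_id=None))

    return "\n".join(lines), GroundTruth(truths)


def score_recovery(
    protocol: StructuredProtocol, truth: GroundTruth
) -> tuple[float, float, float]:
    """(action recall, action precision, descriptor value accuracy).

    Actions are matched on (sentence index, action id).  Value accuracy is
    the fraction of ground-truth (kind, value, unit) triples found, with
    the same value and unit, on the matching step.
    """
    truth_actions = [
        (t.sentence_index, t.action_id) for t in truth.sentences if t.action_id
    ]
    predicted = [(s.sentence_index, s.action_id) for s in protocol.steps]
    remaining = list(predicted)
    matched = 0
    for ta in truth_actions:
        if ta in remaining:
            remaining.remove(ta)
            matched += 1
    recall = matched / len(truth_actions) if truth_actions else 1.0
    precision = (
        (len(predicted) - len(remaining)) / len(predicted) if predicted else 1.0
    )

    steps_by_key = {}
    for s in protocol.steps:
        steps_by_key.setdefault((s.sentence_index, s.action_id), s)
    total = hit = 0
    for t in truth.sentences:
        if not t.action_id:
            continue
        step = steps_by_key.get((t.sentence_index, t.action_id))
        for kind, value, unit in t.descriptors:
            total += 1
            if step is None:
                continue
            for d in step.descriptors:
                if d.kind != kind:
                    continue
                if isinstance(d.value, Quantity):
                    if (
                        unit is not None
                        and d.value.unit == unit
                        and abs(d.value.magnitude - float(value)) < 1e-9
                    ):
                        hit += 1
                        break
                elif unit is None and str(d.value).strip().lower() == str(value).strip().lower():
                    hit += 1
                    break
    accuracy = hit / total if total else 1.0
    return recall, precision, accuracy
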