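"""Translate protocol text into the structured, machine-amenable format.

The pipeline composes the earlier stages: normalize the text, expand
lab-specific abbreviations, split into sentences, identify one experimental
action per sentence copy (a sentence with several action verbs yields that
many copies), then fill each action's descriptor slots:

* quantity mentions are assigned to the descriptor kinds the action allows,
  via the unit clue table (30°C -> temperature);
* default tokens ("overnight", "room temperature") resolve through the lab
  defaults table, recorded with provenance ``default``;
* biochemical entities and equipment are linked to lab-config records and
  their external IDs;
* conditions, goals and protocol-method references are captured as verbatim
  text from a small prepositional-cue lexicon;
* optionally, a missing essential biochemical entity is inherited from the
  nearest preceding step (provenance ``inferred``, flagged for user
  confirmation).

Whatever the rules cannot place is preserved — unmatched sentences and
surplus mentions are kept as free-text notes, never discarded.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field, replace

from .catalog import (
    DESCRIPTOR_KINDS,
    ActionCatalog,
    descriptor_requirements,
    match_action_verb,
)
from .labconfig import EntityRecord, LabConfig, expand_abbreviations
from .textproc import (
    QuantityMention,
    Sentence,
    find_candidate_verbs,
    find_quantities,
    normalize_text,
    split_sentences,
)
from .units import Quantity, UnitTable, load_unit_table

__all__ = [
    "DescriptorValue",
    "ActionInstance",
    "StructuredProtocol",
    "identify_actions",
    "extract_descriptors",
    "infer_carry_forward",
    "translate_protocol",
    "protocol_to_dict",
    "protocol_to_json",
]


@dataclass
class DescriptorValue:
    kind: str
    value: Quantity | str
    unit_id: str | None = None
    entity_id: tuple[str, str] | None = None  # (source, value)
    provenance: str = "extracted"  # extracted | default | inferred | user
    char_span: tuple[int, int] | None = None
    essential: bool = False

    @property
    def relation(self) -> str:
        return DESCRIPTOR_KINDS[self.kind].relation


@dataclass
class ActionInstance:
    step_index: int  # 1-based
    action_id: str
    action_label: str
    sentence_index: int
    sentence_copy: str
    descriptors: list[DescriptorValue] = field(default_factory=list)
    missing_essential: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    verb_span: tuple[int, int] | None = None  # document offsets of the verb

    def kinds(self) -> set[str]:
        return {d.kind for d in self.descriptors}

    def first_value(self, kind: str) -> DescriptorValue | None:
        for d in self.descriptors:
            if d.kind == kind:
                return d
        return None


@dataclass
class StructuredProtocol:
    steps: list[ActionInstance] = field(default_factory=list)
    unmatched_sentences: list[int] = field(default_factory=list)
    title: str | None = None
    author: str | None = None
    source_path: str | None = None


def identify_actions(
    sentences: list[Sentence], catalog: ActionCatalog
) -> tuple[list[ActionInstance], list[int]]:
    """One ActionInstance per (sentence, matched verb); unmatched indices too.

    A sentence containing several action verbs yields that many instances,
    each holding its own copy of the sentence.
    """
    lexicon = catalog.verb_lexicon
    instances: list[ActionInstance] = []
    unmatched: list[int] = []
    for s in sentences:
        matched: list[tuple[str, tuple[int, int]]] = []
        seen_ids: set[str] = set()
        for lemma, span in find_candidate_verbs(s, lexicon=lexicon):
            action = match_action_verb(lemma, catalog)
            if action is not None and action.id not in seen_ids:
                matched.append((action.id, span))
                seen_ids.add(action.id)
        if not matched:
            unmatched.append(s.index)
            continue
        for action_id, span in matched:
            action = catalog.get(action_id)
            instances.append(
                ActionInstance(
                    step_index=len(instances) + 1,
                    action_id=action_id,
                    action_label=action.label,
                    sentence_index=s.index,
                    sentence_copy=s.text,
                    verb_span=span,
                )
            )
    return instances, unmatched


def _pick_mention(
    mentions: list[QuantityMention], kind: str, sentence: Sentence, verb_span
) -> tuple[QuantityMention, list[QuantityMention]]:
    """Choose one mention when several share a kind; return (winner, losers).

    A concentration explicitly introduced by the cue "concentration of"
    outranks bare or entity-adjacent mentions; remaining ties go to the
    mention nearest the action verb.
    """
    pool = mentions
    if kind == "concentration" and len(mentions) > 1:
        base = sentence.char_span[0]
        cued = [
            m
            for m in mentions
            if re.search(r"concentration of\s*$", sentence.text[: m.char_span[0] - base])
        ]
        if cued:
            pool = cued
    anchor = verb_span[0] if verb_span else sentence.char_span[0]
    winner = min(pool, key=lambda m: (abs(m.char_span[0] - anchor), m.char_span[0]))
    return winner, [m for m in mentions if m is not winner]


def _find_records(
    sentence: Sentence, records: list[EntityRecord]
) -> list[tuple[EntityRecord, tuple[int, int]]]:
    """Non-overlapping, case-insensitive occurrences of record names/aliases,
    longest surface form first."""
    surfaces: list[tuple[str, EntityRecord]] = []
    for r in records:
        for name in (r.name, *r.aliases):
            surfaces.append((name, r))
    surfaces.sort(key=lambda x: len(x[0]), reverse=True)
    base = sentence.char_span[0]
    taken: list[tuple[int, int]] = []
    hits: list[tuple[EntityRecord, tuple[int, int]]] = []
    lowered = sentence.text.lower()
    for name, rec in surfaces:
        for m in re.finditer(re.escape(name.lower()), lowered):
            s, e = m.start(), m.end()
            if (s > 0 and lowered[s - 1].isalnum()) or (e < len(lowered) and lowered[e].isalnum()):
                continue  # token boundary
            if any(s < te and ts < e for ts, te in taken):
                continue
            taken.append((s, e))
            hits.append((rec, (base + s, base + e)))
    hits.sort(key=lambda h: h[1][0])
    return hits


_CONDITION_CUES = [
    re.compile(r"\bunder ([^.,;]+)"),
    re.compile(r"\bin the presence of ([^.,;]+)"),
    re.compile(r"\bwith (\w+ing\b[^.,;]*)"),
]
_GOAL_CUES = [
    re.compile(r"\bin order to ([^.;]+)"),
    re.compile(r",? to ([a-z]+(?: [^.;]*)?)[.;]?$"),
]
_GOAL_STOPWORDS = {"the", "a", "an", "each", "all", "this", "that", "its", "it"}
_METHOD_CUES = [
    re.compile(r"\baccording to ([^.,;]+)"),
    re.compile(r"\bas described in ([^.,;]+)"),
]


def _capture_text(
    cues: list[re.Pattern[str]], sentence: Sentence
) -> tuple[str, tuple[int, int]] | None:
    for cue in cues:
        m = cue.search(sentence.text)
        if m:
            text = m.group(1).strip().rstrip(".;,")
            if not text:
                continue
            # a goal clause must open with a verb-like word, not a determiner
            if cues is _GOAL_CUES and text.split()[0] in _GOAL_STOPWORDS:
                continue
            # do not let a condition swallow a trailing goal clause
            cut = text.find(" in order to")
            if cut != -1:
                text = text[:cut].rstrip(".;,")
            if text:
                base = sentence.char_span[0]
                return text, (base + m.start(1), base + m.start(1) + len(text))
    return None


def extract_descriptors(
    instance: ActionInstance,
    sentence: Sentence,
    catalog: ActionCatalog,
    config: LabConfig,
    units: UnitTable | None = None,
) -> ActionInstance:
    """Fill descriptor slots of one action instance from its sentence."""
    units = units or load_unit_table()
    action = catalog.get(instance.action_id)
    if action is None:
        raise KeyError(f"action {instance.action_id} not in catalog")
    essential, optional = descriptor_requirements(action)
    allowed = set(essential) | set(optional)
    ess = set(essential)
    values: list[DescriptorValue] = []
    notes = list(instance.notes)

    # --- quantity mentions --------------------------------------------------
    by_kind: dict[str, list[QuantityMention]] = {}
    for m in find_quantities(sentence, units):
        if m.kind_hint in allowed:
            by_kind.setdefault(m.kind_hint, []).append(m)
        else:
            kind = m.kind_hint or "unknown-kind"
            notes.append(f"unplaced quantity ({kind}): {m.magnitude:g} {m.unit_symbol}")
    for kind, ms in by_kind.items():
        winner, losers = _pick_mention(ms, kind, sentence, instance.verb_span)
        if winner.unit_id is None:
            notes.append(f"unknown unit id for {kind}: {winner.unit_symbol}")
        values.append(
            DescriptorValue(
                kind=kind,
                value=Quantity(winner.magnitude, winner.unit_symbol),
                unit_id=winner.unit_id,
                char_span=winner.char_span,
                essential=kind in ess,
            )
        )
        for m in losers:
            notes.append(f"unused {kind} mention: {m.magnitude:g} {m.unit_symbol}")

    # --- participants: biochemical entities and equipment -------------------
    if "biochemical_entity" in allowed:
        ehits = _find_records(sentence, config.entities)
        anchor = instance.verb_span[0] if instance.verb_span else sentence.char_span[0]
        ehits.sort(key=lambda h: (abs(h[1][0] - anchor), h[1][0]))
        seen: set[str] = set()
        for rec, span in ehits:
            if rec.name in seen:
                continue
            seen.add(rec.name)
            entity_id = (rec.id_source, rec.id_value) if rec.id_source else None
            values.append(
                DescriptorValue(
                    kind="biochemical_entity",
                    value=rec.name,
                    entity_id=entity_id,
                    char_span=span,
                    essential="biochemical_entity" in ess,
                )
            )
    if "equipment" in allowed:
        for rec, span in _find_records(sentence, config.equipment):
            entity_id = (rec.id_source, rec.id_value) if rec.id_source else None
            values.append(
                DescriptorValue(
                    kind="equipment",
                    value=rec.name,
                    entity_id=entity_id,
                    char_span=span,
                    essential="equipment" in ess,
                )
            )
            break  # one equipment slot

    # --- defaults for ambiguous tokens --------------------------------------
    placed = {v.kind for v in values}
    for token, setting in config.defaults.items():
        if setting.kind not in allowed or setting.kind in placed:
            continue
        m = re.search(rf"(?<!\w){re.escape(token)}(?!\w)", sentence.text, re.IGNORECASE)
        if m:
            base = sentence.char_span[0]
            info = units.resolve(setting.quantity.unit)
            values.append(
                DescriptorValue(
                    kind=setting.kind,
                    value=setting.quantity,
                    unit_id=info.uo_id if info else None,
                    provenance="default",
                    char_span=(base + m.start(), base + m.end()),
                    essential=setting.kind in ess,
                )
            )
            placed.add(setting.kind)

    # --- propositions: condition, goal, protocol method ---------------------
    for kind, cues in (
        ("condition", _CONDITION_CUES),
        ("goal", _GOAL_CUES),
        ("protocol_method", _METHOD_CUES),
    ):
        if kind not in allowed or kind in placed:
            continue
        cap = _capture_text(cues, sentence)
        if cap:
            text, span = cap
            values.append(
                DescriptorValue(kind=kind, value=text, char_span=span, essential=kind in ess)
            )
            placed.add(kind)

    missing = [k for k in essential if k not in {v.kind for v in values}]
    return replace(instance, descriptors=values, missing_essential=missing, notes=notes)


def infer_carry_forward(protocol: StructuredProtocol, enabled: bool = True) -> StructuredProtocol:
    """Inherit a missing essential biochemical entity from the nearest
    preceding step; inherited values are flagged ``inferred`` and await user
    confirmation.  No other descriptor kind is carried forward."""
    if not enabled:
        return protocol
    out = copy.deepcopy(protocol)
    last: DescriptorValue | None = None
    for step in out.steps:
        if "biochemical_entity" in step.missing_essential and last is not None:
            step.descriptors.append(
                DescriptorValue(
                    kind="biochemical_entity",
                    value=last.value,
                    entity_id=last.entity_id,
                    provenance="inferred",
                    essential=True,
                )
            )
            step.missing_essential = [
                k for k in step.missing_essential if k != "biochemical_entity"
            ]
        candidate = step.first_value("biochemical_entity")
        if candidate is not None:
            last = candidate
    return out


def translate_protocol(
    text: str | bytes,
    catalog: ActionCatalog,
    config: LabConfig,
    units: UnitTable | None = None,
    carry_forward: bool = False,
    title: str | None = None,
    author: str | None = None,
    source_path: str | None = None,
) -> StructuredProtocol:
    """Full translation: raw text in, structured protocol out.  Deterministic."""
    units = units or load_unit_table()
    doc = normalize_text(text)
    doc, _subs = expand_abbreviations(doc, config)
    sentences = split_sentences(doc)
    instances, unmatched = identify_actions(sentences, catalog)
    by_index = {s.index: s for s in sentences}
    steps = [
        extract_descriptors(inst, by_index[inst.sentence_index], catalog, config, units)
        for inst in instances
    ]
    # attach unmatched sentences as notes to the nearest (preferably
    # preceding) step; they are retained verbatim, never parsed
    for idx in unmatched:
        target = None
        for step in steps:
            if step.sentence_index < idx:
                target = step
        if target is None and steps:
            target = steps[0]
        if target is not None:
            target.notes.append(f"unmatched sentence: {by_index[idx].text}")
    protocol = StructuredProtocol(
        steps=steps,
        unmatched_sentences=unmatched,
        title=title,
        author=author,
        source_path=source_path,
    )
    return infer_carry_forward(protocol, enabled=carry_forward)


def protocol_to_dict(protocol: StructuredProtocol) -> dict:
    """JSON-ready representation (shape documented in protocol.schema.json)."""

    def _value(d: DescriptorValue):
        if isinstance(d.value, Quantity):
            return d.value.magnitude
        return d.value

    return {
        "title": protocol.title,
        "provenance": {
            "author": protocol.author,
            "source_path": protocol.source_path,
        },
        "steps": [
            {
                "step_index": s.step_index,
                "action": {"id": s.action_id, "label": s.action_label},
                "descriptors": [
                    {
                        "kind": d.kind,
                        "relation": d.relation,
                        "value": _value(d),
                        "unit": d.value.unit if isinstance(d.value, Quantity) else None,
                        "unit_id": d.unit_id,
                        "entity_id": (
                            {"source": d.entity_id[0], "value": d.entity_id[1]}
                            if d.entity_id
                            else None
                        ),
                        "provenance": d.provenance,
                        "essential": d.essential,
                    }
                    for d in s.descriptors
                ],
                "missing_essential": list(s.missing_essential),
                "source_sentence": s.sentence_copy,
                "notes": list(s.notes),
            }
            for s in protocol.steps
        ],
        "unmatched": list(protocol.unmatched_sentences),
    }


def protocol_to_json(protocol: StructuredProtocol, indent: int = 2) -> str:
    return json.dumps(protocol_to_dict(protocol), indent=indent, ensure_ascii=False)
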