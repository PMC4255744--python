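"""Completeness checking and user-in-the-loop correction.

An action can be reproduced by another lab only if all of its essential
descriptor values are recorded.  ``check_completeness`` reports, per step,
the essential kinds with no value, inferred values still awaiting user
confirmation, and quantity values whose unit has no ontology accession.
``apply_user_answers`` folds user-supplied values back into the protocol
(provenance ``user``), and ``record_update_suggestions`` turns manual verb
mappings into curation suggestions for the catalog — the catalog itself is
never mutated automatically.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .catalog import DESCRIPTOR_KINDS, ActionCatalog, descriptor_requirements
from .extract import ActionInstance, DescriptorValue, StructuredProtocol
from .units import Quantity, UnitTable, load_unit_table

__all__ = [
    "StepReport",
    "ValidationReport",
    "IntegrityError",
    "AnswerError",
    "check_completeness",
    "apply_user_answers",
    "record_update_suggestions",
    "UpdateSuggestion",
]


class IntegrityError(ValueError):
    """The protocol references an action absent from the catalog."""


class AnswerError(ValueError):
    """A user answer targets a step or descriptor kind that does not exist."""


@dataclass
class StepReport:
    step_index: int
    action_id: str
    action_label: str
    missing_essential: list[str]
    unconfirmed_inferred: list[str]
    unknown_units: list[str]

    @property
    def ok(self) -> bool:
        return not self.missing_essential and not self.unconfirmed_inferred


@dataclass
class ValidationReport:
    steps: list[StepReport] = field(default_factory=list)
    unmatched_sentences: list[int] = field(default_factory=list)
    status: str = "complete"  # complete | incomplete

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "steps": [
                {
                    "step_index": s.step_index,
                    "action": {"id": s.action_id, "label": s.action_label},
                    "missing_essential": s.missing_essential,
                    "unconfirmed_inferred": s.unconfirmed_inferred,
                    "unknown_units": s.unknown_units,
                }
                for s in self.steps
            ],
            "unmatched_sentences": self.unmatched_sentences,
        }

    def to_text(self) -> str:
        lines = [f"protocol status: {self.status}"]
        for s in self.steps:
            flags = []
            if s.missing_essential:
                flags.append("missing essential: " + ", ".join(s.missing_essential))
            if s.unconfirmed_inferred:
                flags.append("inferred, please confirm: " + ", ".join(s.unconfirmed_inferred))
            if s.unknown_units:
                flags.append("unit without ontology id: " + ", ".join(s.unknown_units))
            state = "; ".join(flags) if flags else "ok"
            lines.append(f"  step {s.step_index} ({s.action_label}): {state}")
        if self.unmatched_sentences:
            lines.append(
                "  unmatched sentences (kept as notes): "
                + ", ".join(str(i) for i in self.unmatched_sentences)
            )
        return "\n".join(lines)


def check_completeness(protocol: StructuredProtocol, catalog: ActionCatalog) -> ValidationReport:
    """Per-step completeness report; deterministic.

    Status is ``complete`` iff every step has an empty missing-essential set
    and no inferred essential value is still unconfirmed.  Unmatched
    sentences persist as notes and do not block completeness.
    """
    reports: list[StepReport] = []
    for step in protocol.steps:
        action = catalog.get(step.action_id)
        if action is None:
            raise IntegrityError(f"step {step.step_index}: unknown action {step.action_id}")
        essential = set(action.essential_kinds)
        unconfirmed = sorted(
            {d.kind for d in step.descriptors if d.provenance == "inferred" and d.kind in essential}
        )
        unknown_units = sorted(
            {
                d.kind
                for d in step.descriptors
                if isinstance(d.value, Quantity) and d.unit_id is None
            }
        )
        reports.append(
            StepReport(
                step_index=step.step_index,
                action_id=step.action_id,
                action_label=step.action_label,
                missing_essential=list(step.missing_essential),
                unconfirmed_inferred=unconfirmed,
                unknown_units=unknown_units,
            )
        )
    status = "complete" if all(r.ok for r in reports) else "incomplete"
    return ValidationReport(
        steps=reports,
        unmatched_sentences=list(protocol.unmatched_sentences),
        status=status,
    )


CONFIRM = "confirm"  # sentinel answer that confirms an inferred value


def apply_user_answers(
    protocol: StructuredProtocol,
    answers: dict[tuple[int, str], object],
    catalog: ActionCatalog,
    units: UnitTable | None = None,
) -> StructuredProtocol:
    """Insert user-supplied descriptor values; monotone completion.

    Answers map ``(step_index, kind)`` to a value: a string for text or
    entity kinds, a :class:`Quantity` (or ``"<number> <unit>"`` string) for
    quantity kinds, or the sentinel ``"confirm"`` to confirm an inferred
    value.  Extracted values are never removed; inferred and default values
    of the answered kind are superseded.
    """
    units = units or load_unit_table()
    out = copy.deepcopy(protocol)
    by_index = {s.step_index: s for s in out.steps}
    for (step_index, kind), raw in answers.items():
        step = by_index.get(step_index)
        if step is None:
            raise AnswerError(f"no step with index {step_index}")
        action = catalog.get(step.action_id)
        if action is None:
            raise IntegrityError(f"step {step_index}: unknown action {step.action_id}")
        essential, optional = descriptor_requirements(action)
        if kind not in set(essential) | set(optional):
            raise AnswerError(
                f"step {step_index} ({step.action_label}): descriptor kind {kind!r} "
                f"is not allowed for this action (allowed: "
                f"{', '.join(essential + optional)})"
            )
        existing = step.first_value(kind)
        if raw in (CONFIRM, True):
            if existing is None:
                raise AnswerError(
                    f"step {step_index}: nothing to confirm for kind {kind!r}"
                )
            existing.provenance = "user"
            continue
        value, unit_id = _coerce_value(kind, raw, units)
        # supersede machine-guessed values; keep extracted/user ones
        step.descriptors = [
            d
            for d in step.descriptors
            if not (d.kind == kind and d.provenance in ("inferred", "default"))
        ]
        step.descriptors.append(
            DescriptorValue(
                kind=kind,
                value=value,
                unit_id=unit_id,
                provenance="user",
                essential=kind in set(essential),
            )
        )
        step.missing_essential = [k for k in step.missing_essential if k != kind]
    return out


def _coerce_value(kind: str, raw: object, units: UnitTable) -> tuple[Quantity | str, str | None]:
    value_class = DESCRIPTOR_KINDS[kind].value_class
    if value_class == "quantity":
        if isinstance(raw, Quantity):
            q = raw
        else:
            parts = str(raw).split(None, 1)
            if len(parts) != 2:
                raise AnswerError(
                    f"{kind!r} needs a quantity like '30 °C', got {raw!r}"
                )
            try:
                q = Quantity(float(parts[0]), parts[1])
            except ValueError as exc:
                raise AnswerError(f"{kind!r}: non-numeric magnitude in {raw!r}") from exc
        info = units.resolve(q.unit)
        return q, info.uo_id if info else None
    return str(raw), None


@dataclass(frozen=True)
class UpdateSuggestion:
    """A curation suggestion emitted from user corrections (never applied
    automatically)."""

    kind: str  # new_synonym | noop
    verb: str
    action_id: str
    note: str = ""


def record_update_suggestions(
    protocol: StructuredProtocol,
    corrections: dict[str, str],
    catalog: ActionCatalog,
) -> list[UpdateSuggestion]:
    """Turn manual verb→action mappings into catalog curation suggestions.

    ``corrections`` maps a verb the user resolved by hand to the id (or
    label) of the action it should denote.  Verbs already in the catalog
    lexicon yield a no-op suggestion with a note.
    """
    suggestions: list[UpdateSuggestion] = []
    labels = {a.label: a.id for a in catalog.actions}
    for verb, target in corrections.items():
        action_id = labels.get(target, target)
        if catalog.get(action_id) is None:
            raise IntegrityError(f"correction {verb!r}: unknown action {target!r}")
        if verb in catalog.verb_lexicon:
            suggestions.append(
                UpdateSuggestion(
                    kind="noop",
                    verb=verb,
                    action_id=action_id,
                    note=f"verb {verb!r} already maps to an action in the catalog",
                )
            )
        else:
            suggestions.append(
                UpdateSuggestion(
                    kind="new_synonym",
                    verb=verb,
                    action_id=action_id,
                    note=f"add {verb!r} as a synonym of {action_id}",
                )
            )
    return suggestions
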