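"""The experimental-action catalog.

The catalog is the reference model for protocol translation: one entry per
atomic laboratory operation (incubate, store, aliquot, ...), each defined by
a set of typed *descriptors*.  A descriptor is either *essential* — its
value must be recorded for the action to be reproducible by another lab —
or *optional*.  Descriptors are linked to actions by one of three semantic
relations:

* ``is-participant-of`` — material participants (biochemical entity,
  equipment), referenced by external IDs;
* ``is-quality-of`` — measurable qualities (temperature, volume, speed,
  concentration), quantity-valued;
* ``is-proposition`` — statements about the action (period, condition,
  goal, protocol method, time point).

Entries carry a provenance tag: ``legacy`` (carried over from the previous
catalog revision), ``added_v2`` (new in this revision), or ``imported_obi``
(imported from the Ontology for Biomedical Investigations).  External-term
imports follow the MIREOT convention: source ontology URI, term URI and
target superclass URI are all recorded.

The bundled catalog ships as YAML in ``data/actions.yaml``; an OBO-like
flat export is provided for interop.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = [
    "DESCRIPTOR_KINDS",
    "DescriptorKind",
    "DescriptorSpec",
    "ExperimentalAction",
    "ImportedTerm",
    "ActionCatalog",
    "CatalogError",
    "CatalogFormatError",
    "CatalogValidationError",
    "load_catalog",
    "match_action_verb",
    "descriptor_requirements",
    "catalog_stats",
    "export_obo",
]

PROVENANCES = ("legacy", "added_v2", "imported_obi")
_ID_RE = re.compile(r"^EXACT2_\d{6}$")


@dataclass(frozen=True)
class DescriptorKind:
    """A descriptor type: its semantic relation and value class."""

    name: str
    relation: str  # is-participant-of | is-proposition | is-quality-of
    value_class: str  # quantity | entity_ref | text


#: Registry of all descriptor kinds an action may declare.
DESCRIPTOR_KINDS: dict[str, DescriptorKind] = {
    k.name: k
    for k in (
        DescriptorKind("biochemical_entity", "is-participant-of", "entity_ref"),
        DescriptorKind("equipment", "is-participant-of", "entity_ref"),
        DescriptorKind("temperature", "is-quality-of", "quantity"),
        DescriptorKind("volume", "is-quality-of", "quantity"),
        DescriptorKind("speed", "is-quality-of", "quantity"),
        DescriptorKind("concentration", "is-quality-of", "quantity"),
        DescriptorKind("period", "is-proposition", "quantity"),
        DescriptorKind("condition", "is-proposition", "text"),
        DescriptorKind("goal", "is-proposition", "text"),
        DescriptorKind("protocol_method", "is-proposition", "text"),
        DescriptorKind("time_point", "is-proposition", "quantity"),
    )
}


@dataclass(frozen=True)
class DescriptorSpec:
    kind: str  # key into DESCRIPTOR_KINDS
    essential: bool


@dataclass
class ExperimentalAction:
    """One catalog entry: a verb class with its descriptor requirements."""

    id: str
    label: str
    definition: str
    synonyms: list[str] = field(default_factory=list)
    descriptors: list[DescriptorSpec] = field(default_factory=list)
    external_mapping: str | None = None  # "has synonym" annotation, e.g. "OBI:storage"
    provenance: str = "legacy"

    @property
    def essential_kinds(self) -> list[str]:
        return [d.kind for d in self.descriptors if d.essential]

    @property
    def optional_kinds(self) -> list[str]:
        return [d.kind for d in self.descriptors if not d.essential]

    @property
    def lemmas(self) -> list[str]:
        return [self.label, *self.synonyms]


@dataclass(frozen=True)
class ImportedTerm:
    """A MIREOT record for an external ontology term."""

    source_ontology: str
    term_uri: str
    target_superclass: str
    label: str | None = None


class CatalogError(ValueError):
    pass


class CatalogFormatError(CatalogError):
    """The file does not parse as the documented catalog format."""


class CatalogValidationError(CatalogError):
    """The parsed catalog violates a structural invariant."""


@dataclass
class ActionCatalog:
    actions: list[ExperimentalAction] = field(default_factory=list)
    imported_terms: list[ImportedTerm] = field(default_factory=list)
    version: str = "0"

    def __post_init__(self) -> None:
        self._by_id = {a.id: a for a in self.actions}
        self._by_lemma: dict[str, ExperimentalAction] = {}
        for a in self.actions:
            for lemma in a.lemmas:
                self._by_lemma.setdefault(lemma, a)

    def get(self, action_id: str) -> ExperimentalAction | None:
        return self._by_id.get(action_id)

    @property
    def verb_lexicon(self) -> frozenset[str]:
        return frozenset(self._by_lemma)

    def __len__(self) -> int:
        return len(self.actions)


def _validate(catalog: ActionCatalog) -> None:
    problems: list[str] = []
    seen_ids: set[str] = set()
    seen_lemmas: dict[str, str] = {}
    for a in catalog.actions:
        if not _ID_RE.match(a.id):
            problems.append(f"{a.id}: id does not match pattern EXACT2_NNNNNN")
        if a.id in seen_ids:
            problems.append(f"{a.id}: duplicate id")
        seen_ids.add(a.id)
        if a.provenance not in PROVENANCES:
            problems.append(f"{a.id}: unknown provenance {a.provenance!r}")
        for lemma in a.lemmas:
            if lemma in seen_lemmas:
                problems.append(
                    f"{a.id}: verb {lemma!r} already maps to {seen_lemmas[lemma]}"
                )
            seen_lemmas[lemma] = a.id
        kinds = [d.kind for d in a.descriptors]
        for k in kinds:
            if k not in DESCRIPTOR_KINDS:
                problems.append(f"{a.id}: unknown descriptor kind {k!r}")
        dupes = {k for k in kinds if kinds.count(k) > 1}
        if dupes:
            problems.append(f"{a.id}: descriptor kinds listed twice: {sorted(dupes)}")
    for t in catalog.imported_terms:
        if not (t.source_ontology and t.term_uri and t.target_superclass):
            problems.append(f"imported term {t.label or t.term_uri!r}: incomplete MIREOT triple")
    if problems:
        raise CatalogValidationError(
            "catalog validation failed:\n  " + "\n  ".join(problems)
        )


def load_catalog(path: str | None = None) -> ActionCatalog:
    """Load and validate a catalog file (YAML); bundled default if ``path`` is None."""
    if path is None:
        text = resources.files("protoact").joinpath("data/actions.yaml").read_text("utf-8")
        src = "<bundled>"
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        src = str(path)
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # carries line info via problem_mark
        raise CatalogFormatError(f"{src}: not valid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "actions" not in doc:
        raise CatalogFormatError(f"{src}: expected a mapping with an 'actions' list")
    actions = []
    for i, entry in enumerate(doc["actions"]):
        try:
            specs = [DescriptorSpec(k, True) for k in entry.get("essential", [])]
            specs += [DescriptorSpec(k, False) for k in entry.get("optional", [])]
            actions.append(
                ExperimentalAction(
                    id=entry["id"],
                    label=entry["label"],
                    definition=entry.get("definition", ""),
                    synonyms=list(entry.get("synonyms") or []),
                    descriptors=specs,
                    external_mapping=entry.get("external_mapping"),
                    provenance=entry.get("provenance", "legacy"),
                )
            )
        except (KeyError, TypeError) as exc:
            raise CatalogFormatError(f"{src}: action entry {i}: {exc}") from exc
    imported = [
        ImportedTerm(
            source_ontology=t.get("source_ontology", ""),
            term_uri=t.get("term_uri", ""),
            target_superclass=t.get("target_superclass", ""),
            label=t.get("label"),
        )
        for t in doc.get("imported_terms", [])
    ]
    catalog = ActionCatalog(actions=actions, imported_terms=imported,
                            version=str(doc.get("version", "0")))
    _validate(catalog)
    return catalog


def match_action_verb(verb_lemma: str, catalog: ActionCatalog) -> ExperimentalAction | None:
    """Return the unique action whose label or synonyms contain the lemma."""
    return catalog._by_lemma.get(verb_lemma)


def descriptor_requirements(action: ExperimentalAction) -> tuple[list[str], list[str]]:
    """Partition an action's descriptor kinds into (essential, optional)."""
    return action.essential_kinds, action.optional_kinds


def catalog_stats(catalog: ActionCatalog) -> dict[str, int]:
    """Action counts per provenance tag, plus the total."""
    stats = {p: 0 for p in PROVENANCES}
    for a in catalog.actions:
        stats[a.provenance] += 1
    stats["total"] = len(catalog.actions)
    return stats


def export_obo(catalog: ActionCatalog) -> str:
    """OBO-like flat-text export (id/name/synonym/xref stanzas)."""
    lines = [f"format-version: 1.2", f"data-version: {catalog.version}", ""]
    for a in catalog.actions:
        lines.append("[Term]")
        lines.append(f"id: {a.id.replace('_', ':', 1)}")
        lines.append(f"name: {a.label}")
        if a.definition:
            lines.append(f'def: "{a.definition}"')
        for s in a.synonyms:
            lines.append(f'synonym: "{s}" EXACT []')
        if a.external_mapping:
            lines.append(f"xref: {a.external_mapping}")
        lines.append(f"property_value: provenance {a.provenance}")
        lines.append("")
    return "\n".join(lines)
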