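"""Laboratory-specific knowledge: equipment, entities, abbreviations, defaults.

Protocol text is written against a lab's local vocabulary: abbreviations
("TCA", "ON"), equipment names, biochemical entities known by catalogue
IDs, and conventional default settings (overnight = 16 hours, room
temperature = 22 °C).  This module loads that knowledge from a YAML file
and exposes the lookups the translation pipeline needs.

Abbreviation matching is case-sensitive and whole-token: "ON" must fire in
"Store ON at RT." but never inside "CONICAL".  The word "overnight" and the
abbreviation "ON" normalize to one default key because the abbreviation
table maps ON -> overnight and the defaults table is keyed by the expansion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .units import Quantity, UnitTable, load_unit_table

__all__ = [
    "EntityRecord",
    "DefaultSetting",
    "Substitution",
    "LabConfig",
    "LabConfigError",
    "load_lab_config",
    "expand_abbreviations",
    "resolve_entity",
    "resolve_default",
]


class LabConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EntityRecord:
    """A named thing (biochemical entity or equipment) with an external ID."""

    name: str
    aliases: tuple[str, ...] = ()
    id_source: str | None = None  # e.g. "NCBI Pubchem", "ChEBI", "lab-internal"
    id_value: str | None = None


@dataclass(frozen=True)
class DefaultSetting:
    """A conventional value for an ambiguous token, e.g. overnight = 16 h."""

    quantity: Quantity
    kind: str  # descriptor kind implied by the unit (period, temperature, ...)


@dataclass(frozen=True)
class Substitution:
    """One abbreviation expansion applied to a text.

    ``span`` is the half-open range of the *expansion* in the expanded text;
    replacing it with ``abbreviation`` reconstructs the original.
    """

    span: tuple[int, int]
    abbreviation: str
    expansion: str


@dataclass
class LabConfig:
    equipment: list[EntityRecord] = field(default_factory=list)
    entities: list[EntityRecord] = field(default_factory=list)
    abbreviations: dict[str, str] = field(default_factory=dict)
    defaults: dict[str, DefaultSetting] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._entity_index = _build_index(self.entities)
        self._equipment_index = _build_index(self.equipment)


def _build_index(records: list[EntityRecord]) -> dict[str, EntityRecord]:
    index: dict[str, EntityRecord] = {}
    for r in records:
        for name in (r.name, *r.aliases):
            index.setdefault(name.lower(), r)
    return index


def _parse_records(section: list | None, src: str, what: str) -> list[EntityRecord]:
    records = []
    names: set[str] = set()
    for entry in section or []:
        if isinstance(entry, str):
            entry = {"name": entry}
        name = entry.get("name")
        if not name:
            raise LabConfigError(f"{src}: {what} entry without a name: {entry!r}")
        if name in names:
            raise LabConfigError(f"{src}: duplicate {what} name {name!r}")
        names.add(name)
        id_source, id_value = entry.get("id_source"), entry.get("id_value")
        if id_source and not id_value:
            raise LabConfigError(f"{src}: {what} {name!r}: id_source given without id_value")
        records.append(
            EntityRecord(
                name=name,
                aliases=tuple(entry.get("aliases") or ()),
                id_source=id_source,
                id_value=str(id_value) if id_value is not None else None,
            )
        )
    return records


def load_lab_config(path: str | None = None, units: UnitTable | None = None) -> LabConfig:
    """Load a lab config (YAML); bundled example config if ``path`` is None.

    Missing sections default to empty.  Default settings must carry a
    numeric value and a unit known to the unit table.
    """
    units = units or load_unit_table()
    if path is None:
        text = resources.files("protoact").joinpath("data/labconfig.yaml").read_text("utf-8")
        src = "<bundled>"
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        src = str(path)
    try:
        doc = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise LabConfigError(f"{src}: not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise LabConfigError(f"{src}: expected a mapping of sections")

    abbreviations: dict[str, str] = {}
    for key, expansion in (doc.get("abbreviations") or {}).items():
        if key in abbreviations:
            raise LabConfigError(f"{src}: duplicate abbreviation {key!r}")
        abbreviations[str(key)] = str(expansion)

    defaults: dict[str, DefaultSetting] = {}
    for token, spec in (doc.get("defaults") or {}).items():
        if not isinstance(spec, dict) or "value" not in spec or "unit" not in spec:
            raise LabConfigError(f"{src}: default {token!r} must map to {{value, unit}}")
        try:
            value = float(spec["value"])
        except (TypeError, ValueError) as exc:
            raise LabConfigError(f"{src}: default {token!r}: non-numeric value {spec['value']!r}") from exc
        unit = str(spec["unit"])
        info = units.resolve(unit)
        if info is None:
            raise LabConfigError(f"{src}: default {token!r}: unknown unit {unit!r}")
        kind = spec.get("kind") or info.kind
        if kind is None:
            raise LabConfigError(f"{src}: default {token!r}: unit {unit!r} implies no descriptor kind")
        defaults[str(token).lower()] = DefaultSetting(Quantity(value, unit), kind)

    return LabConfig(
        equipment=_parse_records(doc.get("equipment"), src, "equipment"),
        entities=_parse_records(doc.get("entities"), src, "entity"),
        abbreviations=abbreviations,
        defaults=defaults,
    )


def expand_abbreviations(text: str, config: LabConfig) -> tuple[str, list[Substitution]]:
    """Replace whole-token, case-sensitive abbreviation occurrences.

    Returns the expanded text and a substitution log whose spans index the
    expanded text, so the original can be reconstructed exactly.
    """
    if not config.abbreviations:
        return text, []
    keys = sorted(config.abbreviations, key=len, reverse=True)
    pattern = re.compile(
        r"(?<![\w])(" + "|".join(re.escape(k) for k in keys) + r")(?![\w])"
    )
    out: list[str] = []
    subs: list[Substitution] = []
    pos = 0
    out_len = 0
    for m in pattern.finditer(text):
        out.append(text[pos:m.start()])
        out_len += m.start() - pos
        expansion = config.abbreviations[m.group(1)]
        subs.append(Substitution((out_len, out_len + len(expansion)), m.group(1), expansion))
        out.append(expansion)
        out_len += len(expansion)
        pos = m.end()
    out.append(text[pos:])
    return "".join(out), subs


def revert_abbreviations(expanded: str, substitutions: list[Substitution]) -> str:
    """Inverse of :func:`expand_abbreviations` (used to check the log)."""
    pieces: list[str] = []
    pos = 0
    for s in substitutions:
        pieces.append(expanded[pos:s.span[0]])
        pieces.append(s.abbreviation)
        pos = s.span[1]
    pieces.append(expanded[pos:])
    return "".join(pieces)


def resolve_entity(surface: str, config: LabConfig) -> EntityRecord | None:
    """Case-insensitive lookup against entity names and aliases."""
    return config._entity_index.get(surface.strip().lower())


def resolve_equipment(surface: str, config: LabConfig) -> EntityRecord | None:
    """Case-insensitive lookup against equipment names and aliases."""
    return config._equipment_index.get(surface.strip().lower())


def resolve_default(token: str, config: LabConfig) -> Quantity | None:
    """Resolve a default token ("overnight", "RT") to its conventional value.

    The token is first pushed through the abbreviation table so that the
    abbreviation and its expansion share one defaults key.
    """
    token = token.strip()
    token = config.abbreviations.get(token, token)
    setting = config.defaults.get(token.lower())
    return setting.quantity if setting else None
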