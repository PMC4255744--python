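"""Measurement units and the semantic-clue table.

A small curated unit table maps surface unit symbols (and their common
aliases) to a canonical symbol, a Units Ontology accession where one
exists, and the descriptor kind the unit signals when it appears next to
a number in protocol text ("°C" signals a temperature, "rpm" a speed,
and so on).  The table lives in ``data/units.yaml`` so it can be extended
without touching code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = ["Quantity", "UnitInfo", "UnitTable", "load_unit_table"]


@dataclass(frozen=True)
class Quantity:
    """A magnitude with a unit symbol, e.g. ``Quantity(30, "°C")``."""

    magnitude: float
    unit: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        mag = int(self.magnitude) if self.magnitude == int(self.magnitude) else self.magnitude
        return f"{mag} {self.unit}"


@dataclass(frozen=True)
class UnitInfo:
    symbol: str
    kind: str | None  # descriptor kind hinted by this unit, or None
    uo_id: str | None  # Units Ontology accession, e.g. "UO:0000027"
    aliases: tuple[str, ...] = ()


@dataclass
class UnitTable:
    units: list[UnitInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_surface: dict[str, UnitInfo] = {}
        for u in self.units:
            self._by_surface[u.symbol] = u
            for a in u.aliases:
                self._by_surface[a] = u

    def resolve(self, surface: str) -> UnitInfo | None:
        """Look up a surface unit string (symbol or alias)."""
        return self._by_surface.get(surface)

    def surfaces_longest_first(self) -> list[str]:
        return sorted(self._by_surface, key=len, reverse=True)

    def quantity_pattern(self) -> re.Pattern[str]:
        """Compiled regex matching a number followed by a known unit.

        Alternatives are ordered longest-first so compound units
        (``μg/mL``) win over their prefixes (``μg``).
        """
        alt = "|".join(re.escape(s) for s in self.surfaces_longest_first())
        return re.compile(
            rf"(?<![\w.])(-?\d+(?:\.\d+)?)[ \t]*({alt})(?![A-Za-z0-9°μ/%])"
        )


def load_unit_table(path: str | None = None) -> UnitTable:
    """Load the unit table from ``path`` or the bundled default."""
    if path is None:
        text = resources.files("protoact").joinpath("data/units.yaml").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text) or {}
    units = [
        UnitInfo(
            symbol=entry["symbol"],
            kind=entry.get("kind"),
            uo_id=entry.get("uo"),
            aliases=tuple(entry.get("aliases") or ()),
        )
        for entry in doc.get("units", [])
    ]
    return UnitTable(units)
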