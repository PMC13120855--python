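"""Catalog of scored social actions and their behavioral categories.

The default catalog covers the action set scored across the comparative
screen: three threat-type and four contact-type aggressive actions, three
wing-borne and two locomotor courtship actions, the two female sexual
responses (ovipositor extrusion for rejection, wing spreading for
acceptance), and copulation as the terminal action that ends a trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CATEGORIES = frozenset(
    {
        "aggression-threat",
        "aggression-contact",
        "courtship-wing",
        "courtship-locomotor",
        "female-response",
        "terminal",
    }
)

#: Categories whose actions count as male courtship for dominance scaling,
#: preference indices and photostimulation gain.
COURTSHIP_CATEGORIES = frozenset({"courtship-wing", "courtship-locomotor"})

#: Categories whose actions count as aggression.
AGGRESSION_CATEGORIES = frozenset({"aggression-threat", "aggression-contact"})

_DEFAULT_ENTRIES = [
    ("threat", "aggression-threat"),
    ("pump", "aggression-threat"),
    ("charge", "aggression-threat"),
    ("lunge", "aggression-contact"),
    ("hold", "aggression-contact"),
    ("tussle", "aggression-contact"),
    ("headbutt", "aggression-contact"),
    ("barrage", "aggression-contact"),
    ("UWE", "courtship-wing"),
    ("BWE", "courtship-wing"),
    ("row", "courtship-wing"),
    ("circle", "courtship-locomotor"),
    ("copulation attempt", "courtship-locomotor"),
    ("ovipositor extrusion", "female-response"),
    ("wing spreading", "female-response"),
    ("copulation", "terminal"),
]


@dataclass(frozen=True)
class ActionCatalog:
    """Mapping of action labels to behavioral categories.

    Parameters
    ----------
    entries
        ``{name: category}`` with categories drawn from :data:`CATEGORIES`.
    """

    entries: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_ENTRIES)
    )

    def __post_init__(self) -> None:
        bad = {c for c in self.entries.values() if c not in CATEGORIES}
        if bad:
            raise ValueError(f"unknown action categories: {sorted(bad)}")

    def __contains__(self, action: str) -> bool:
        return action in self.entries

    def category(self, action: str) -> str:
        try:
            return self.entries[action]
        except KeyError:
            raise KeyError(f"unknown action label: {action!r}") from None

    def is_courtship(self, action: str) -> bool:
        return self.category(action) in COURTSHIP_CATEGORIES

    def is_aggression(self, action: str) -> bool:
        return self.category(action) in AGGRESSION_CATEGORIES

    @property
    def actions(self) -> list[str]:
        return list(self.entries)

    def extended(self, extra: dict[str, str]) -> "ActionCatalog":
        """Return a catalog with additional ``{name: category}`` entries."""
        merged = dict(self.entries)
        merged.update(extra)
        return ActionCatalog(merged)


DEFAULT_CATALOG = ActionCatalog()
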