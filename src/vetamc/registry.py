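"""Active-ingredient registry: class membership and importance categories.

The registry maps each declared chemical-compound name (including salt and
hydrate forms, e.g. ``"tetracycline hydrochloride"``) to a canonical active
ingredient, its antimicrobial class/subclass, WOAH veterinary-importance and
WHO human-health-importance categories, and — for potency-labelled products —
the IU-to-milligram conversion factor.

Name resolution is case-insensitive and goes through an explicit synonym
table: the bundled default registry was compiled from the ingredients
reported in Fiji's 2017-2021 veterinary import records.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "WoahCategory",
    "WhoCategory",
    "IngredientEntry",
    "IngredientRegistry",
    "RegistryError",
    "ResolutionError",
    "load_registry",
    "default_registry",
    "normalise_name",
]


class RegistryError(ValueError):
    """The registry file violates an invariant (duplicate name, missing factor)."""


class ResolutionError(KeyError):
    """An ingredient name cannot be resolved against the registry."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class WoahCategory(str, enum.Enum):
    """WOAH (OIE) veterinary importance: critically/highly/important."""

    VCIA = "VCIA"
    VHIA = "VHIA"
    VIA = "VIA"
    UNCLASSIFIED = "UNCLASSIFIED"


class WhoCategory(str, enum.Enum):
    """WHO human-health importance (CIA list)."""

    CIA_HIGHEST = "CIA_HIGHEST"
    CIA_HIGH = "CIA_HIGH"
    HIGHLY_IMPORTANT = "HIGHLY_IMPORTANT"
    IMPORTANT = "IMPORTANT"
    UNCLASSIFIED = "UNCLASSIFIED"


def normalise_name(name: str) -> str:
    """Lowercase and collapse whitespace; the synonym table does the rest."""
    return " ".join(name.strip().lower().split())


@dataclass(frozen=True)
class IngredientEntry:
    name: str
    class_: str
    subclass: str = ""
    woah: WoahCategory = WoahCategory.UNCLASSIFIED
    who: WhoCategory = WhoCategory.UNCLASSIFIED
    iu_to_mg: float | None = None
    synonyms: tuple[str, ...] = ()


@dataclass
class IngredientRegistry:
    """Lookup from declared ingredient names to class and importance data.

    ``entries`` is keyed by canonical name; ``_index`` additionally maps every
    normalised synonym to its canonical name.
    """

    entries: dict[str, IngredientEntry]
    list_edition: dict[str, str] = field(default_factory=dict)
    _index: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        index: dict[str, str] = {}
        for canonical, entry in self.entries.items():
            for alias in (canonical, *entry.synonyms):
                key = normalise_name(alias)
                if key in index and index[key] != canonical:
                    raise RegistryError(
                        f"duplicate ingredient name {alias!r}: maps to both "
                        f"{index[key]!r} and {canonical!r}"
                    )
                index[key] = canonical
        self._index = index

    def resolve(self, name: str) -> IngredientEntry:
        """Return the entry for a declared name; raise if unknown."""
        key = normalise_name(name)
        try:
            return self.entries[self._index[key]]
        except KeyError:
            raise ResolutionError(
                f"ingredient {name!r} is not in the registry; add it (or a "
                f"synonym) before quantifying"
            ) from None

    def __contains__(self, name: str) -> bool:
        return normalise_name(name) in self._index

    def iu_factor(self, name: str) -> float:
        """mg-per-IU factor for a potency-labelled ingredient."""
        entry = self.resolve(name)
        if entry.iu_to_mg is None:
            raise ResolutionError(
                f"no IU-to-mg conversion factor registered for {entry.name!r}"
            )
        return entry.iu_to_mg

    def class_categories(self) -> dict[tuple[str, str], WoahCategory]:
        """WOAH category per (class, subclass), checked for consistency."""
        out: dict[tuple[str, str], WoahCategory] = {}
        for entry in self.entries.values():
            key = (entry.class_, entry.subclass)
            if key in out and out[key] != entry.woah:
                raise RegistryError(
                    f"inconsistent WOAH category within class {key}: "
                    f"{out[key].value} vs {entry.woah.value}"
                )
            out[key] = entry.woah
        return out

    def class_who_categories(self) -> dict[tuple[str, str], WhoCategory]:
        """WHO category per (class, subclass), checked for consistency."""
        out: dict[tuple[str, str], WhoCategory] = {}
        for entry in self.entries.values():
            key = (entry.class_, entry.subclass)
            if key in out and out[key] != entry.who:
                raise RegistryError(
                    f"inconsistent WHO category within class {key}: "
                    f"{out[key].value} vs {entry.who.value}"
                )
            out[key] = entry.who
        return out


def _parse(doc: dict) -> IngredientRegistry:
    entries: dict[str, IngredientEntry] = {}
    for raw in doc.get("ingredients", []):
        name = normalise_name(raw["name"])
        if name in entries:
            raise RegistryError(f"duplicate ingredient name {raw['name']!r}")
        iu = raw.get("iu_to_mg")
        if iu is not None and iu < 0:
            raise RegistryError(f"negative iu_to_mg for {name!r}")
        entries[name] = IngredientEntry(
            name=name,
            class_=normalise_name(raw["class"]),
            subclass=normalise_name(raw.get("subclass", "") or ""),
            woah=WoahCategory(raw.get("woah", "UNCLASSIFIED")),
            who=WhoCategory(raw.get("who", "UNCLASSIFIED")),
            iu_to_mg=None if iu is None else float(iu),
            synonyms=tuple(raw.get("synonyms") or ()),
        )
    return IngredientRegistry(
        entries=entries, list_edition=dict(doc.get("list_edition", {}))
    )


def load_registry(path: str | Path) -> IngredientRegistry:
    """Load an ingredient registry from a YAML file."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "ingredients" not in doc:
        raise RegistryError(f"{path}: not a registry file (no 'ingredients' key)")
    return _parse(doc)


def default_registry() -> IngredientRegistry:
    """The bundled registry covering the study's 13 reported ingredients."""
    text = resources.files("vetamc.data").joinpath("registry.yaml").read_text("utf-8")
    return _parse(yaml.safe_load(text))
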