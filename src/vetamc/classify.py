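"""WOAH veterinary-importance and WHO human-health-importance summaries.

Class-level totals (kg of active ingredient) are partitioned into the WOAH
categories — veterinary critically important (VCIA), veterinary highly
important (VHIA), veterinary important (VIA) — with classes absent from the
WOAH list (e.g. nitroimidazoles) reported separately and excluded from the
classified grand total.  Percentages within a category use that category's
total; the headline VCIA share uses the classified total (VCIA+VHIA+VIA).
WHO flags annotate each class with its human-medicine priority
(e.g. fluoroquinolones and macrolides: critically important, highest
priority; penicillins and aminoglycosides: critically important, high
priority; tetracyclines carry no critical-importance flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .quantify import AnnualClassTotals, ClassKey
from .registry import IngredientRegistry, ResolutionError, WhoCategory, WoahCategory

__all__ = ["ImportanceSummary", "classify", "who_flags"]

_WOAH_ORDER = (WoahCategory.VCIA, WoahCategory.VHIA, WoahCategory.VIA)

WHO_FOOTNOTES = {
    WhoCategory.CIA_HIGHEST: "Critically important, highest priority antimicrobial agent in human health",
    WhoCategory.CIA_HIGH: "Critically important, high priority antimicrobial agent in human health",
}


@dataclass
class ImportanceSummary:
    """kg totals partitioned by WOAH category, plus unclassified classes.

    ``categories`` maps each WOAH category to {(class, subclass): kg};
    ``unclassified`` holds classes outside the WOAH list.  ``who`` is filled
    by :func:`who_flags`.
    """

    categories: dict[WoahCategory, dict[ClassKey, float]] = field(default_factory=dict)
    unclassified: dict[ClassKey, float] = field(default_factory=dict)
    who: dict[ClassKey, WhoCategory] = field(default_factory=dict)

    def category_total(self, category: WoahCategory) -> float:
        return math.fsum(self.categories.get(category, {}).values())

    def classified_total(self) -> float:
        """Total kg over VCIA+VHIA+VIA, excluding unclassified classes."""
        return math.fsum(self.category_total(c) for c in _WOAH_ORDER)

    def category_share(self, category: WoahCategory) -> float:
        """Percent of the classified total held by one WOAH category."""
        total = self.classified_total()
        if total == 0:
            return 0.0
        return 100.0 * self.category_total(category) / total

    def within_category_share(self, category: WoahCategory, key: ClassKey) -> float:
        """Percent of a category's kg held by one class."""
        total = self.category_total(category)
        if total == 0:
            return 0.0
        return 100.0 * self.categories.get(category, {}).get(key, 0.0) / total

    def to_frame(self) -> pd.DataFrame:
        """Long table: class, subclass, WOAH category, kg, percents, WHO flag."""
        rows = []
        for category in _WOAH_ORDER:
            for key, kg in sorted(self.categories.get(category, {}).items()):
                class_, subclass = key
                rows.append({
                    "class": class_,
                    "subclass": subclass,
                    "woah_category": category.value,
                    "kg": kg,
                    "percent_of_category": self.within_category_share(category, key),
                    "who_category": self.who.get(key, WhoCategory.UNCLASSIFIED).value,
                })
        for key, kg in sorted(self.unclassified.items()):
            class_, subclass = key
            rows.append({
                "class": class_,
                "subclass": subclass,
                "woah_category": WoahCategory.UNCLASSIFIED.value,
                "kg": kg,
                "percent_of_category": float("nan"),
                "who_category": self.who.get(key, WhoCategory.UNCLASSIFIED).value,
            })
        return pd.DataFrame(
            rows,
            columns=["class", "subclass", "woah_category", "kg",
                     "percent_of_category", "who_category"],
        )


def _as_class_totals(
    totals: AnnualClassTotals | dict[ClassKey, float]
) -> dict[ClassKey, float]:
    if isinstance(totals, AnnualClassTotals):
        return totals.class_totals()
    return dict(totals)


def classify(
    totals: AnnualClassTotals | dict[ClassKey, float],
    registry: IngredientRegistry,
) -> ImportanceSummary:
    """Partition class totals into WOAH importance categories.

    Every classified kilogram lands in exactly one category; classes the
    registry does not cover raise a :class:`ResolutionError` rather than
    being silently dropped.
    """
    class_totals = _as_class_totals(totals)
    category_by_class = registry.class_categories()
    summary = ImportanceSummary(categories={c: {} for c in _WOAH_ORDER})
    for key, kg in class_totals.items():
        try:
            category = category_by_class[key]
        except KeyError:
            raise ResolutionError(
                f"class {key} not covered by the registry's importance lists"
            ) from None
        if category is WoahCategory.UNCLASSIFIED:
            summary.unclassified[key] = kg
        else:
            summary.categories[category][key] = kg
    return summary


def who_flags(
    summary: ImportanceSummary, registry: IngredientRegistry
) -> ImportanceSummary:
    """Annotate a summary with WHO human-health-importance categories."""
    who_by_class = registry.class_who_categories()
    keys = set(summary.unclassified)
    for bucket in summary.categories.values():
        keys.update(bucket)
    for key in keys:
        summary.who[key] = who_by_class.get(key, WhoCategory.UNCLASSIFIED)
    return summary
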