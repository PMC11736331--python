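"""Convert import records to mass of active ingredient and aggregate.

Each finished-product shipment line is converted to grams of active
antimicrobial ingredient from its declared strength and geometry:

* liquid container:  g = strength (mg/ml) x container volume (ml) / 1000,
  then x number of packs;
* potency-labelled liquid (IU/ml): the strength is first converted to mg/ml
  with the ingredient's mg-per-IU factor, then treated as a liquid;
* tablet blister:  g = strength per tablet (mg) x blisters per pack
  x tablets per blister / 1000, then x number of packs.

All internal arithmetic is in exact double-precision grams with no
intermediate rounding; kilograms and percentages are derived at report time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .records import Formulation, ImportRecord
from .registry import IngredientRegistry

__all__ = [
    "QuantifiedImport",
    "AnnualClassTotals",
    "container_amount_g",
    "package_amount_g",
    "blister_amount_g",
    "iu_to_mg_per_ml",
    "quantify_record",
    "quantify_records",
    "aggregate",
]

ClassKey = tuple[str, str]  # (class, subclass); subclass may be ""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


def container_amount_g(strength_mg_per_ml: float, container_volume_ml: float) -> float:
    """Grams of active ingredient in one liquid container."""
    _require_positive(
        strength_mg_per_ml=strength_mg_per_ml, container_volume_ml=container_volume_ml
    )
    return strength_mg_per_ml * container_volume_ml / 1000.0


def package_amount_g(container_g: float, packs: int) -> float:
    """Grams in a consignment of ``packs`` identical containers."""
    if packs < 1:
        raise ValueError(f"packs must be >= 1, got {packs}")
    _require_positive(container_g=container_g)
    return container_g * packs


def blister_amount_g(
    strength_mg_per_tablet: float, blisters: int, tablets_per_blister: int
) -> float:
    """Grams of active ingredient in one blister pack."""
    _require_positive(
        strength_mg_per_tablet=strength_mg_per_tablet,
        blisters=blisters,
        tablets_per_blister=tablets_per_blister,
    )
    return strength_mg_per_tablet * blisters * tablets_per_blister / 1000.0


def iu_to_mg_per_ml(strength_iu_per_ml: float, iu_to_mg: float) -> float:
    """Convert a potency label (IU/ml) to a mass concentration (mg/ml)."""
    _require_positive(strength_iu_per_ml=strength_iu_per_ml, iu_to_mg=iu_to_mg)
    return strength_iu_per_ml * iu_to_mg


@dataclass(frozen=True)
class QuantifiedImport:
    """One import record resolved to grams of active ingredient."""

    record_id: str
    year: int
    ingredient_name: str
    class_: str
    subclass: str
    grams_active: float


def quantify_record(
    record: ImportRecord, registry: IngredientRegistry
) -> QuantifiedImport:
    """Deterministically convert one record to grams of active ingredient.

    Dispatches on the formulation; unresolvable ingredients raise a
    :class:`~vetamc.registry.ResolutionError` naming the ingredient rather
    than being silently dropped.
    """
    entry = registry.resolve(record.ingredient_name)
    f = record.formulation
    if f is Formulation.LIQUID:
        grams = package_amount_g(
            container_amount_g(record.strength, record.container_volume_ml),
            record.packs,
        )
    elif f is Formulation.IU_LIQUID:
        mg_per_ml = iu_to_mg_per_ml(
            record.strength, registry.iu_factor(record.ingredient_name)
        )
        grams = package_amount_g(
            container_amount_g(mg_per_ml, record.container_volume_ml), record.packs
        )
    elif f is Formulation.BLISTER:
        grams = blister_amount_g(
            record.strength, record.blisters_per_pack, record.tablets_per_blister
        ) * record.packs
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown formulation {record.formulation!r}")
    return QuantifiedImport(
        record_id=record.record_id,
        year=record.year,
        ingredient_name=entry.name,
        class_=entry.class_,
        subclass=entry.subclass,
        grams_active=grams,
    )


def quantify_records(
    records: list[ImportRecord], registry: IngredientRegistry
) -> list[QuantifiedImport]:
    """Quantify every food-animal record; non-food-animal records are excluded."""
    return [
        quantify_record(r, registry) for r in records if r.food_animal_indication
    ]


@dataclass
class AnnualClassTotals:
    """Year x antimicrobial-class totals in kilograms of active ingredient.

    ``cells`` maps (year, (class, subclass)) to kilograms.  Derived views
    (per-year totals, per-class totals, grand total, percent-of-year) are
    computed from the unrounded cells.
    """

    cells: dict[tuple[int, ClassKey], float] = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        return sorted({year for year, _ in self.cells})

    @property
    def classes(self) -> list[ClassKey]:
        return sorted({key for _, key in self.cells})

    def year_totals(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for year in self.years:
            out[year] = math.fsum(
                kg for (y, _), kg in self.cells.items() if y == year
            )
        return out

    def class_totals(self) -> dict[ClassKey, float]:
        out: dict[ClassKey, float] = {}
        for key in self.classes:
            out[key] = math.fsum(
                kg for (_, k), kg in self.cells.items() if k == key
            )
        return out

    def grand_total(self) -> float:
        return math.fsum(self.cells.values())

    def percent_of_year(self, year: int, key: ClassKey) -> float:
        total = self.year_totals().get(year, 0.0)
        if total == 0:
            return 0.0
        return 100.0 * self.cells.get((year, key), 0.0) / total

    def class_shares(self) -> dict[ClassKey, float]:
        """Percent of the grand total per class (unrounded)."""
        grand = self.grand_total()
        if grand == 0:
            return {key: 0.0 for key in self.classes}
        return {key: 100.0 * kg / grand for key, kg in self.class_totals().items()}

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per class, one column per year, plus totals."""
        years = self.years
        rows = []
        for key in self.classes:
            class_, subclass = key
            row: dict[str, object] = {"class": class_, "subclass": subclass}
            for year in years:
                row[str(year)] = self.cells.get((year, key), 0.0)
            row["total"] = math.fsum(
                self.cells.get((year, key), 0.0) for year in years
            )
            rows.append(row)
        frame = pd.DataFrame(rows, columns=["class", "subclass", *map(str, years), "total"])
        return frame


def aggregate(quantified: list[QuantifiedImport]) -> AnnualClassTotals:
    """Sum record-level grams into year x class kilograms.

    Conservation holds exactly: the grand total equals the sum of record
    grams divided by 1000, with no internal rounding.  The result is
    independent of record order.
    """
    groups: dict[tuple[int, ClassKey], list[float]] = {}
    for q in quantified:
        groups.setdefault((q.year, (q.class_, q.subclass)), []).append(q.grams_active)
    cells = {
        key: math.fsum(grams) / 1000.0
        for key, grams in sorted(groups.items())
    }
    return AnnualClassTotals(cells=cells)
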