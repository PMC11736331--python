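"""Domain types and CSV I/O for import records and livestock denominator inputs.

An :class:`ImportRecord` is one shipment line of a finished veterinary
product: the declared active ingredient, the formulation geometry (liquid
container, tablet blister, or an IU-potency-labelled liquid such as
injectable penicillin G), and the number of packs imported.

CSV conventions are fixed — UTF-8, comma separator, ``.`` decimal — so that
a record file parses identically across locales.
"""

from __future__ import annotations

import csv
import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "Formulation",
    "ImportRecord",
    "RecordValidationError",
    "SchemaError",
    "read_import_records",
    "write_import_records",
    "SpeciesInputs",
    "Census",
    "SlaughterYear",
    "DenominatorInputs",
    "read_denominators",
    "write_denominators",
    "DEFAULT_CONVERSION_COEFFICIENTS",
    "SPECIES",
]

SCHEMA_VERSION = "1"

RECORD_COLUMNS = [
    "record_id",
    "year",
    "ingredient_name",
    "formulation",
    "strength",
    "container_volume_ml",
    "tablets_per_blister",
    "blisters_per_pack",
    "packs",
    "food_animal_indication",
]


class SchemaError(ValueError):
    """A required column is missing from an input CSV."""


class RecordValidationError(ValueError):
    """One or more rows violate the record invariants."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "invalid import records:\n  " + "\n  ".join(problems)
        )


class Formulation(str, enum.Enum):
    """How a finished product declares its active-ingredient content.

    LIQUID    — strength in mg/ml plus a container volume in ml.
    BLISTER   — strength in mg per tablet plus blister geometry.
    IU_LIQUID — strength in international units per ml (potency label);
                converted to mg/ml via the ingredient's IU factor.
    """

    LIQUID = "LIQUID"
    BLISTER = "BLISTER"
    IU_LIQUID = "IU_LIQUID"


@dataclass(frozen=True)
class ImportRecord:
    """One shipment line of a finished veterinary antimicrobial product."""

    record_id: str
    year: int
    ingredient_name: str
    formulation: Formulation
    strength: float  # mg/ml (LIQUID), mg/tablet (BLISTER), IU/ml (IU_LIQUID)
    packs: int
    container_volume_ml: float | None = None
    tablets_per_blister: int | None = None
    blisters_per_pack: int | None = None
    food_animal_indication: bool = True

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        problems = []
        if not (isinstance(self.strength, (int, float)) and math.isfinite(self.strength)
                and self.strength > 0):
            problems.append(f"strength must be a positive finite number, got {self.strength!r}")
        if self.packs < 1:
            problems.append(f"packs must be >= 1, got {self.packs}")
        liquidlike = self.formulation in (Formulation.LIQUID, Formulation.IU_LIQUID)
        if liquidlike:
            if self.container_volume_ml is None or self.container_volume_ml <= 0:
                problems.append(
                    f"{self.formulation.value} requires positive container_volume_ml, "
                    f"got {self.container_volume_ml!r}"
                )
            if self.tablets_per_blister is not None or self.blisters_per_pack is not None:
                problems.append(
                    f"{self.formulation.value} must not set blister geometry"
                )
        else:  # BLISTER
            if self.tablets_per_blister is None or self.tablets_per_blister < 1:
                problems.append(
                    f"BLISTER requires tablets_per_blister >= 1, got "
                    f"{self.tablets_per_blister!r}"
                )
            if self.blisters_per_pack is None or self.blisters_per_pack < 1:
                problems.append(
                    f"BLISTER requires blisters_per_pack >= 1, got "
                    f"{self.blisters_per_pack!r}"
                )
            if self.container_volume_ml is not None:
                problems.append("BLISTER must not set container_volume_ml")
        return problems


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {text!r}")


def read_import_records(
    path: str | Path, schema_version: str = SCHEMA_VERSION
) -> list[ImportRecord]:
    """Read and validate import records from a CSV file.

    Unknown columns are ignored with a logged warning; missing required
    columns raise :class:`SchemaError`; rows violating invariants raise
    :class:`RecordValidationError` listing every offending row.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected a header row")
        missing = [c for c in RECORD_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        unknown = [c for c in reader.fieldnames if c not in RECORD_COLUMNS]
        if unknown:
            logger.warning("%s: ignoring unknown column(s): %s", path, ", ".join(unknown))

        records, problems = [], []
        for lineno, row in enumerate(reader, start=2):
            rid = row["record_id"] or f"row{lineno}"
            try:
                rec = ImportRecord(
                    record_id=rid,
                    year=int(row["year"]),
                    ingredient_name=row["ingredient_name"],
                    formulation=Formulation(row["formulation"]),
                    strength=float(row["strength"]),
                    packs=int(row["packs"]),
                    container_volume_ml=(
                        float(row["container_volume_ml"])
                        if row["container_volume_ml"] else None
                    ),
                    tablets_per_blister=(
                        int(row["tablets_per_blister"])
                        if row["tablets_per_blister"] else None
                    ),
                    blisters_per_pack=(
                        int(row["blisters_per_pack"])
                        if row["blisters_per_pack"] else None
                    ),
                    food_animal_indication=_parse_bool(row["food_animal_indication"]),
                )
            except (ValueError, KeyError) as exc:
                problems.append(f"line {lineno} ({rid}): {exc}")
                continue
            row_problems = rec.validate()
            if row_problems:
                problems.extend(f"line {lineno} ({rid}): {p}" for p in row_problems)
            else:
                records.append(rec)
    if problems:
        raise RecordValidationError(problems)
    return records


def write_import_records(records: list[ImportRecord], path: str | Path) -> None:
    """Write records to CSV; inverse of :func:`read_import_records`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_COLUMNS)
        for r in records:
            writer.writerow([
                r.record_id,
                r.year,
                r.ingredient_name,
                r.formulation.value,
                repr(r.strength) if isinstance(r.strength, float) else r.strength,
                "" if r.container_volume_ml is None else repr(float(r.container_volume_ml)),
                "" if r.tablets_per_blister is None else r.tablets_per_blister,
                "" if r.blisters_per_pack is None else r.blisters_per_pack,
                r.packs,
                "true" if r.food_animal_indication else "false",
            ])


# --------------------------------------------------------------------------
# Livestock denominator inputs
# --------------------------------------------------------------------------

SPECIES = ("cattle", "sheep", "goat", "pig", "chicken")

# carcass-weight : live-weight ratios per species
DEFAULT_CONVERSION_COEFFICIENTS = {
    "cattle": 0.7,
    "sheep": 0.47,
    "goat": 0.47,
    "pig": 0.78,
    "chicken": 0.7,
}

# standard live weight used for small ruminants in population-based biomass
SMALL_RUMINANT_STANDARD_WEIGHT_KG = 37.5


@dataclass(frozen=True)
class Census:
    year1: int
    pop1: float
    year2: int
    pop2: float

    def __post_init__(self) -> None:
        if self.year1 == self.year2:
            raise ValueError("census years must be distinct")
        if self.pop1 <= 0 or self.pop2 <= 0:
            raise ValueError("census populations must be positive")


@dataclass(frozen=True)
class SlaughterYear:
    count: float
    total_weight_kg: float | None = None


@dataclass
class SpeciesInputs:
    """Denominator inputs for one species."""

    census: Census | None = None
    slaughter: dict[int, SlaughterYear] = field(default_factory=dict)
    conversion_coefficient: float = 0.7
    standard_weight_kg: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.conversion_coefficient <= 1):
            raise ValueError(
                f"conversion coefficient must be in (0, 1], got "
                f"{self.conversion_coefficient}"
            )


@dataclass
class DenominatorInputs:
    """Census, slaughter, and weight inputs for the five food-animal species."""

    species: dict[str, SpeciesInputs] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.species:
            if name not in SPECIES:
                raise ValueError(f"unknown species {name!r}; expected one of {SPECIES}")

    def for_species(self, name: str) -> SpeciesInputs:
        try:
            return self.species[name]
        except KeyError:
            raise ValueError(f"no denominator inputs for species {name!r}") from None


_DENOM_COLUMNS = ["species", "item", "year", "value"]


def write_denominators(inputs: DenominatorInputs, path: str | Path) -> None:
    """Serialise denominator inputs to a long-format CSV.

    Columns: species, item, year, value.  Items: census_population (two rows
    per species), slaughter_count, slaughter_weight_kg, and the year-less
    parameters conversion_coefficient and standard_weight_kg.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DENOM_COLUMNS)
        for name, sp in inputs.species.items():
            if sp.census is not None:
                writer.writerow([name, "census_population", sp.census.year1, repr(float(sp.census.pop1))])
                writer.writerow([name, "census_population", sp.census.year2, repr(float(sp.census.pop2))])
            for year in sorted(sp.slaughter):
                s = sp.slaughter[year]
                writer.writerow([name, "slaughter_count", year, repr(float(s.count))])
                if s.total_weight_kg is not None:
                    writer.writerow([name, "slaughter_weight_kg", year, repr(float(s.total_weight_kg))])
            writer.writerow([name, "conversion_coefficient", "", repr(float(sp.conversion_coefficient))])
            if sp.standard_weight_kg is not None:
                writer.writerow([name, "standard_weight_kg", "", repr(float(sp.standard_weight_kg))])


def read_denominators(path: str | Path) -> DenominatorInputs:
    """Read denominator inputs from the long-format CSV written by
    :func:`write_denominators`."""
    path = Path(path)
    census_rows: dict[str, list[tuple[int, float]]] = {}
    slaughter_counts: dict[str, dict[int, float]] = {}
    slaughter_weights: dict[str, dict[int, float]] = {}
    coefficients: dict[str, float] = {}
    standard_weights: dict[str, float] = {}

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected a header row")
        missing = [c for c in _DENOM_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        for row in reader:
            sp, item, value = row["species"], row["item"], float(row["value"])
            if item == "census_population":
                census_rows.setdefault(sp, []).append((int(row["year"]), value))
            elif item == "slaughter_count":
                slaughter_counts.setdefault(sp, {})[int(row["year"])] = value
            elif item == "slaughter_weight_kg":
                slaughter_weights.setdefault(sp, {})[int(row["year"])] = value
            elif item == "conversion_coefficient":
                coefficients[sp] = value
            elif item == "standard_weight_kg":
                standard_weights[sp] = value
            else:
                logger.warning("%s: ignoring unknown item %r", path, item)

    species: dict[str, SpeciesInputs] = {}
    names = set(census_rows) | set(slaughter_counts) | set(coefficients) | set(standard_weights)
    for name in names:
        census = None
        if name in census_rows:
            rows = sorted(census_rows[name])
            if len(rows) != 2:
                raise RecordValidationError(
                    [f"{name}: expected exactly 2 census_population rows, got {len(rows)}"]
                )
            census = Census(rows[0][0], rows[0][1], rows[1][0], rows[1][1])
        slaughter = {
            year: SlaughterYear(count, slaughter_weights.get(name, {}).get(year))
            for year, count in slaughter_counts.get(name, {}).items()
        }
        species[name] = SpeciesInputs(
            census=census,
            slaughter=slaughter,
            conversion_coefficient=coefficients.get(
                name, DEFAULT_CONVERSION_COEFFICIENTS.get(name, 0.7)
            ),
            standard_weight_kg=standard_weights.get(name),
        )
    return DenominatorInputs(species=species)
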