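"""Annual national food-animal biomass denominator in kilograms.

The standardisation denominator is the total live weight of the food-animal
population at risk.  Populations between and beyond the two agricultural
census years are interpolated geometrically with the compound annual growth
rate

    r = (P2 / P1)^(1/y) - 1

where P1 and P2 are the census populations and y the number of years between
them.  Live weight per head is derived from slaughter statistics: carcass
weight = total slaughter weight / number slaughtered, and live weight =
carcass weight / species conversion coefficient (0.7 cattle, 0.47 sheep,
0.47 goat, 0.78 pig, 0.7 chicken).

Species biomass conventions:

* cattle — interpolated population x live weight (a census-based exception,
  used when the slaughtered fraction per age group is unknown);
* sheep and goats — by default, interpolated population x a 37.5 kg standard
  live weight; a slaughter-based mode (number slaughtered x live weight) is
  available behind a switch;
* pigs and chicken — number slaughtered x live weight; chicken falls back to
  a configurable standard live weight (default 2.0 kg) when slaughter weight
  totals are unavailable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .records import (
    SMALL_RUMINANT_STANDARD_WEIGHT_KG,
    SPECIES,
    DenominatorInputs,
    SpeciesInputs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthRate",
    "BiomassTable",
    "growth_rate",
    "interpolate_population",
    "carcass_weight",
    "live_weight",
    "species_biomass",
    "national_biomass",
    "biomass_table",
    "DEFAULT_CHICKEN_STANDARD_WEIGHT_KG",
]

# fallback live weight per bird when slaughter weights are unavailable;
# not a census/slaughter statistic — a configurable assumption
DEFAULT_CHICKEN_STANDARD_WEIGHT_KG = 2.0


@dataclass(frozen=True)
class GrowthRate:
    """Compound annual population growth rate between two censuses."""

    species: str
    r: float
    P1: float
    P2: float
    y: int

    def __post_init__(self) -> None:
        # invariant: (1+r)^y scales P1 onto P2
        if not math.isclose(self.P1 * (1.0 + self.r) ** self.y, self.P2, rel_tol=1e-9):
            raise ValueError(
                f"inconsistent growth rate for {self.species}: "
                f"{self.P1} x (1+{self.r})^{self.y} != {self.P2}"
            )


def growth_rate(P1: float, P2: float, y: int, species: str = "") -> GrowthRate:
    """Annual growth rate r = (P2/P1)^(1/y) - 1 between census populations."""
    if P1 <= 0 or P2 <= 0:
        raise ValueError(f"census populations must be positive, got P1={P1}, P2={P2}")
    if y < 1:
        raise ValueError(f"years between censuses must be >= 1, got {y}")
    r = (P2 / P1) ** (1.0 / y) - 1.0
    return GrowthRate(species=species, r=r, P1=P1, P2=P2, y=y)


def interpolate_population(P_ref: float, r: GrowthRate | float, dt: int) -> float:
    """Population ``dt`` years after (or before, dt < 0) a reference census.

    Geometric interpolation at constant r; the result is a real number, not
    rounded — biomass is a continuous denominator.
    """
    if P_ref <= 0:
        raise ValueError(f"reference population must be positive, got {P_ref}")
    rate = r.r if isinstance(r, GrowthRate) else float(r)
    return P_ref * (1.0 + rate) ** dt


def carcass_weight(total_slaughter_weight_kg: float, n_slaughtered: float) -> float:
    """Mean carcass weight in kg/head from annual slaughter statistics."""
    if n_slaughtered < 1:
        raise ValueError(f"number slaughtered must be >= 1, got {n_slaughtered}")
    if total_slaughter_weight_kg < 0:
        raise ValueError("slaughter weight cannot be negative")
    if total_slaughter_weight_kg == 0:
        logger.warning("zero total slaughter weight with %s head slaughtered", n_slaughtered)
    return total_slaughter_weight_kg / n_slaughtered


def live_weight(carcass_kg: float, conversion_coefficient: float) -> float:
    """Live weight per head: carcass weight / carcass:live conversion ratio."""
    if not (0 < conversion_coefficient <= 1):
        raise ValueError(
            f"conversion coefficient must be in (0, 1], got {conversion_coefficient}"
        )
    if carcass_kg < 0:
        raise ValueError("carcass weight cannot be negative")
    return carcass_kg / conversion_coefficient


def _interpolated_population(sp: SpeciesInputs, species: str, year: int) -> float:
    if sp.census is None:
        raise ValueError(f"{species}: census populations required for year {year}")
    c = sp.census
    gr = growth_rate(c.pop1, c.pop2, abs(c.year2 - c.year1), species=species)
    # anchor at the later census and project backwards/forwards
    return interpolate_population(c.pop2, gr, year - c.year2)


def _live_weight_from_slaughter(
    sp: SpeciesInputs, species: str, year: int
) -> float:
    try:
        s = sp.slaughter[year]
    except KeyError:
        raise ValueError(
            f"{species}: slaughter data required for year {year} but missing"
        ) from None
    if s.total_weight_kg is None:
        if sp.standard_weight_kg is not None:
            return sp.standard_weight_kg
        if species == "chicken":
            return DEFAULT_CHICKEN_STANDARD_WEIGHT_KG
        raise ValueError(
            f"{species}: slaughter weight total missing for year {year} and no "
            f"standard weight configured"
        )
    return live_weight(
        carcass_weight(s.total_weight_kg, s.count), sp.conversion_coefficient
    )


def species_biomass(
    species: str,
    year: int,
    inputs: DenominatorInputs,
    small_ruminant_mode: str = "population",
) -> float:
    """Biomass in kg for one species in one year.

    ``small_ruminant_mode`` selects the sheep/goat convention:
    ``"population"`` (interpolated population x 37.5 kg standard weight,
    the default) or ``"slaughter"`` (number slaughtered x live weight).
    """
    if small_ruminant_mode not in ("population", "slaughter"):
        raise ValueError(f"unknown small-ruminant mode {small_ruminant_mode!r}")
    sp = inputs.for_species(species)

    if species == "cattle":
        population = _interpolated_population(sp, species, year)
        lw = _live_weight_from_slaughter(sp, species, year)
        return population * lw

    if species in ("sheep", "goat"):
        if small_ruminant_mode == "population":
            population = _interpolated_population(sp, species, year)
            standard = (
                sp.standard_weight_kg
                if sp.standard_weight_kg is not None
                else SMALL_RUMINANT_STANDARD_WEIGHT_KG
            )
            return population * standard
        s = sp.slaughter.get(year)
        if s is None:
            raise ValueError(
                f"{species}: slaughter data required for year {year} but missing"
            )
        return s.count * _live_weight_from_slaughter(sp, species, year)

    # pigs and chicken: slaughter-based
    s = sp.slaughter.get(year)
    if s is None:
        raise ValueError(
            f"{species}: slaughter data required for year {year} but missing"
        )
    return s.count * _live_weight_from_slaughter(sp, species, year)


def national_biomass(
    year: int,
    inputs: DenominatorInputs,
    small_ruminant_mode: str = "population",
) -> float:
    """National denominator: sum of species biomasses for the year, in kg."""
    return math.fsum(
        species_biomass(sp, year, inputs, small_ruminant_mode) for sp in SPECIES
    )


@dataclass
class BiomassTable:
    """Species x year biomass in kg, summable to the national denominator."""

    entries: dict[tuple[str, int], float] = field(default_factory=dict)

    def national_total(self, year: int) -> float:
        total = math.fsum(
            kg for (_, y), kg in self.entries.items() if y == year
        )
        if total <= 0:
            raise ValueError(f"no biomass entries for year {year}")
        return total

    @property
    def years(self) -> list[int]:
        return sorted({y for _, y in self.entries})

    def to_frame(self) -> pd.DataFrame:
        years = self.years
        rows = []
        for sp in SPECIES:
            row: dict[str, object] = {"species": sp}
            for y in years:
                row[str(y)] = self.entries.get((sp, y), 0.0)
            rows.append(row)
        rows.append(
            {"species": "national_total", **{str(y): self.national_total(y) for y in years}}
        )
        return pd.DataFrame(rows, columns=["species", *map(str, years)])


def biomass_table(
    years: list[int],
    inputs: DenominatorInputs,
    small_ruminant_mode: str = "population",
) -> BiomassTable:
    """Compute the full species x year biomass table for the study window."""
    entries = {
        (sp, year): species_biomass(sp, year, inputs, small_ruminant_mode)
        for sp in SPECIES
        for year in years
    }
    return BiomassTable(entries=entries)
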