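"""Synthetic import records and denominator tables with exact ground truth.

National veterinary import registries are rarely deposited publicly, so the
pipeline is validated on generated data whose true totals are known by
construction.  The generator emulates a tier-1 (point-of-entry) import
dataset: right-skewed per-shipment masses, a class mix dominated by
penicillins and tetracyclines, mixed formulations including potency-labelled
(IU) injectable penicillin, and an optional late-window import collapse such
as the 2020-2021 COVID-era drop.

Every record's geometry (strength, container volume or blister layout, pack
count) is back-solved from the drawn target mass on realistic grids, and the
ledger stores each record's mass recomputed from the same defining formulas
— so ledger-versus-pipeline equality is exact, not approximate.

Denominator tables are generated as two census points consistent with a
drawn compound annual growth rate plus slaughter statistics consistent with
drawn carcass weights; the ledger holds the implied national biomass.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .quantify import ClassKey
from .records import (
    Census,
    DenominatorInputs,
    Formulation,
    ImportRecord,
    SlaughterYear,
    SpeciesInputs,
)
from .registry import IngredientRegistry, default_registry

__all__ = ["GeneratorConfig", "Ledger", "generate_records", "generate_denominators"]

# default class mix: heavily skewed to penicillins and tetracyclines, as in
# the Fiji import profile
DEFAULT_CLASS_MIX = {
    "penicillins": 0.55,
    "tetracyclines": 0.18,
    "sulfonamides": 0.08,
    "macrolides": 0.05,
    "lincosamides": 0.05,
    "aminoglycosides": 0.04,
    "cephalosporins": 0.03,
    "quinolones": 0.01,
    "nitroimidazoles": 0.01,
}

DEFAULT_FORMULATION_MIX = {
    Formulation.LIQUID: 0.60,
    Formulation.BLISTER: 0.25,
    Formulation.IU_LIQUID: 0.15,
}

# declared compound names per class (salt/hydrate forms exercise the
# registry's synonym normalisation)
_CLASS_INGREDIENTS: dict[str, tuple[str, ...]] = {
    "penicillins": ("penicillin G procaine",),
    "tetracyclines": ("tetracycline hydrochloride",),
    "sulfonamides": ("sulfamethoxazole", "silver sulfadiazine"),
    "macrolides": ("erythromycin",),
    "lincosamides": ("lincomycin hydrochloride monohydrate",),
    "aminoglycosides": ("gentamycin sulphate",),
    "cephalosporins": ("cephalothin sodium", "cefuroxime sodium"),
    "quinolones": ("ciprofloxacin hydrochloride", "norfloxacin"),
    "nitroimidazoles": ("metronidazole",),
}

_PACK_GRID = (1, 4, 6, 10, 12, 20)  # typical pack counts, incl. single units
_LIQUID_STRENGTHS = (50, 100, 150, 200, 250, 500)  # mg/ml
_IU_STRENGTHS = (200_000, 300_000, 400_000)  # IU/ml
_TABLET_STRENGTHS = (50, 100, 250, 500)  # mg/tablet
_TABLETS_PER_BLISTER = (8, 10)
_MAX_VOLUME_ML = 5000
_MAX_BLISTERS = 500

# denominator scales, anchored on Fiji's 2020 agricultural census and
# slaughter statistics of plausible magnitude
_SPECIES_BASE = {
    # species: (2020-scale population, carcass kg/head, annual slaughter fraction)
    "cattle": (120_000, 200.0, 0.10),
    "sheep": (37_000, 17.6, 0.25),
    "goat": (144_000, 17.6, 0.25),
    "pig": (90_000, 60.0, 0.60),
    "chicken": (1_400_000, 1.4, 3.0),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic import dataset."""

    seed: int = 0
    years: tuple[int, ...] = (2017, 2018, 2019, 2020, 2021)
    n_records_per_year: int | dict[int, int] = 40
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    formulation_mix: dict[Formulation, float] = field(
        default_factory=lambda: dict(DEFAULT_FORMULATION_MIX)
    )
    # log-normal parameters of the per-shipment mass in grams
    shipment_log_mean: float = math.log(800.0)
    shipment_log_sd: float = 1.4
    # multiplier on shipment mass per year, e.g. a COVID-era collapse
    shock_years: dict[int, float] = field(
        default_factory=lambda: {2020: 0.15, 2021: 0.2}
    )
    census_years: tuple[int, int] = (2009, 2020)
    growth_rate_mean: float = 0.01
    growth_rate_sd: float = 0.015

    def __post_init__(self) -> None:
        for name, mix in (("class_mix", self.class_mix),
                          ("formulation_mix", self.formulation_mix)):
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{name} probabilities must be non-negative")
            if not math.isclose(sum(mix.values()), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} probabilities must sum to 1")

    def records_for_year(self, year: int) -> int:
        if isinstance(self.n_records_per_year, dict):
            return self.n_records_per_year.get(year, 0)
        return self.n_records_per_year


@dataclass
class Ledger:
    """Exact ground truth written by the generator."""

    year_class_grams: dict[tuple[int, ClassKey], float] = field(default_factory=dict)
    biomass_kg: dict[int, float] = field(default_factory=dict)

    def grand_total_grams(self) -> float:
        return math.fsum(self.year_class_grams.values())

    def to_json(self, path: str | Path) -> None:
        doc = {
            "year_class_grams": {
                f"{year}|{key[0]}|{key[1]}": grams
                for (year, key), grams in self.year_class_grams.items()
            },
            "biomass_kg": {str(y): v for y, v in self.biomass_kg.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "Ledger":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        ycg = {}
        for key, grams in doc.get("year_class_grams", {}).items():
            year, class_, subclass = key.split("|")
            ycg[(int(year), (class_, subclass))] = grams
        return cls(
            year_class_grams=ycg,
            biomass_kg={int(y): v for y, v in doc.get("biomass_kg", {}).items()},
        )


def _choose(rng: np.random.Generator, options, probs=None):
    idx = rng.choice(len(options), p=probs)
    return options[int(idx)]


def _backsolve_liquid(
    rng: np.random.Generator, target_g: float, mg_per_ml_of, strengths
) -> tuple[int, int, int, float]:
    """Pick (strength, volume, packs) whose exact mass approximates target_g.

    Returns (strength, volume_ml, packs, exact_grams) where exact_grams is
    computed with the same expression the quantification stage uses.
    """
    for attempt in range(20):
        strength = _choose(rng, strengths)
        packs = _choose(rng, _PACK_GRID)
        ideal = target_g * 1000.0 / (mg_per_ml_of(strength) * packs)
        volume = int(round(ideal))
        if 1 <= volume <= _MAX_VOLUME_ML:
            break
    else:
        volume = min(max(volume, 1), _MAX_VOLUME_ML)
    exact = mg_per_ml_of(strength) * volume / 1000.0 * packs
    return strength, volume, packs, exact


def generate_records(
    config: GeneratorConfig, registry: IngredientRegistry | None = None
) -> tuple[list[ImportRecord], Ledger]:
    """Draw a synthetic import-record dataset plus its exact ledger.

    Deterministic given the config seed: one documented RNG stream drives
    all draws.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(config.seed)
    classes = sorted(config.class_mix)
    class_probs = np.array([config.class_mix[c] for c in classes])
    formulations = sorted(config.formulation_mix, key=lambda f: f.value)
    form_probs = np.array([config.formulation_mix[f] for f in formulations])

    records: list[ImportRecord] = []
    per_cell_grams: dict[tuple[int, ClassKey], list[float]] = {}
    counter = 0
    for year in config.years:
        shock = config.shock_years.get(year, 1.0)
        for _ in range(config.records_for_year(year)):
            counter += 1
            class_ = _choose(rng, classes, class_probs)
            ingredient = _choose(rng, _CLASS_INGREDIENTS[class_])
            entry = registry.resolve(ingredient)
            formulation = _choose(rng, formulations, form_probs)
            if formulation is Formulation.IU_LIQUID and entry.iu_to_mg is None:
                formulation = Formulation.LIQUID  # potency labels: penicillin only
            target_g = float(
                rng.lognormal(config.shipment_log_mean, config.shipment_log_sd)
            ) * shock

            if formulation is Formulation.LIQUID:
                strength, volume, packs, exact = _backsolve_liquid(
                    rng, target_g, lambda s: float(s), _LIQUID_STRENGTHS
                )
                rec = ImportRecord(
                    record_id=f"SYN{counter:05d}",
                    year=year,
                    ingredient_name=ingredient,
                    formulation=Formulation.LIQUID,
                    strength=float(strength),
                    container_volume_ml=float(volume),
                    packs=packs,
                )
            elif formulation is Formulation.IU_LIQUID:
                factor = entry.iu_to_mg
                strength, volume, packs, exact = _backsolve_liquid(
                    rng, target_g, lambda s: s * factor, _IU_STRENGTHS
                )
                rec = ImportRecord(
                    record_id=f"SYN{counter:05d}",
                    year=year,
                    ingredient_name=ingredient,
                    formulation=Formulation.IU_LIQUID,
                    strength=float(strength),
                    container_volume_ml=float(volume),
                    packs=packs,
                )
            else:  # BLISTER
                for attempt in range(20):
                    strength = _choose(rng, _TABLET_STRENGTHS)
                    tablets = _choose(rng, _TABLETS_PER_BLISTER)
                    packs = _choose(rng, _PACK_GRID)
                    ideal = target_g * 1000.0 / (strength * tablets * packs)
                    blisters = int(round(ideal))
                    if 1 <= blisters <= _MAX_BLISTERS:
                        break
                else:
                    blisters = min(max(blisters, 1), _MAX_BLISTERS)
                exact = strength * blisters * tablets / 1000.0 * packs
                rec = ImportRecord(
                    record_id=f"SYN{counter:05d}",
                    year=year,
                    ingredient_name=ingredient,
                    formulation=Formulation.BLISTER,
                    strength=float(strength),
                    tablets_per_blister=tablets,
                    blisters_per_pack=blisters,
                    packs=packs,
                )
            records.append(rec)
            key = (year, (entry.class_, entry.subclass))
            per_cell_grams.setdefault(key, []).append(exact)

    ledger = Ledger(
        year_class_grams={
            key: math.fsum(grams) for key, grams in sorted(per_cell_grams.items())
        }
    )
    return records, ledger


def generate_denominators(
    config: GeneratorConfig,
) -> tuple[DenominatorInputs, Ledger]:
    """Draw census/slaughter denominator tables plus the implied biomass.

    Census pairs are constructed to be exactly consistent with a drawn
    compound annual growth rate; slaughter totals are count x drawn carcass
    weight.  The ledger's per-year national biomass is computed from the
    same defining formulas the biomass stage applies (population-based
    small ruminants with the 37.5 kg standard weight).
    """
    from .records import DEFAULT_CONVERSION_COEFFICIENTS, SMALL_RUMINANT_STANDARD_WEIGHT_KG

    rng = np.random.default_rng(config.seed + 1)
    y1, y2 = config.census_years
    span = abs(y2 - y1)
    species_inputs: dict[str, SpeciesInputs] = {}
    biomass_per_year: dict[int, list[float]] = {y: [] for y in config.years}

    for species, (base_pop, carcass_kg, slaughter_frac) in _SPECIES_BASE.items():
        pop2 = float(base_pop) * float(rng.lognormal(0.0, 0.1))
        r_drawn = float(rng.normal(config.growth_rate_mean, config.growth_rate_sd))
        pop1 = pop2 / (1.0 + r_drawn) ** span
        # recompute r the way the census defines it, so the ledger and the
        # pipeline share one arithmetic path
        r = (pop2 / pop1) ** (1.0 / span) - 1.0
        coef = DEFAULT_CONVERSION_COEFFICIENTS[species]
        carcass = carcass_kg * float(rng.lognormal(0.0, 0.05))

        slaughter: dict[int, SlaughterYear] = {}
        for year in config.years:
            population = pop2 * (1.0 + r) ** (year - y2)
            count = float(int(population * slaughter_frac))
            slaughter[year] = SlaughterYear(
                count=count, total_weight_kg=count * carcass
            )
            lw = (count * carcass / count) / coef  # carcass_weight -> live_weight
            if species == "cattle":
                biomass_per_year[year].append(population * lw)
            elif species in ("sheep", "goat"):
                biomass_per_year[year].append(
                    population * SMALL_RUMINANT_STANDARD_WEIGHT_KG
                )
            else:
                biomass_per_year[year].append(count * lw)

        species_inputs[species] = SpeciesInputs(
            census=Census(y1, pop1, y2, pop2),
            slaughter=slaughter,
            conversion_coefficient=coef,
        )

    ledger = Ledger(
        biomass_kg={y: math.fsum(parts) for y, parts in biomass_per_year.items()}
    )
    return DenominatorInputs(species=species_inputs), ledger
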