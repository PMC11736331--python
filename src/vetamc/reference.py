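"""Published reference tables for Fiji's 2017-2021 veterinary antimicrobial
imports.

The national study this pipeline operationalises did not deposit its
record-level import data, but its summary layer is public: annual kilograms
of active ingredient by antimicrobial class, and the same totals partitioned
by WOAH veterinary importance.  Those printed values are reproduced here so
the aggregation, classification, and trend stages can be checked end-to-end
against known national results.

Transcription notes (the printed tables are internally inconsistent at the
last decimal, a consequence of the source rounding each cell independently):

* The second-generation-cephalosporin class total is printed as 0 in the
  year-by-class table but 0.01 kg in both its 2019 cell and the importance
  table; 0.01 is carried here, which also makes the class-total column sum
  exactly to the printed 464.31 kg grand total.
* Summing the printed per-year cells reproduces the printed annual and class
  totals only to within 0.01-0.1 kg; the printed totals row/column is
  authoritative for downstream shares.
"""

from __future__ import annotations

from dataclasses import dataclass

from .quantify import AnnualClassTotals, ClassKey
from .registry import WoahCategory

__all__ = [
    "STUDY_YEARS",
    "ReferenceTables",
    "reference_tables",
    "reference_annual_totals",
    "reference_class_totals",
    "reference_year_class_table",
]

STUDY_YEARS = (2017, 2018, 2019, 2020, 2021)

# class keys: (class, subclass)
AMINOGLYCOSIDES: ClassKey = ("aminoglycosides", "")
CEPH_1G: ClassKey = ("cephalosporins", "first-generation cephalosporin")
CEPH_2G: ClassKey = ("cephalosporins", "second-generation cephalosporin")
FLUOROQUINOLONES: ClassKey = ("quinolones", "fluoroquinolone")
LINCOSAMIDES: ClassKey = ("lincosamides", "")
MACROLIDES: ClassKey = ("macrolides", "")
PENICILLINS: ClassKey = ("penicillins", "")
SULFONAMIDES: ClassKey = ("sulfonamides", "")
TETRACYCLINES: ClassKey = ("tetracyclines", "")
NITROIMIDAZOLES: ClassKey = ("nitroimidazoles", "")

# kg of active ingredient per (class, year), as printed
_YEAR_CELLS: dict[ClassKey, tuple[float, float, float, float, float]] = {
    AMINOGLYCOSIDES: (0.29, 0.0, 0.16, 0.14, 1.39),
    CEPH_1G: (0.83, 0.10, 0.43, 0.08, 0.60),
    CEPH_2G: (0.0, 0.0, 0.01, 0.0, 0.0),
    FLUOROQUINOLONES: (0.01, 0.01, 0.10, 0.0, 0.01),
    LINCOSAMIDES: (14.25, 0.0, 0.04, 0.03, 0.05),
    MACROLIDES: (0.02, 28.75, 0.01, 0.0, 0.0),
    PENICILLINS: (103.16, 101.84, 94.33, 13.63, 10.78),
    SULFONAMIDES: (1.85, 0.0, 1.35, 3.29, 12.57),
    TETRACYCLINES: (9.49, 3.48, 57.06, 2.06, 1.97),
    NITROIMIDAZOLES: (0.03, 0.0, 0.08, 0.0, 0.15),
}

# printed class totals (kg) over 2017-2021; see transcription notes
_CLASS_TOTALS: dict[ClassKey, float] = {
    AMINOGLYCOSIDES: 1.98,
    CEPH_1G: 1.94,
    CEPH_2G: 0.01,
    FLUOROQUINOLONES: 0.13,
    LINCOSAMIDES: 14.36,
    MACROLIDES: 28.78,
    PENICILLINS: 323.73,
    SULFONAMIDES: 19.06,
    TETRACYCLINES: 74.06,
    NITROIMIDAZOLES: 0.26,
}

# printed annual totals (kg), 2017-2021
_ANNUAL_TOTALS = (129.93, 134.08, 153.56, 19.22, 27.51)

# WOAH category per class as applied in the published importance table
_WOAH_ASSIGNMENT: dict[ClassKey, WoahCategory] = {
    AMINOGLYCOSIDES: WoahCategory.VCIA,
    CEPH_1G: WoahCategory.VHIA,
    CEPH_2G: WoahCategory.VHIA,
    FLUOROQUINOLONES: WoahCategory.VCIA,
    LINCOSAMIDES: WoahCategory.VHIA,
    MACROLIDES: WoahCategory.VCIA,
    PENICILLINS: WoahCategory.VCIA,
    SULFONAMIDES: WoahCategory.VCIA,
    TETRACYCLINES: WoahCategory.VCIA,
    NITROIMIDAZOLES: WoahCategory.UNCLASSIFIED,
}


@dataclass(frozen=True)
class ReferenceTables:
    """The published national summary layer, transcribed verbatim."""

    years: tuple[int, ...]
    year_class_kg: dict[tuple[int, ClassKey], float]
    class_totals_kg: dict[ClassKey, float]
    annual_totals_kg: dict[int, float]
    grand_total_kg: float
    woah_assignment: dict[ClassKey, WoahCategory]

    def annual_totals_series(self) -> list[float]:
        """The five annual totals in year order (the trend-test input)."""
        return [self.annual_totals_kg[y] for y in self.years]

    def as_annual_class_totals(self) -> AnnualClassTotals:
        """Per-year cells as an :class:`AnnualClassTotals` object."""
        return AnnualClassTotals(cells=dict(self.year_class_kg))


def reference_tables() -> ReferenceTables:
    """The published Fiji 2017-2021 summary tables."""
    cells = {
        (year, key): _YEAR_CELLS[key][i]
        for key in _YEAR_CELLS
        for i, year in enumerate(STUDY_YEARS)
    }
    return ReferenceTables(
        years=STUDY_YEARS,
        year_class_kg=cells,
        class_totals_kg=dict(_CLASS_TOTALS),
        annual_totals_kg=dict(zip(STUDY_YEARS, _ANNUAL_TOTALS)),
        grand_total_kg=464.31,
        woah_assignment=dict(_WOAH_ASSIGNMENT),
    )


def reference_annual_totals() -> list[float]:
    """Printed annual total imports (kg), 2017 through 2021."""
    return list(_ANNUAL_TOTALS)


def reference_class_totals() -> dict[ClassKey, float]:
    """Printed 2017-2021 class totals (kg)."""
    return dict(_CLASS_TOTALS)


def reference_year_class_table() -> AnnualClassTotals:
    """Printed per-year, per-class cells as an AnnualClassTotals."""
    return reference_tables().as_annual_class_totals()
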