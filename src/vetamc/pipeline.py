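"""End-to-end pipeline: records -> quantities -> denominators -> report bundle.

``run_pipeline`` ties the stages together and writes the report bundle:

* ``annual_class_totals.csv`` — year x class kilograms with percent-of-year
  cells (the national summary table layout);
* ``importance_summary.csv``  — WOAH/WHO importance partition;
* ``mg_per_kg.csv``           — biomass-standardised consumption per year;
* ``trend.json``              — Mann-Kendall result and the series tested;
* ``mg_per_kg.png``           — yearly standardised-consumption bar chart;
* ``run.log``                 — configuration, list editions, exclusions.

All report rounding is half-up at the configured number of digits (default
2); every CSV is written from unrounded internal values at the last step,
so two runs with identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from . import biomass as biomass_mod
from .classify import classify, who_flags
from .quantify import AnnualClassTotals, aggregate, quantify_records
from .records import read_denominators, read_import_records
from .registry import IngredientRegistry, default_registry, load_registry
from .trend import MkMethod, adjust_by_biomass, annual_mean_sd, mann_kendall

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "round_half_up"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the CLI."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def round_half_up(x: float, digits: int = 2) -> float:
    """Round half away from zero at ``digits`` decimals (report style)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    records: str | Path
    denominators: str | Path | None = None
    registry: str | Path | None = None  # None -> bundled default
    years: tuple[int, ...] | None = None  # None -> infer from records
    out_dir: str | Path = "vetamc-report"
    rounding_digits: int = 2
    mk_method: MkMethod | str | None = None  # None -> automatic
    biomass_mode: str = "population"  # small-ruminant basis

    def __post_init__(self) -> None:
        if self.rounding_digits < 0:
            raise ValueError("rounding_digits must be >= 0")
        if self.years is not None:
            self.years = tuple(sorted(self.years))
            if not self.years:
                raise ValueError("years must be non-empty when given")


def _stage(stage: str):
    """Decorator-free helper: wrap exceptions with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(stage, str(exc)) from exc
            return False

    return _Ctx()


def _write_totals_csv(
    totals: AnnualClassTotals, path: Path, digits: int
) -> None:
    years = totals.years
    year_totals = totals.year_totals()
    grand = totals.grand_total()
    lines = ["class,subclass," + ",".join(str(y) for y in years) + ",total"]
    class_totals = totals.class_totals()
    for key in totals.classes:
        cells = []
        for y in years:
            kg = totals.cells.get((y, key), 0.0)
            pct = totals.percent_of_year(y, key)
            cells.append(f"{round_half_up(kg, digits)} ({round_half_up(pct, digits)})")
        total_kg = class_totals[key]
        pct = 100.0 * total_kg / grand if grand else 0.0
        cells.append(f"{round_half_up(total_kg, digits)} ({round_half_up(pct, digits)})")
        lines.append(",".join([key[0], key[1], *cells]))
    total_cells = [
        f"{round_half_up(year_totals[y], digits)} "
        f"({round_half_up(100.0 * year_totals[y] / grand if grand else 0.0, digits)})"
        for y in years
    ]
    total_cells.append(f"{round_half_up(grand, digits)} (100)")
    lines.append(",".join(["total", "", *total_cells]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a dict of the in-memory results (totals, summary, adjusted
    consumption, trend) for library callers.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"config: {dataclasses.asdict(config)!r}"]

    with _stage("registry"):
        registry: IngredientRegistry = (
            load_registry(config.registry) if config.registry else default_registry()
        )
        log_lines.append(f"list editions: {registry.list_edition}")

    with _stage("records"):
        records = read_import_records(config.records)
        excluded = [r.record_id for r in records if not r.food_animal_indication]
        if excluded:
            log_lines.append(
                f"excluded {len(excluded)} record(s) without food-animal "
                f"indication: {', '.join(excluded)}"
            )
        if config.years is not None:
            outside = [r.record_id for r in records if r.year not in config.years]
            if outside:
                log_lines.append(
                    f"excluded {len(outside)} record(s) outside the study years: "
                    f"{', '.join(outside)}"
                )
                records = [r for r in records if r.year in config.years]

    with _stage("quantify"):
        quantified = quantify_records(records, registry)
        totals = aggregate(quantified)
        _write_totals_csv(
            totals, out / "annual_class_totals.csv", config.rounding_digits
        )

    with _stage("classify"):
        summary = who_flags(classify(totals, registry), registry)
        frame = summary.to_frame()
        frame["kg"] = frame["kg"].map(
            lambda v: round_half_up(v, config.rounding_digits)
        )
        frame["percent_of_category"] = frame["percent_of_category"].map(
            lambda v: round_half_up(v, config.rounding_digits) if v == v else ""
        )
        frame.to_csv(out / "importance_summary.csv", index=False)

    years = config.years or tuple(totals.years)
    adjusted = None
    if config.denominators:
        with _stage("biomass"):
            denominators = read_denominators(config.denominators)
            table = biomass_mod.biomass_table(
                list(years), denominators, config.biomass_mode
            )
            table.to_frame().to_csv(out / "biomass.csv", index=False)
        with _stage("adjust"):
            adjusted = adjust_by_biomass(totals, table)
            lines = ["year,total_kg,biomass_kg,mg_per_kg"]
            year_totals = totals.year_totals()
            for year in totals.years:
                lines.append(
                    f"{year},{year_totals[year]!r},"
                    f"{table.national_total(year)!r},"
                    f"{round_half_up(adjusted.mg_per_kg[year], config.rounding_digits)}"
                )
            (out / "mg_per_kg.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")
            _plot_mg_per_kg(adjusted.mg_per_kg, out / "mg_per_kg.png")

    with _stage("trend"):
        series = [totals.year_totals()[y] for y in totals.years]
        trend = mann_kendall(series, config.mk_method)
        mean, sd = annual_mean_sd(series)
        doc = trend.to_dict() | {
            "series": series,
            "series_years": totals.years,
            "mean_kg_per_year": mean,
            "sd_kg_per_year": sd,
        }
        (out / "trend.json").write_text(json.dumps(doc, indent=2), encoding="utf-8")

    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return {
        "totals": totals,
        "summary": summary,
        "adjusted": adjusted,
        "trend": trend,
    }


def _plot_mg_per_kg(mg_per_kg: dict[int, float], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    years = sorted(mg_per_kg)
    ax.bar([str(y) for y in years], [mg_per_kg[y] for y in years], color="#4878a8")
    ax.set_xlabel("Year")
    ax.set_ylabel("Antimicrobial imports (mg) per kg animal biomass")
    ax.set_title("Biomass-standardised antimicrobial consumption")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
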