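# File formats

All files are UTF-8 CSV with comma separators and `.` decimals (locale
independent), or YAML/JSON where noted.  Quantities are metric: mg, ml, kg.

## records.csv

One row per shipment line of a finished product.

| column | type | notes |
|---|---|---|
| record_id | string | opaque; row numbers are used when empty.  Combination products use one row per active ingredient with a shared id prefix |
| year | int | calendar year of import |
| ingredient_name | string | declared compound, salt/hydrate forms allowed (resolved via the registry synonym table) |
| formulation | enum | `LIQUID`, `BLISTER`, `IU_LIQUID` |
| strength | float > 0 | mg/ml (LIQUID), mg/tablet (BLISTER), IU/ml (IU_LIQUID) |
| container_volume_ml | float > 0 | LIQUID and IU_LIQUID only; empty otherwise |
| tablets_per_blister | int ≥ 1 | BLISTER only |
| blisters_per_pack | int ≥ 1 | BLISTER only |
| packs | int ≥ 1 | single-unit imports are valid |
| food_animal_indication | bool | `true`/`false`; false rows are excluded from all totals |

Unknown columns are ignored with a logged warning; missing required columns
and rows violating the formulation-specific field rules are errors.

## registry.yaml

```yaml
list_edition: {woah: "...", who: "..."}
ingredients:
  - name: penicillin
    synonyms: [penicillin G procaine, benzylpenicillin]
    class: penicillins
    subclass: ""            # optional
    woah: VCIA              # VCIA | VHIA | VIA | UNCLASSIFIED
    who: CIA_HIGH           # CIA_HIGHEST | CIA_HIGH | HIGHLY_IMPORTANT | IMPORTANT | UNCLASSIFIED
    iu_to_mg: 0.0006        # required iff the ingredient appears in IU_LIQUID records
```

Duplicate names/synonyms are errors.  The bundled default is
`src/vetamc/data/registry.yaml`.

## denominators.csv

Long format: `species,item,year,value`.

| item | year | value |
|---|---|---|
| census_population | census year (exactly two rows per species) | head count |
| slaughter_count | study year | head slaughtered |
| slaughter_weight_kg | study year | total carcass weight, kg |
| conversion_coefficient | empty | carcass:live ratio in (0, 1] |
| standard_weight_kg | empty | standard live weight per head, kg (optional) |

Species: `cattle`, `sheep`, `goat`, `pig`, `chicken`.

## Outputs

* `annual_class_totals.csv` — rows = class/subclass, columns = years +
  total, cells `kg (percent-of-year)`, rounded half-up to 2 decimals.
* `importance_summary.csv` — class, subclass, WOAH category, kg, percent of
  category, WHO category.
* `biomass.csv` — species × year matrix in kg plus a national-totals row.
* `mg_per_kg.csv` — year, total_kg, biomass_kg, mg_per_kg.
* `trend.json` — n, S, tau, var_S, p_two_sided, method, the series tested,
  and the annual mean/sd.
* `ledger.json` (from `vetamc simulate`) — exact generated grams per
  year/class and biomass per year.
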