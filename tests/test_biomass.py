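"""Biomass denominator: census growth interpolation, carcass/live weights,
and the species conventions."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vetamc.biomass import (
    biomass_table,
    carcass_weight,
    growth_rate,
    interpolate_population,
    live_weight,
    national_biomass,
    species_biomass,
)
from vetamc.records import (
    Census,
    DenominatorInputs,
    SlaughterYear,
    SpeciesInputs,
)


class TestGrowthRate:
    def test_equal_populations_give_zero_rate(self):
        assert growth_rate(1000, 1000, 11).r == pytest.approx(0.0, abs=1e-12)

    def test_doubling_over_eleven_years(self):
        gr = growth_rate(100, 200, 11)
        assert gr.r == pytest.approx(0.06504, abs=5e-6)
        # oracle: compounding back onto the second census
        assert 100 * (1 + gr.r) ** 11 == pytest.approx(200, rel=1e-12)

    def test_population_decline(self):
        gr = growth_rate(200, 100, 11)
        assert gr.r == pytest.approx(-0.06107, abs=5e-6)
        assert 200 * (1 + gr.r) ** 11 == pytest.approx(100, rel=1e-12)

    @pytest.mark.parametrize("P1,P2,y", [(0, 100, 11), (100, -5, 11), (100, 100, 0)])
    def test_domain_errors(self, P1, P2, y):
        with pytest.raises(ValueError):
            growth_rate(P1, P2, y)

    @given(
        P1=st.floats(1.0, 1e7),
        P2=st.floats(1.0, 1e7),
        y=st.integers(1, 30),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_with_interpolation(self, P1, P2, y):
        gr = growth_rate(P1, P2, y)
        assert interpolate_population(P1, gr, y) == pytest.approx(P2, rel=1e-9)
        assert interpolate_population(P2, gr, -y) == pytest.approx(P1, rel=1e-9)


class TestInterpolatePopulation:
    def test_dt_zero_is_identity(self):
        assert interpolate_population(119_691, 0.05, 0) == 119_691

    def test_zero_rate_holds_population(self):
        assert interpolate_population(119_691, 0.0, 1) == 119_691

    def test_result_is_unrounded(self):
        pop = interpolate_population(100, growth_rate(100, 150, 11), 3)
        assert pop != round(pop)


class TestWeights:
    @pytest.mark.parametrize(
        "total,n,expected", [(210_000, 1000, 210.0), (37_500, 500, 75.0)]
    )
    def test_carcass_weight(self, total, n, expected):
        assert carcass_weight(total, n) == expected

    def test_zero_weight_is_degenerate_not_fatal(self, caplog):
        with caplog.at_level("WARNING"):
            assert carcass_weight(0, 10) == 0.0
        assert caplog.records

    def test_zero_animals_is_an_error(self):
        with pytest.raises(ValueError):
            carcass_weight(210_000, 0)

    @pytest.mark.parametrize(
        "carcass,coef,expected",
        [(210, 0.7, 300.0), (35.25, 0.47, 75.0), (78, 0.78, 100.0)],
    )
    def test_live_weight(self, carcass, coef, expected):
        assert live_weight(carcass, coef) == pytest.approx(expected)
        # conversion coefficients <= 1 can only inflate carcass to live weight
        assert live_weight(carcass, coef) >= carcass

    @pytest.mark.parametrize("coef", [0.0, -0.1, 1.5])
    def test_live_weight_coefficient_domain(self, coef):
        with pytest.raises(ValueError):
            live_weight(100.0, coef)


def _inputs(cattle_pop=100_000.0, goat_pop=143_853.0, chicken_kill=1_000_000.0,
            scale=1.0):
    """Inputs built so cattle live weight is 300 kg and chicken's is 2 kg."""
    return DenominatorInputs(species={
        "cattle": SpeciesInputs(
            census=Census(2009, cattle_pop * scale, 2020, cattle_pop * scale),
            slaughter={y: SlaughterYear(1000.0, 210_000.0) for y in range(2017, 2022)},
            conversion_coefficient=0.7,
        ),
        "sheep": SpeciesInputs(
            census=Census(2009, 37_435.0 * scale, 2020, 37_435.0 * scale),
            conversion_coefficient=0.47,
        ),
        "goat": SpeciesInputs(
            census=Census(2009, goat_pop * scale, 2020, goat_pop * scale),
            slaughter={y: SlaughterYear(5000.0, 88_125.0) for y in range(2017, 2022)},
            conversion_coefficient=0.47,
        ),
        "pig": SpeciesInputs(
            slaughter={y: SlaughterYear(2000.0 * scale, 124_800.0 * scale)
                       for y in range(2017, 2022)},
            conversion_coefficient=0.78,
        ),
        "chicken": SpeciesInputs(
            slaughter={y: SlaughterYear(chicken_kill * scale, None)
                       for y in range(2017, 2022)},
            conversion_coefficient=0.7,
        ),
    })


class TestSpeciesBiomass:
    def test_cattle_is_population_times_live_weight(self):
        # carcass 210 kg / 0.7 -> live 300 kg; population 100,000
        assert species_biomass("cattle", 2019, _inputs()) == pytest.approx(3.0e7)

    def test_goats_default_to_standard_weight(self):
        assert species_biomass("goat", 2019, _inputs()) == pytest.approx(
            143_853 * 37.5
        )

    def test_goats_slaughter_mode(self):
        # carcass 88125/5000 = 17.625 kg / 0.47 -> live 37.5 kg x 5000 head
        assert species_biomass(
            "goat", 2019, _inputs(), small_ruminant_mode="slaughter"
        ) == pytest.approx(5000 * 37.5)

    def test_chicken_standard_weight_fallback(self):
        # no slaughter weight totals -> default 2.0 kg/bird
        assert species_biomass("chicken", 2019, _inputs()) == pytest.approx(2.0e6)

    def test_missing_slaughter_year_names_species_and_year(self):
        with pytest.raises(ValueError, match="pig.*2030"):
            species_biomass("pig", 2030, _inputs())


class TestNationalBiomass:
    def test_additive_over_species(self):
        inputs = _inputs()
        total = national_biomass(2019, inputs)
        parts = [species_biomass(sp, 2019, inputs)
                 for sp in ("cattle", "sheep", "goat", "pig", "chicken")]
        assert total == pytest.approx(sum(parts), rel=1e-12)

    def test_homogeneous_of_degree_one(self):
        assert national_biomass(2019, _inputs(scale=2.0)) == pytest.approx(
            2.0 * national_biomass(2019, _inputs()), rel=1e-9
        )

    def test_table_matches_pointwise_computation(self):
        inputs = _inputs()
        table = biomass_table([2017, 2018, 2019], inputs)
        for year in (2017, 2018, 2019):
            assert table.national_total(year) == pytest.approx(
                national_biomass(year, inputs), rel=1e-12
            )

    def test_missing_year_raises(self):
        table = biomass_table([2019], _inputs())
        with pytest.raises(ValueError):
            table.national_total(1999)
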