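"""Mann-Kendall trend test (score, tie handling, exact and normal p-values)
plus the annual summary statistics and biomass adjustment."""

import itertools
import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vetamc.biomass import BiomassTable
from vetamc.quantify import AnnualClassTotals
from vetamc.trend import (
    MkMethod,
    adjust_by_biomass,
    annual_mean_sd,
    mahonian_counts,
    mann_kendall,
)

FIJI_ANNUAL_TOTALS = [129.93, 134.08, 153.56, 19.22, 27.51]


def brute_force_p(series):
    """Oracle: two-sided exact p by enumerating every ordering of the values."""
    def score(xs):
        return sum(
            int(xs[j] > xs[i]) - int(xs[j] < xs[i])
            for i, j in itertools.combinations(range(len(xs)), 2)
        )

    observed = abs(score(series))
    perms = list(itertools.permutations(series))
    hits = sum(abs(score(p)) >= observed for p in perms)
    return hits / len(perms)


class TestMannKendall:
    def test_fiji_series_reproduces_published_statistic(self):
        result = mann_kendall(FIJI_ANNUAL_TOTALS)
        assert result.S == -2
        assert result.tau == -0.2
        assert result.var_S == pytest.approx(300 / 18)  # n(n-1)(2n+5)/18, no ties

    def test_fiji_series_exact_p_matches_brute_force(self):
        result = mann_kendall(FIJI_ANNUAL_TOTALS, MkMethod.EXACT_ENUMERATION)
        assert result.p_two_sided == pytest.approx(98 / 120)
        assert result.p_two_sided == brute_force_p(FIJI_ANNUAL_TOTALS)

    def test_fiji_series_normal_cc_p(self):
        # the continuity-corrected normal route, which R's approximation uses
        result = mann_kendall(FIJI_ANNUAL_TOTALS, MkMethod.NORMAL_CC)
        assert result.p_two_sided == pytest.approx(0.8065, abs=5e-4)

    def test_strictly_monotone_series(self):
        result = mann_kendall([1, 2, 3, 4, 5])
        assert (result.S, result.tau) == (10, 1.0)
        assert result.p_two_sided == pytest.approx(2 / 120)

    def test_agrees_with_r_kendall_correlation(self, tmp_path):
        # independent oracle: base R cor.test against the time index
        script = tmp_path / "mk.R"
        script.write_text(
            "x <- c(129.93, 134.08, 153.56, 19.22, 27.51)\n"
            "ct <- cor.test(seq_along(x), x, method='kendall')\n"
            "cat(sprintf('%.15g', c(ct$estimate, ct$p.value)), sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, check=True,
        ).stdout.split()
        r_tau, r_p = float(out[0]), float(out[1])
        result = mann_kendall(FIJI_ANNUAL_TOTALS, MkMethod.EXACT_ENUMERATION)
        assert result.tau == pytest.approx(r_tau, abs=1e-9)
        assert result.p_two_sided == pytest.approx(r_p, abs=1e-9)

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_exact_p_equals_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(8):
            series = list(rng.normal(size=n))
            result = mann_kendall(series, MkMethod.EXACT_ENUMERATION)
            assert result.p_two_sided == pytest.approx(brute_force_p(series))

    def test_normal_cc_close_to_exact_at_n10(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            series = list(rng.normal(size=10))
            exact = mann_kendall(series, MkMethod.EXACT_ENUMERATION).p_two_sided
            approx = mann_kendall(series, MkMethod.NORMAL_CC).p_two_sided
            assert abs(exact - approx) < 0.02

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=12, unique=True))
    @settings(max_examples=100, deadline=None)
    def test_reversal_negates_s_and_tau(self, series):
        fwd = mann_kendall(series)
        rev = mann_kendall(series[::-1])
        assert rev.S == -fwd.S
        assert rev.tau == pytest.approx(-fwd.tau)
        assert rev.p_two_sided == pytest.approx(fwd.p_two_sided)

    def test_invariant_under_increasing_transform(self):
        series = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6]
        a = mann_kendall(series)
        b = mann_kendall([math.exp(x / 10) for x in series])
        assert (a.S, a.tau, a.p_two_sided) == (b.S, b.tau, b.p_two_sided)

    def test_ties_use_corrected_variance_and_fall_back_to_normal(self):
        series = [1.0, 2.0, 2.0, 3.0, 0.5]
        result = mann_kendall(series, MkMethod.EXACT_ENUMERATION)
        assert result.method is MkMethod.NORMAL_CC  # exact refuses ties
        # var = [n(n-1)(2n+5) - t(t-1)(2t+5)]/18 with one tie group of 2
        assert result.var_S == pytest.approx((300 - 2 * 1 * 9) / 18)

    def test_constant_series_has_no_trend(self, caplog):
        with caplog.at_level("WARNING"):
            result = mann_kendall([5.0, 5.0, 5.0])
        assert (result.tau, result.p_two_sided) == (0.0, 1.0)

    def test_short_series_is_rejected(self):
        with pytest.raises(ValueError):
            mann_kendall([1.0, 2.0])

    def test_mahonian_counts_sum_to_factorial(self):
        for n in range(1, 9):
            assert sum(mahonian_counts(n)) == math.factorial(n)


class TestAnnualMeanSd:
    def test_fiji_totals(self):
        mean, sd = annual_mean_sd(FIJI_ANNUAL_TOTALS)
        assert mean == pytest.approx(92.86)
        # from the printed (rounded) totals; the source prints 64.12 from
        # unrounded internals
        assert sd == pytest.approx(64.13, abs=5e-3)

    def test_constant_series_sd_zero(self):
        assert annual_mean_sd([5, 5, 5]) == (5.0, 0.0)

    def test_empty_series_is_an_error(self):
        with pytest.raises(ValueError):
            annual_mean_sd([])

    def test_matches_numpy_ddof1(self):
        rng = np.random.default_rng(0)
        series = list(rng.lognormal(3, 1, size=11))
        mean, sd = annual_mean_sd(series)
        assert mean == pytest.approx(np.mean(series))
        assert sd == pytest.approx(np.std(series, ddof=1))


class TestAdjustByBiomass:
    def _totals(self, kg_by_year):
        return AnnualClassTotals(cells={
            (year, ("penicillins", "")): kg for year, kg in kg_by_year.items()
        })

    def test_unit_conversion(self):
        totals = self._totals({2019: 1.0})
        biomass = BiomassTable(entries={("cattle", 2019): 1e6})
        adjusted = adjust_by_biomass(totals, biomass)
        assert adjusted.mg_per_kg == {2019: pytest.approx(1.0)}

    def test_zero_imports_give_zero_rate(self):
        totals = self._totals({2019: 0.0, 2020: 2.0})
        biomass = BiomassTable(entries={("cattle", 2019): 1e6, ("cattle", 2020): 1e6})
        adjusted = adjust_by_biomass(totals, biomass)
        assert adjusted.mg_per_kg[2019] == 0.0
        assert adjusted.mg_per_kg[2020] == pytest.approx(2.0)

    def test_mean_and_sd_across_years(self):
        totals = self._totals({2019: 1.0, 2020: 3.0})
        biomass = BiomassTable(entries={("cattle", 2019): 1e6, ("cattle", 2020): 1e6})
        adjusted = adjust_by_biomass(totals, biomass)
        assert adjusted.mean == pytest.approx(2.0)
        assert adjusted.sd == pytest.approx(math.sqrt(2))

    def test_missing_biomass_year_is_an_error(self):
        totals = self._totals({2019: 1.0})
        with pytest.raises(ValueError):
            adjust_by_biomass(totals, BiomassTable(entries={("cattle", 2018): 1e6}))
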