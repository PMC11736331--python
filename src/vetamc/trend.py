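"""Annual-series summary statistics and the Mann-Kendall trend test.

The Mann-Kendall test is a nonparametric test for a monotonic trend in a
time series.  The score is

    S = sum_{i<j} sign(x_j - x_i),

Kendall's tau-b normalises S by the number of comparable pairs with a tie
correction, and the null variance is

    var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18

where t runs over tie-group sizes.  Two p-value routes are implemented from
first principles:

* EXACT_ENUMERATION — for short tie-free series the null distribution of S
  follows the Mahonian (permutation inversion-count) distribution; the
  two-sided p-value is P(|S*| >= |S|) over all n! orderings, computed from
  the inversion-count recurrence without enumerating permutations.
* NORMAL_CC — the continuity-corrected normal approximation
  z = (S - sign(S)) / sqrt(var(S)).

The biomass adjustment divides annual imports (converted to mg) by the
national food-animal biomass (kg), giving the standardised mg/kg rate.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

from .biomass import BiomassTable
from .quantify import AnnualClassTotals

logger = logging.getLogger(__name__)

__all__ = [
    "MkMethod",
    "TrendResult",
    "AdjustedConsumption",
    "mann_kendall",
    "annual_mean_sd",
    "adjust_by_biomass",
    "mahonian_counts",
]


class MkMethod(str, enum.Enum):
    EXACT_ENUMERATION = "EXACT_ENUMERATION"
    NORMAL_CC = "NORMAL_CC"  # continuity-corrected normal approximation
    NORMAL = "NORMAL"


@dataclass(frozen=True)
class TrendResult:
    n: int
    S: int
    tau: float
    var_S: float
    p_two_sided: float
    method: MkMethod

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "S": self.S,
            "tau": self.tau,
            "var_S": self.var_S,
            "p_two_sided": self.p_two_sided,
            "method": self.method.value,
        }


def _score_and_ties(series: list[float]) -> tuple[int, list[int]]:
    n = len(series)
    S = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = series[j] - series[i]
            S += (d > 0) - (d < 0)
    counts: dict[float, int] = {}
    for x in series:
        counts[x] = counts.get(x, 0) + 1
    ties = [t for t in counts.values() if t > 1]
    return S, ties


def mahonian_counts(n: int) -> list[int]:
    """Number of permutations of n distinct items with k inversions,
    for k = 0 .. n(n-1)/2 (the Mahonian distribution).

    Built by the generating-function recurrence: the inversion polynomial of
    S_n is prod_{i=1..n} (1 + q + ... + q^(i-1)).
    """
    counts = [1]
    for i in range(2, n + 1):
        # multiply by (1 + q + ... + q^(i-1)) using a sliding cumulative sum
        new = [0] * (len(counts) + i - 1)
        running = 0
        for k in range(len(new)):
            if k < len(counts):
                running += counts[k]
            if k - i >= 0:
                running -= counts[k - i]
            new[k] = running
        counts = new
    return counts


def _exact_p(S: int, n: int) -> float:
    """Two-sided exact p-value P(|S*| >= |S|) for a tie-free series.

    With no ties, S = n(n-1)/2 - 2*inversions, so the null distribution of S
    is the (symmetric) Mahonian distribution rescaled.
    """
    counts = mahonian_counts(n)
    n0 = n * (n - 1) // 2
    total = math.factorial(n)
    favourable = sum(
        c for k, c in enumerate(counts) if abs(n0 - 2 * k) >= abs(S)
    )
    return favourable / total


def _normal_sf(z: float) -> float:
    """Upper-tail standard normal probability."""
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def mann_kendall(
    series: list[float], method: MkMethod | str | None = None
) -> TrendResult:
    """Mann-Kendall test for monotonic trend in an annual series.

    By default the exact enumeration is used for tie-free series with
    n <= 10 and the continuity-corrected normal approximation otherwise.
    A constant series yields tau = 0, p = 1 with a logged warning.
    """
    series = [float(x) for x in series]
    n = len(series)
    if n < 3:
        raise ValueError(f"Mann-Kendall needs at least 3 observations, got {n}")
    if not all(math.isfinite(x) for x in series):
        raise ValueError("series contains non-finite values")
    if method is not None:
        method = MkMethod(method)

    S, ties = _score_and_ties(series)
    n0 = n * (n - 1) // 2
    tie_pairs = sum(t * (t - 1) // 2 for t in ties)
    denom = math.sqrt((n0 - tie_pairs) * n0)  # tau-b; the time axis has no ties
    if denom == 0:
        logger.warning("constant series: no trend is identifiable")
        var_S = 0.0
        return TrendResult(n=n, S=S, tau=0.0, var_S=var_S, p_two_sided=1.0,
                           method=method or MkMethod.EXACT_ENUMERATION)
    tau = S / denom

    var_S = (
        n * (n - 1) * (2 * n + 5)
        - sum(t * (t - 1) * (2 * t + 5) for t in ties)
    ) / 18.0

    if method is None:
        method = (
            MkMethod.EXACT_ENUMERATION
            if n <= 10 and not ties
            else MkMethod.NORMAL_CC
        )
    elif method is MkMethod.EXACT_ENUMERATION and ties:
        logger.info(
            "exact enumeration is only valid without ties; "
            "falling back to the continuity-corrected normal approximation"
        )
        method = MkMethod.NORMAL_CC

    if method is MkMethod.EXACT_ENUMERATION:
        p = _exact_p(S, n)
    else:
        if var_S <= 0:
            p = 1.0
        else:
            if method is MkMethod.NORMAL_CC:
                z = (S - (S > 0) + (S < 0)) / math.sqrt(var_S)
            else:
                z = S / math.sqrt(var_S)
            p = min(1.0, 2.0 * _normal_sf(abs(z)))
    return TrendResult(n=n, S=S, tau=tau, var_S=var_S, p_two_sided=p, method=method)


def annual_mean_sd(series: list[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation of a series."""
    n = len(series)
    if n == 0:
        raise ValueError("empty series")
    mean = math.fsum(series) / n
    if n < 2:
        return mean, float("nan")
    ss = math.fsum((x - mean) ** 2 for x in series)
    return mean, math.sqrt(ss / (n - 1))


@dataclass
class AdjustedConsumption:
    """Biomass-standardised consumption: mg of active ingredient per kg of
    food-animal biomass, by year, with mean and sample sd across years."""

    mg_per_kg: dict[int, float]

    @property
    def mean(self) -> float:
        return annual_mean_sd(list(self.mg_per_kg.values()))[0]

    @property
    def sd(self) -> float:
        return annual_mean_sd(list(self.mg_per_kg.values()))[1]


def adjust_by_biomass(
    totals: AnnualClassTotals, biomass: BiomassTable
) -> AdjustedConsumption:
    """Divide annual imports (mg) by national biomass (kg) per year.

    mg/kg = annual kg x 10^6 / national biomass kg.  A zero or missing
    biomass denominator is an error.
    """
    year_totals = totals.year_totals()
    out: dict[int, float] = {}
    for year in totals.years:
        denom = biomass.national_total(year)  # raises if missing
        if denom <= 0:
            raise ValueError(f"non-positive biomass denominator for year {year}")
        out[year] = year_totals[year] * 1e6 / denom
    return AdjustedConsumption(mg_per_kg=out)
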