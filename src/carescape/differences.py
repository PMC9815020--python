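"""Urban-rural difference statistics and regional ranking summaries.

Three elementary statistics compare urban and rural development:

* time-series ratio  T_t = S_t / S_base   (base year ratio = 1),
* proportion difference  P = P_urban - P_rural  (percentage points),
* composite-score ratio  Z_ratio = Z_urban / Z_rural.

Plus cumulative percentage-point changes over a window, the coefficient of
variation of city scores, and 20/60/20 ranking bands reported as regional
shares of the full city set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indicators import PROPORTION_IDS, QUANTITY_IDS, REGIONS
from .io import IndicatorPanel, NationalTables

__all__ = [
    "round_display",
    "timeseries_ratio",
    "proportion_diff",
    "composite_ratio",
    "cumulative_pp_change",
    "coefficient_of_variation",
    "RegionalBands",
    "regional_bands",
    "time_ratio_table",
    "proportion_diff_table",
]

logger = logging.getLogger("carescape.differences")


def round_display(x, dp: int = 2):
    """Half-away-from-zero rounding used for all published-table displays."""
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** dp
    # nudge compensates for binary representation of decimal inputs
    # (e.g. 2.675 * 100 == 267.49999...)
    out = np.sign(x) * np.floor(np.abs(x) * factor * (1 + 1e-12) + 0.5) / factor
    return out.item() if out.ndim == 0 else out


def timeseries_ratio(series: pd.Series, base_year: int | None = None) -> pd.Series:
    """Ratio of each year's value to the base-year value (base ratio = 1).

    ``series`` is indexed by year. If the base year's value is missing or
    zero, the next usable year becomes the base (logged) and earlier years are
    dropped, mirroring the stated fallback for cities whose initial year is
    unrecorded. Raw ratios are returned; display rounding is separate.
    """
    s = series.sort_index().astype(float)
    if s.isna().all():
        raise ValueError("all years missing in time series")
    years = list(s.index)
    base = base_year if base_year is not None else years[0]
    if base not in years:
        raise ValueError(f"base year {base} not in series")
    usable = [y for y in years if y >= base and not pd.isna(s[y]) and s[y] != 0]
    if not usable:
        raise ZeroDivisionError("no usable base year: all candidates missing or zero")
    if usable[0] != base:
        logger.warning("base year %s missing or zero; substituting %s", base, usable[0])
        base = usable[0]
    out = s[s.index >= base] / s[base]
    out.name = series.name
    return out


def proportion_diff(urban_pct, rural_pct):
    """Urban minus rural percentage, both required to lie in [0, 100]."""
    u, r = np.asarray(urban_pct, dtype=float), np.asarray(rural_pct, dtype=float)
    for name, v in (("urban", u), ("rural", r)):
        valid = np.isnan(v) | ((v >= 0) & (v <= 100))
        if not valid.all():
            raise ValueError(f"{name} proportion outside [0, 100]")
    out = u - r
    return out.item() if out.ndim == 0 else out


def composite_ratio(z_urban: float, z_rural: float, city_id: str | None = None) -> float:
    """Urban-to-rural composite score ratio Z_u / Z_r (requires Z_r > 0)."""
    if z_rural == 0:
        where = f" for city {city_id}" if city_id else ""
        raise ZeroDivisionError(f"rural composite score is zero{where}")
    return z_urban / z_rural


def cumulative_pp_change(panel: IndicatorPanel, indicators, area: str,
                         start_year: int, end_year: int) -> float:
    """Sum over indicators of (value at end_year - value at start_year),
    in percentage points, for one area of the national series."""
    df = panel.data
    total = 0.0
    for ind in indicators:
        sub = df[(df["indicator"] == ind) & (df["area"] == area)]
        by_year = sub.groupby("year")["value"].mean()
        for y in (start_year, end_year):
            if y not in by_year.index or pd.isna(by_year[y]):
                raise ValueError(f"{ind} ({area}) missing endpoint year {y}")
        total += by_year[end_year] - by_year[start_year]
    return total


def coefficient_of_variation(scores) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    x = np.asarray(list(scores), dtype=float)
    if len(x) < 2:
        raise ValueError("coefficient of variation needs at least two values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("zero mean: coefficient of variation undefined")
    return x.std(ddof=1) / mean


@dataclass
class RegionalBands:
    """20/60/20 ranking bands as regional shares of all ranked cities."""

    shares: pd.DataFrame = field(repr=False)  # index band, columns region, % of n
    assignment: pd.Series = field(repr=False)  # city_id -> band label
    n: int = 0

    BANDS = ("top20", "middle60", "bottom20")


def regional_bands(scores: pd.Series, regions: pd.Series,
                   bands: tuple[float, float, float] = (0.2, 0.6, 0.2)) -> RegionalBands:
    """Rank cities by score (descending, ties broken by city_id ascending)
    and report each region's share of the top/middle/bottom bands.

    Band sizes use the ceiling rule: top = ceil(share_top * n) and
    bottom = ceil(share_bottom * n), the remainder is the middle band.
    Shares are percentages of the full ranked set, so one area's shares sum
    to 100 up to rounding.
    """
    scores = scores.dropna()
    if scores.empty:
        raise ValueError("no scores to rank")
    if not math.isclose(sum(bands), 1.0, abs_tol=1e-9):
        raise ValueError("band shares must sum to 1")
    order = sorted(scores.index, key=lambda c: (-scores[c], c))
    n = len(order)
    n_top = math.ceil(bands[0] * n)
    n_bot = math.ceil(bands[2] * n)
    if n_top + n_bot > n:  # degenerate tiny inputs
        n_bot = n - n_top
    labels = {}
    for rank, city in enumerate(order):
        if rank < n_top:
            labels[city] = "top20"
        elif rank >= n - n_bot:
            labels[city] = "bottom20"
        else:
            labels[city] = "middle60"
    assignment = pd.Series(labels, name="band").sort_index()
    tab = pd.DataFrame(0.0, index=list(RegionalBands.BANDS), columns=list(REGIONS))
    for city, band in assignment.items():
        tab.loc[band, regions[city]] += 1
    tab = tab / n * 100.0
    return RegionalBands(shares=tab, assignment=assignment, n=n)


# -- published-table layouts ------------------------------------------------

def time_ratio_table(tables: NationalTables, dp: int | None = 2) -> pd.DataFrame:
    """Base-2010 time ratios for the six quantity indicators, urban and rural
    (the published layout: rows (area, indicator), columns years)."""
    rows = {}
    for area in ("urban", "rural"):
        tab = tables.table(area)
        for ind in QUANTITY_IDS:
            ratios = timeseries_ratio(tab.loc[ind])
            if dp is not None:
                ratios = pd.Series(round_display(ratios, dp), index=ratios.index)
            rows[(area, ind)] = ratios
    out = pd.DataFrame(rows).T
    out.index.names = ["area", "indicator"]
    return out


def proportion_diff_table(tables: NationalTables, dp: int | None = 2) -> pd.DataFrame:
    """Urban-minus-rural percentage points for the 11 proportional indicators
    (published layout: rows indicators, columns years)."""
    urban, rural = tables.table("urban"), tables.table("rural")
    out = {}
    for ind in PROPORTION_IDS:
        diff = proportion_diff(urban.loc[ind].to_numpy(), rural.loc[ind].to_numpy())
        out[ind] = round_display(diff, dp) if dp is not None else diff
    table = pd.DataFrame(out, index=urban.columns).T
    table.index.name = "indicator"
    return table
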