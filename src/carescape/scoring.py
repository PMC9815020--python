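"""Indicator weights, range standardization and composite scores.

Weighting follows the published two-step scheme: every tertiary indicator
starts from the equal base weight 1/17; the three proportional secondary
groups (staff age structure, resident nature, self-care ability) then have
their pooled weight 3/17 redistributed within the group by expert shares
(0.5/0.3/0.2, 0.2/0.3/0.5 and 0.2/0.35/0.45 in table order). Weights are
carried as exact fractions and only rounded to 4 decimals for display.

The composite score of a city/area/year is Z = sum_i w_i * d_i where d_i is
the min-max (range) standardized indicator value over a declared comparison
pool. Secondary and primary scores use their subtree weights renormalized to
the subtree total, so every score lies in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
import yaml

from .indicators import INDICATORS, INDICATOR_IDS, by_id
from .io import IndicatorPanel

__all__ = [
    "WeightScheme",
    "StandardizedPanel",
    "CompositeScores",
    "DegenerateScaleError",
    "build_weight_scheme",
    "minmax_standardize",
    "composite_score",
]

logger = logging.getLogger("carescape.scoring")

POOLS = ("all_years_both_areas", "per_year_per_area")


class DegenerateScaleError(ValueError):
    """An indicator's comparison pool has max == min."""


@dataclass(frozen=True)
class WeightScheme:
    """Tertiary weights (exact fractions) plus the aggregation tree."""

    weights: dict[str, Fraction]
    tree: dict[str, dict[str, list[str]]]
    directions: dict[str, str]

    def weight(self, indicator_id: str) -> float:
        return float(self.weights[indicator_id])

    def weight_rounded(self, indicator_id: str, dp: int = 4) -> float:
        return round(float(self.weights[indicator_id]), dp)

    @property
    def total(self) -> Fraction:
        return sum(self.weights.values(), Fraction(0))

    def as_series(self) -> pd.Series:
        return pd.Series({k: float(v) for k, v in self.weights.items()},
                         name="weight").loc[list(INDICATOR_IDS)]

    def to_yaml(self, path) -> None:
        payload = [{"indicator": i,
                    "secondary": by_id(i).secondary,
                    "primary": by_id(i).primary,
                    "weight": [self.weights[i].numerator, self.weights[i].denominator],
                    "direction": self.directions[i]}
                   for i in INDICATOR_IDS]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "WeightScheme":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        weights = {e["indicator"]: Fraction(*e["weight"]) for e in payload}
        directions = {e["indicator"]: e.get("direction", "positive") for e in payload}
        tree: dict[str, dict[str, list[str]]] = {}
        for e in payload:
            tree.setdefault(e["primary"], {}).setdefault(e["secondary"], []).append(e["indicator"])
        scheme = cls(weights=weights, tree=tree, directions=directions)
        scheme._check()
        return scheme

    def _check(self) -> None:
        if abs(float(self.total) - 1.0) > 1e-9:
            raise ValueError(f"tertiary weights sum to {float(self.total)}, not 1")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all weights must be positive")


def build_weight_scheme() -> WeightScheme:
    """Construct the default 17-indicator weight scheme.

    The 8 indicators outside the redistribution groups keep the base 1/17;
    each redistribution-group indicator gets (3/17) x its within-group share,
    so each group still sums to 3/17 and the total is exactly 1.
    """
    base = Fraction(1, 17)
    group_total = 3 * base
    weights: dict[str, Fraction] = {}
    tree: dict[str, dict[str, list[str]]] = {}
    for ind in INDICATORS:
        weights[ind.id] = group_total * ind.share if ind.share is not None else base
        tree.setdefault(ind.primary, {}).setdefault(ind.secondary, []).append(ind.id)
    scheme = WeightScheme(weights=weights, tree=tree,
                          directions={i: "positive" for i in INDICATOR_IDS})
    scheme._check()
    return scheme


@dataclass
class StandardizedPanel:
    """Range-standardized panel: same keys as the input, values d in [0, 1].

    ``frame`` records the comparison pool used for min/max; ``bounds`` holds
    the per-pool (min, max) actually applied.
    """

    data: pd.DataFrame = field(repr=False)
    pool: str = "all_years_both_areas"
    bounds: pd.DataFrame | None = None


def minmax_standardize(panel: IndicatorPanel,
                       scheme: WeightScheme | None = None,
                       pool: str = "all_years_both_areas") -> StandardizedPanel:
    """Map each indicator to [0, 1] by (x - min)/(max - min) over the pool.

    ``pool`` = ``all_years_both_areas`` (default) uses one min/max per
    indicator over all cities, both area types and all years, so scores stay
    comparable across years and between urban and rural; ``per_year_per_area``
    recomputes the frame within each year/area slice. Direction is taken from
    the scheme (all indicators positive by default); negative indicators use
    (max - x)/(max - min). Missing values remain missing.
    """
    if pool not in POOLS:
        raise ValueError(f"unknown pool {pool!r}; choose from {POOLS}")
    scheme = scheme or build_weight_scheme()
    df = panel.data.copy()
    group_cols = ["indicator"] if pool == "all_years_both_areas" else ["indicator", "year", "area"]
    grp = df.groupby(group_cols)["value"]
    lo, hi = grp.transform("min"), grp.transform("max")

    degenerate = df.loc[(hi == lo) & df["value"].notna(), "indicator"].unique()
    if len(degenerate):
        raise DegenerateScaleError(
            f"max == min in standardization pool for indicator(s): {sorted(degenerate)}")

    d = (df["value"] - lo) / (hi - lo)
    neg = df["indicator"].map(scheme.directions) == "negative"
    d = d.where(~neg, 1.0 - d)
    df["value"] = d

    bounds = (df.assign(lo=lo, hi=hi)
              .groupby(group_cols)[["lo", "hi"]].first().rename(
                  columns={"lo": "pool_min", "hi": "pool_max"}))
    return StandardizedPanel(data=df, pool=pool, bounds=bounds)


@dataclass
class CompositeScores:
    """Per (city_id, area, year): overall Z plus secondary/primary subscores.

    ``data`` columns: city_id, region, area, year, Z, sec_<group>...,
    pri_<dimension>..., n_missing.
    """

    data: pd.DataFrame = field(repr=False)

    def overall(self) -> pd.DataFrame:
        return self.data[["city_id", "region", "area", "year", "Z"]]

    def series(self, area: str, year: int) -> pd.Series:
        sub = self.data[(self.data["area"] == area) & (self.data["year"] == year)]
        return sub.set_index("city_id")["Z"].sort_index()


def composite_score(std: StandardizedPanel,
                    scheme: WeightScheme | None = None,
                    missing: str = "propagate") -> CompositeScores:
    """Aggregate standardized values into secondary, primary and overall scores.

    ``missing`` controls incomplete city/area/years:
      * ``propagate`` (default) — any missing tertiary value makes the scores
        that depend on it NaN (downstream zero-assignment handles these);
      * ``renormalize`` — weights are rescaled over the observed indicators;
      * ``strict`` — raise on any missing value.
    The overall Z is always the flat weighted sum over the 17 tertiary
    weights; subtree scores divide by their subtree weight total so each lies
    in [0, 1].
    """
    if missing not in {"propagate", "renormalize", "strict"}:
        raise ValueError(f"unknown missing policy {missing!r}")
    scheme = scheme or build_weight_scheme()
    wide = (std.data.set_index(["city_id", "region", "area", "year", "indicator"])
            ["value"].unstack("indicator"))
    absent = [i for i in INDICATOR_IDS if i not in wide.columns]
    if absent and missing == "strict":
        raise ValueError(f"indicators absent from panel: {absent}")
    for i in absent:
        wide[i] = np.nan
    wide = wide[list(INDICATOR_IDS)]
    if missing == "strict" and wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)][0]
        raise ValueError(f"missing standardized values, e.g. at {bad}")

    w = scheme.as_series()
    vals = wide.to_numpy(dtype=float)
    obs = ~np.isnan(vals)

    def weighted(cols: list[str]) -> np.ndarray:
        sel = [wide.columns.get_loc(c) for c in cols]
        v, m = vals[:, sel], obs[:, sel]
        wsub = w.iloc[sel].to_numpy()
        if missing == "renormalize":
            denom = (m * wsub).sum(axis=1)
            num = np.nansum(np.where(m, v, 0.0) * wsub, axis=1)
            out = np.divide(num, denom, out=np.full(len(v), np.nan), where=denom > 0)
        else:
            out = (v * wsub).sum(axis=1) / wsub.sum()
        return out

    scores = wide.index.to_frame(index=False)
    # overall Z: flat dot product with the full (unit-sum) weight vector
    if missing == "renormalize":
        scores["Z"] = weighted(list(INDICATOR_IDS))
    else:
        scores["Z"] = (vals * w.to_numpy()).sum(axis=1)
    for primary, secondaries in scheme.tree.items():
        for secondary, ids in secondaries.items():
            scores[f"sec_{secondary}"] = weighted(ids)
        scores[f"pri_{primary}"] = weighted(
            [i for ids in secondaries.values() for i in ids])
    scores["n_missing"] = (~obs).sum(axis=1)
    return CompositeScores(data=scores)
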