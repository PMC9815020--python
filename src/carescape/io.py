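"""Panel data model, CSV/GeoJSON input-output, validation and imputation.

The panel is long (tidy): one row per (city_id, region, area, year, indicator)
with the observation in yearbook units. Out-of-range or unparseable values are
flagged missing with a logged warning rather than dropped, so that downstream
stages can apply the stated imputation or zero-assignment policies explicitly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .indicators import (AREAS, INDICATOR_IDS, PROPORTION_IDS, REGIONS, by_id)

__all__ = [
    "IndicatorPanel",
    "NationalTables",
    "PanelSchemaError",
    "PanelIntegrityError",
    "read_panel",
    "write_panel",
    "impute_missing",
    "load_fixture_tables",
    "fixture_panel",
    "load_reference_time_ratios",
    "load_reference_proportion_diffs",
    "read_city_geometry",
    "write_city_geometry",
]

logger = logging.getLogger("carescape.io")

PANEL_COLUMNS = ["city_id", "region", "area", "year", "indicator", "value"]
#: proportional secondary groups whose shares, as printed, need not sum to 100;
#: validation only warns when a group total exceeds this bound
GROUP_SUM_WARN = 100.5


class PanelSchemaError(ValueError):
    """A required column is absent or a categorical value is unrecognised."""


class PanelIntegrityError(ValueError):
    """A (city_id, area, year, indicator) key occurs more than once."""


@dataclass
class IndicatorPanel:
    """Validated long-format indicator panel.

    ``data`` columns: city_id, region, area, year, indicator, value (float,
    NaN = missing), missing (bool), imputed (bool).
    """

    data: pd.DataFrame = field(repr=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, validate: bool = True) -> "IndicatorPanel":
        df = df.copy()
        missing_cols = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise PanelSchemaError(f"missing required columns: {missing_cols}")
        df["city_id"] = df["city_id"].astype(str)
        df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
        raw = df["value"]
        df["value"] = pd.to_numeric(raw, errors="coerce").astype(float)
        unparseable = df["value"].isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if unparseable.any():
            logger.warning("flagged %d unparseable values as missing", int(unparseable.sum()))
        if "missing" not in df.columns:
            df["missing"] = False
        df["missing"] = df["missing"].astype(bool) | df["value"].isna()
        if "imputed" not in df.columns:
            df["imputed"] = False
        df["imputed"] = df["imputed"].astype(bool)
        df.loc[df["missing"], "value"] = np.nan
        panel = cls(df[PANEL_COLUMNS + ["missing", "imputed"]].reset_index(drop=True))
        if validate:
            panel.validate()
        return panel

    # -- validation ---------------------------------------------------------

    def validate(self) -> "IndicatorPanel":
        df = self.data
        bad_ind = set(df["indicator"]) - set(INDICATOR_IDS)
        if bad_ind:
            raise PanelSchemaError(f"unknown indicators: {sorted(bad_ind)}")
        bad_area = set(df["area"]) - set(AREAS)
        if bad_area:
            raise PanelSchemaError(f"unknown area types: {sorted(bad_area)}")
        bad_region = set(df["region"]) - set(REGIONS)
        if bad_region:
            raise PanelSchemaError(f"unknown regions: {sorted(bad_region)}")

        key = ["city_id", "area", "year", "indicator"]
        dup = df.duplicated(subset=key)
        if dup.any():
            example = df.loc[dup, key].iloc[0].tolist()
            raise PanelIntegrityError(
                f"{int(dup.sum())} duplicate panel keys, e.g. {example}")

        # range rules: quantities >= 0, proportions in [0, 100]
        kinds = df["indicator"].map(lambda i: by_id(i).kind)
        neg_qty = (kinds == "quantity") & df["value"].notna() & (df["value"] < 0)
        bad_prop = ((kinds == "proportion") & df["value"].notna()
                    & ~df["value"].between(0.0, 100.0))
        out = neg_qty | bad_prop
        if out.any():
            logger.warning("flagged %d out-of-range values as missing", int(out.sum()))
            df.loc[out, "value"] = np.nan
            df.loc[out, "missing"] = True

        # proportional groups need not sum to 100 exactly; warn when they
        # overshoot materially
        prop = df[df["indicator"].isin(PROPORTION_IDS) & df["value"].notna()].copy()
        if len(prop):
            prop["group"] = prop["indicator"].map(lambda i: by_id(i).secondary)
            sums = prop.groupby(["city_id", "area", "year", "group"])["value"].agg(["sum", "size"])
            over = sums[(sums["size"] == 3) & (sums["sum"] > GROUP_SUM_WARN)]
            if len(over):
                logger.warning("%d proportional groups sum above %.1f%%",
                               len(over), GROUP_SUM_WARN)
        return self

    # -- conveniences -------------------------------------------------------

    def copy(self) -> "IndicatorPanel":
        return IndicatorPanel(self.data.copy())

    @property
    def cities(self) -> list[str]:
        return sorted(self.data["city_id"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    def regions(self) -> pd.Series:
        """city_id -> region mapping (first occurrence wins)."""
        return (self.data.drop_duplicates("city_id")
                .set_index("city_id")["region"].sort_index())

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IndicatorPanel):
            return NotImplemented
        a = self.data.sort_values(PANEL_COLUMNS[:5]).reset_index(drop=True)
        b = other.data.sort_values(PANEL_COLUMNS[:5]).reset_index(drop=True)
        return a.equals(b)


def read_panel(path: str | Path, format: str = "csv") -> IndicatorPanel:
    """Read a panel CSV (columns city_id, region, area, year, indicator, value)."""
    if format != "csv":
        raise ValueError(f"unsupported panel format: {format!r}")
    df = pd.read_csv(path, dtype={"city_id": str}, keep_default_na=True,
                     float_precision="round_trip")
    return IndicatorPanel.from_dataframe(df)


def write_panel(panel: IndicatorPanel, path: str | Path) -> None:
    """Write a panel to CSV; missing values serialize as empty fields."""
    # 17 significant digits guarantee binary64 round-trip through text
    panel.data.to_csv(path, index=False, float_format="%.17g")


# -- imputation -------------------------------------------------------------

def _domain_clip(values: np.ndarray, indicator_id: str) -> np.ndarray:
    lo, hi = (0.0, 100.0) if by_id(indicator_id).kind == "proportion" else (0.0, np.inf)
    return np.clip(values, lo, hi)


def _fill_series(years: np.ndarray, vals: np.ndarray, policy: str,
                 indicator_id: str) -> np.ndarray:
    """Fill NaNs in one city/area/indicator series ordered by year."""
    obs = ~np.isnan(vals)
    n_obs = obs.sum()
    out = vals.copy()
    if n_obs == 0 or n_obs == len(vals):
        return out
    oy, ov = years[obs], vals[obs]
    if n_obs == 1:
        out[~obs] = ov[0]
        return _domain_clip(out, indicator_id)

    def trend_boundary(y):
        # linear extrapolation from the two nearest observed years
        if y < oy[0]:
            y0, y1, v0, v1 = oy[0], oy[1], ov[0], ov[1]
        else:
            y0, y1, v0, v1 = oy[-2], oy[-1], ov[-2], ov[-1]
        slope = (v1 - v0) / (y1 - y0)
        return v1 + slope * (y - y1) if y > oy[-1] else v0 + slope * (y - y0)

    mean_val = ov.mean()
    for idx in np.flatnonzero(~obs):
        y = years[idx]
        boundary = y < oy[0] or y > oy[-1]
        if policy == "mean":
            out[idx] = mean_val
        elif policy == "trend":
            out[idx] = trend_boundary(y) if boundary else np.interp(y, oy, ov)
        else:  # "default": trend-extrapolate boundaries, average interiors
            out[idx] = trend_boundary(y) if boundary else mean_val
    return _domain_clip(out, indicator_id)


def impute_missing(panel: IndicatorPanel, policy: str = "default") -> IndicatorPanel:
    """Fill missing values per city/area/indicator series.

    policy:
      * ``mean``    — every gap becomes the series mean of observed values;
      * ``trend``   — boundary gaps are linearly extrapolated from the two
        nearest observed years, interior gaps linearly interpolated;
      * ``default`` — trend extrapolation at the boundaries, series mean in
        the interior;
      * ``none``    — no change.

    Imputed records get ``imputed=True``; entirely-missing series are left
    missing with a warning. Filled values are clipped to the indicator's
    domain (non-negative; proportions capped at 100).
    """
    if policy not in {"mean", "trend", "none", "default"}:
        raise ValueError(f"unknown imputation policy: {policy!r}")
    out = panel.copy()
    if policy == "none":
        return out
    df = out.data
    df.sort_values(["city_id", "area", "indicator", "year"], inplace=True)
    n_left = 0
    for _, idx in df.groupby(["city_id", "area", "indicator"], sort=False).groups.items():
        sub = df.loc[idx]
        vals = sub["value"].to_numpy()
        if not np.isnan(vals).any():
            continue
        if np.isnan(vals).all():
            n_left += 1
            continue
        filled = _fill_series(sub["year"].to_numpy(), vals, policy, sub["indicator"].iloc[0])
        newly = np.isnan(vals) & ~np.isnan(filled)
        df.loc[idx, "value"] = filled
        df.loc[idx[newly], "imputed"] = True
        df.loc[idx[newly], "missing"] = False
    if n_left:
        logger.warning("%d city/indicator series entirely missing; left as missing", n_left)
    df.reset_index(drop=True, inplace=True)
    return out


# -- packaged national aggregate tables -------------------------------------

@dataclass(frozen=True)
class NationalTables:
    """National urban and rural aggregates, 17 indicators x 2010-2016,
    stored exactly to printed precision."""

    urban: pd.DataFrame  # index indicator id, columns int years
    rural: pd.DataFrame

    def table(self, area: str) -> pd.DataFrame:
        if area not in AREAS:
            raise ValueError(f"unknown area {area!r}")
        return self.urban if area == "urban" else self.rural


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("carescape.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_fixture_tables() -> NationalTables:
    """Load the packaged national urban/rural aggregate tables."""
    df = _read_packaged("national_panel.csv")
    tabs = {}
    for area, sub in df.groupby("area"):
        t = sub.drop(columns="area").set_index("indicator")
        t.columns = t.columns.astype(int)
        tabs[area] = t.loc[list(INDICATOR_IDS)]
    return NationalTables(urban=tabs["urban"], rural=tabs["rural"])


def load_reference_time_ratios() -> pd.DataFrame:
    """Published base-2010 time-ratio table for the six quantity indicators,
    exactly as printed (index (area, indicator), columns years)."""
    df = _read_packaged("reference_time_ratios.csv").set_index(["area", "indicator"])
    df.columns = df.columns.astype(int)
    return df


def load_reference_proportion_diffs() -> pd.DataFrame:
    """Published urban-minus-rural percentage-point table for the 11
    proportional indicators, exactly as printed."""
    df = _read_packaged("reference_proportion_diffs.csv").set_index("indicator")
    df.columns = df.columns.astype(int)
    return df


def fixture_panel(region: str = "Eastern") -> IndicatorPanel:
    """The national aggregate tables recast as a one-unit panel (city 'CN'),
    useful for exercising the pipeline without city-level data."""
    tables = load_fixture_tables()
    rows = []
    for area in AREAS:
        tab = tables.table(area)
        for ind in tab.index:
            for year in tab.columns:
                rows.append(("CN", region, area, int(year), ind, float(tab.loc[ind, year])))
    return IndicatorPanel.from_dataframe(pd.DataFrame(rows, columns=PANEL_COLUMNS))


# -- city geometries --------------------------------------------------------

def read_city_geometry(path: str | Path) -> pd.DataFrame:
    """Read city centroids from GeoJSON points or a CSV (city_id, lon, lat[, region]).

    Returns a DataFrame with columns city_id, longitude, latitude and (when
    present) region, sorted by city_id.
    """
    path = Path(path)
    if path.suffix.lower() in {".geojson", ".json"}:
        payload = json.loads(path.read_text())
        rows = []
        for feat in payload.get("features", []):
            lon, lat = feat["geometry"]["coordinates"][:2]
            props = feat.get("properties", {})
            rows.append({"city_id": str(props["city_id"]),
                         "longitude": float(lon), "latitude": float(lat),
                         **({"region": props["region"]} if "region" in props else {})})
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, dtype={"city_id": str})
        df = df.rename(columns={"lon": "longitude", "lat": "latitude"})
    if df["city_id"].duplicated().any():
        raise PanelIntegrityError("duplicate city_id in geometry")
    if not np.isfinite(df[["longitude", "latitude"]].to_numpy()).all():
        raise ValueError("non-finite coordinates in geometry")
    return df.sort_values("city_id").reset_index(drop=True)


def write_city_geometry(geoms: pd.DataFrame, path: str | Path) -> None:
    """Write centroids as a GeoJSON FeatureCollection of points."""
    feats = []
    for _, row in geoms.iterrows():
        props = {"city_id": row["city_id"]}
        if "region" in geoms.columns:
            props["region"] = row["region"]
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [round(float(row["longitude"]), 6),
                                         round(float(row["latitude"]), 6)]},
            "properties": props,
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats},
                                     indent=1, sort_keys=True))
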