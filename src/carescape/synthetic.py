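"""Synthetic city panels with the structure the analysis assumes.

The generator emulates a 276-city, 2010-2016, urban/rural indicator panel:

* city centroids on a jittered grid in a China-like bounding box, labelled
  into four macro-regions with configurable counts (default 33/86/77/80 for
  Northeast/Eastern/Central/Western);
* a latent development level per city and area from a simultaneous
  autoregressive (SAR) field u = (I - rho*W)^(-1) eps plus an east-coast
  longitude gradient, giving positive spatial autocorrelation of composite
  scores and higher levels toward the east;
* quantity indicators that share out the national aggregate anchors
  (the packaged urban/rural tables' 2010 values) proportionally to
  exp(latent), with annual multiplicative trends defaulting to the anchored
  2010->2016 national ratios (urban growth, rural shrinkage) and lognormal
  measurement noise;
* proportional indicators as logistic-normal perturbations around the
  national year profiles, a mild latent effect on development-positive
  shares, clipped to [0, 100];
* missingness injected completely at random at a configurable rate.

Everything is deterministic given the config seed; the true latent levels
are returned for parameter-recovery checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import expit, logit

from .indicators import AREAS, PROPORTION_IDS, QUANTITY_IDS, REGIONS
from .io import IndicatorPanel, NationalTables, load_fixture_tables
from .spatial import SpatialWeights, build_knn_weights

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_city_map",
    "sar_field",
    "default_growth",
    "generate_panel",
]

logger = logging.getLogger("carescape.synthetic")

#: China-like study bounding box (degrees)
BBOX = (78.0, 130.0, 20.0, 52.0)  # lon_min, lon_max, lat_min, lat_max

#: proportional indicators that rise with the latent development level
DEVELOPMENT_POSITIVE = ("pct_university_educated", "pct_age_35_under",
                        "pct_self_financing")

from .indicators import INDICATORS as _INDICATORS  # noqa: E402

#: membership of the three-way proportional share groups (secondary level)
_by_group = {ind.id: ind.secondary for ind in _INDICATORS if ind.share is not None}


@dataclass
class SyntheticConfig:
    """Study conditions for the generator; the defaults are the conditions
    the packaged national tables anchor (276 cities, 2010-2016)."""

    seed: int
    n_cities: int = 276
    years: tuple[int, int] = (2010, 2016)
    rho: float = 0.6
    east_gradient: float = 0.5
    noise_sd: float = 1.0
    urban_growth: dict[str, float] | None = None
    rural_growth: dict[str, float] | None = None
    missing_rate: float = 0.05
    region_counts: tuple[int, int, int, int] = (33, 86, 77, 80)  # NE, E, C, W
    k_neighbors: int = 5
    share_spread: float = 0.8
    proportion_sd: float = 0.3
    latent_effect: float = 0.25
    measurement_sd: float = 0.15

    def validate(self) -> "SyntheticConfig":
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must lie in [0, 0.2]")
        if self.n_cities < 9:
            raise ValueError("need at least 9 cities")
        if self.noise_sd <= 0 or self.measurement_sd < 0 or self.proportion_sd < 0:
            raise ValueError("noise scales must be positive")
        if self.years[1] < self.years[0]:
            raise ValueError("years must be an increasing range")
        return self

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass
class SyntheticDataset:
    panel: IndicatorPanel
    geometry: pd.DataFrame = field(repr=False)
    truth: pd.DataFrame = field(repr=False)  # city_id, area, latent
    config: SyntheticConfig | None = None


def _region_counts(cfg: SyntheticConfig) -> dict[str, int]:
    base = np.array(cfg.region_counts, dtype=float)
    scaled = np.floor(base / base.sum() * cfg.n_cities).astype(int)
    scaled[scaled == 0] += 1  # every region represented
    while scaled.sum() < cfg.n_cities:
        scaled[int(np.argmax(base / base.sum() * cfg.n_cities - scaled))] += 1
    while scaled.sum() > cfg.n_cities:
        scaled[int(np.argmax(scaled))] -= 1
    return dict(zip(REGIONS, scaled.tolist()))


def generate_city_map(cfg: SyntheticConfig) -> pd.DataFrame:
    """Jittered-grid city centroids with stylized macro-region labels.

    Westernmost cities form the Western region; among the rest the highest
    latitudes form the Northeast, the easternmost of the remainder the
    Eastern region, and the rest the Central region — a deterministic,
    roughly geographic assignment that honours the configured counts.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    lon0, lon1, lat0, lat1 = BBOX
    aspect = (lon1 - lon0) / (lat1 - lat0)
    ncols = math.ceil(math.sqrt(cfg.n_cities * aspect))
    nrows = math.ceil(cfg.n_cities / ncols)
    xs = np.linspace(lon0, lon1, ncols, endpoint=False) + (lon1 - lon0) / ncols / 2
    ys = np.linspace(lat0, lat1, nrows, endpoint=False) + (lat1 - lat0) / nrows / 2
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])[:cfg.n_cities]
    jitter = rng.uniform(-0.4, 0.4, size=pts.shape)
    pts = pts + jitter * np.array([(lon1 - lon0) / ncols, (lat1 - lat0) / nrows])

    n = cfg.n_cities
    ids = [f"C{i:03d}" for i in range(1, n + 1)]
    df = pd.DataFrame({"city_id": ids, "longitude": pts[:, 0], "latitude": pts[:, 1]})

    counts = _region_counts(cfg)
    region = pd.Series(index=df.index, dtype=object)
    by_lon = df["longitude"].sort_values().index
    west = by_lon[:counts["Western"]]
    region[west] = "Western"
    rest = df.index.difference(west)
    ne = df.loc[rest, "latitude"].sort_values(ascending=False).index[:counts["Northeast"]]
    region[ne] = "Northeast"
    rest = rest.difference(ne)
    east = df.loc[rest, "longitude"].sort_values(ascending=False).index[:counts["Eastern"]]
    region[east] = "Eastern"
    region[rest.difference(east)] = "Central"
    df["region"] = region
    return df.sort_values("city_id").reset_index(drop=True)


def sar_field(W: SpatialWeights, rho: float, noise_sd: float,
              seed: int | None = None) -> np.ndarray:
    """Draw a simultaneous-autoregressive latent field u = (I - rho W)^(-1) eps
    with eps ~ N(0, noise_sd^2) i.i.d. Requires |rho| < 1 for row-standardized W."""
    if not -1 < rho < 1:
        raise ValueError("rho must lie strictly inside (-1, 1)")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=W.n)
    if rho == 0:
        return eps
    A = sp.identity(W.n, format="csc") - rho * W.matrix.tocsc()
    return spla.spsolve(A, eps)


def default_growth(area: str, tables: NationalTables | None = None) -> dict[str, float]:
    """Annual multiplicative trend per quantity indicator, anchored to the
    national 2010->2016 ratio: r = (v_2016 / v_2010)^(1/6). Urban trends are
    mostly > 1 (growth), rural mostly < 1 (shrinkage)."""
    tables = tables or load_fixture_tables()
    tab = tables.table(area)
    years = sorted(tab.columns)
    span = years[-1] - years[0]
    return {ind: float((tab.loc[ind, years[-1]] / tab.loc[ind, years[0]]) ** (1 / span))
            for ind in QUANTITY_IDS}


def generate_panel(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic panel plus geometry and latent truth."""
    cfg.validate()
    tables = load_fixture_tables()
    geoms = generate_city_map(cfg)
    W = build_knn_weights(geoms, k=cfg.k_neighbors, row_standardize=True)
    # W.ids order is city_id-sorted and geoms is too
    lon = geoms["longitude"].to_numpy()
    lon_std = (lon - lon.mean()) / lon.std()

    growth = {"urban": cfg.urban_growth or default_growth("urban", tables),
              "rural": cfg.rural_growth or default_growth("rural", tables)}
    years = cfg.year_list
    y0 = years[0]

    rows, truth_rows = [], []
    for a_idx, area in enumerate(AREAS):
        ss = np.random.SeedSequence([cfg.seed, 211, a_idx])
        child = ss.spawn(3)
        u = sar_field(W, cfg.rho, cfg.noise_sd, seed=child[0])
        latent = u + cfg.east_gradient * lon_std
        latent = (latent - latent.mean()) / latent.std()
        rng = np.random.default_rng(child[1])
        tab = tables.table(area)
        for city, lv, reg in zip(geoms["city_id"], latent, geoms["region"]):
            truth_rows.append((city, area, float(lv)))

        shares = np.exp(cfg.share_spread * latent)
        shares = shares / shares.sum()

        for ind in QUANTITY_IDS:
            anchor = float(tab.loc[ind, y0])
            r = growth[area][ind]
            for t, year in enumerate(years):
                noise = rng.lognormal(mean=-cfg.measurement_sd ** 2 / 2,
                                      sigma=cfg.measurement_sd, size=cfg.n_cities)
                if ind == "avg_days_in_care":
                    # a per-city mean, not a summable total
                    vals = anchor * (r ** t) * np.exp(0.15 * latent) * noise
                else:
                    vals = anchor * shares * (r ** t) * noise
                for city, reg, v in zip(geoms["city_id"], geoms["region"], vals):
                    rows.append((city, reg, area, year, ind, float(v)))

        prop_draws: dict[tuple[str, int], np.ndarray] = {}
        for ind in PROPORTION_IDS:
            gamma = cfg.latent_effect if ind in DEVELOPMENT_POSITIVE else 0.0
            for year in years:
                p_nat = float(tab.loc[ind, year]) / 100.0
                p_nat = min(max(p_nat, 1e-4), 1 - 1e-4)
                eta = logit(p_nat) + gamma * latent + rng.normal(0, cfg.proportion_sd,
                                                                 size=cfg.n_cities)
                prop_draws[(ind, year)] = np.clip(100.0 * expit(eta), 0.0, 100.0)
        # keep the three-way share groups coherent: scale any group summing
        # past 100 back onto the simplex (the yearbook groups never exceed it)
        groups: dict[str, list[str]] = {}
        for ind in PROPORTION_IDS:
            grp = _by_group.get(ind)
            if grp is not None:
                groups.setdefault(grp, []).append(ind)
        for year in years:
            for members in groups.values():
                stack = np.vstack([prop_draws[(m, year)] for m in members])
                total = stack.sum(axis=0)
                scale = np.where(total > 100.0, 100.0 / total, 1.0)
                for m, row in zip(members, stack * scale):
                    prop_draws[(m, year)] = row
        for (ind, year), vals in prop_draws.items():
            for city, reg, v in zip(geoms["city_id"], geoms["region"], vals):
                rows.append((city, reg, area, year, ind, float(v)))

    df = pd.DataFrame(rows, columns=["city_id", "region", "area", "year",
                                     "indicator", "value"])
    if cfg.missing_rate > 0:
        rng_m = np.random.default_rng(np.random.SeedSequence([cfg.seed, 307]))
        mask = rng_m.random(len(df)) < cfg.missing_rate
        df.loc[mask, "value"] = np.nan
        logger.info("injected %d missing values (MCAR, rate %.3f)",
                    int(mask.sum()), cfg.missing_rate)

    panel = IndicatorPanel.from_dataframe(df)
    truth = pd.DataFrame(truth_rows, columns=["city_id", "area", "latent"])
    return SyntheticDataset(panel=panel, geometry=geoms, truth=truth, config=cfg)
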