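"""End-to-end analysis: score -> compare -> spatial autocorrelation -> reports.

``run_full_analysis`` executes the whole measurement-and-inference chain on
either a supplied panel (+ geometry) or a synthetic dataset, and writes the
report bundle in the published table layouts:

* composite_scores.csv       — per city/area/year overall and subtree scores
* regional_bands.csv         — 20/60/20 regional shares, final year
* secondary_scores.csv       — mean primary-dimension scores, first/last year
* time_ratios.csv            — base-year ratios of the national quantity series
* proportion_diffs.csv       — urban-minus-rural percentage points per year
* global_moran.csv           — I, E[I], z, pseudo-p for area x {first, last} year
* lisa.csv                   — per-city local Moran, category, zero-flag
* lisa_counts.csv            — region x category counts per area/year
* manifest.json              — config echo, seed, versions, emitted files

Every stochastic step derives from the single run seed, so a fixed config
reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differences import (proportion_diff_table, regional_bands, round_display,
                          time_ratio_table, timeseries_ratio)
from .indicators import AREAS, PROPORTION_IDS, QUANTITY_IDS
from .io import (IndicatorPanel, NationalTables, impute_missing, read_city_geometry,
                 read_panel)
from .scoring import build_weight_scheme, composite_score, minmax_standardize
from .spatial import (build_knn_weights, classify_lisa, count_categories,
                      global_moran, impute_missing_zero, local_moran)
from .synthetic import SyntheticConfig, generate_panel

__all__ = ["RunConfig", "run_full_analysis", "compare_tables", "PipelineError"]

logger = logging.getLogger("carescape.pipeline")

REPORT_FILES = (
    "composite_scores.csv", "regional_bands.csv", "secondary_scores.csv",
    "time_ratios.csv", "proportion_diffs.csv", "global_moran.csv",
    "lisa.csv", "lisa_counts.csv",
)


class PipelineError(RuntimeError):
    """Raised with the failing stage named."""


@dataclass
class RunConfig:
    """Configuration of a full run; exactly one of (panel_path) or
    (synthetic) supplies the input data."""

    outdir: str
    seed: int
    panel_path: str | None = None
    geometry_path: str | None = None
    synthetic: SyntheticConfig | None = None
    pool: str = "all_years_both_areas"
    impute_policy: str = "default"
    knn_k: int = 5
    n_perm: int = 999
    alpha: float = 0.05
    spatial_years: tuple[int, int] | None = None  # default: first and last

    def validate(self) -> "RunConfig":
        if (self.panel_path is None) == (self.synthetic is None):
            raise ValueError("supply exactly one of panel_path or synthetic config")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        syn = payload.pop("synthetic", None)
        if syn is not None:
            if "seed" not in syn:
                syn["seed"] = payload.get("seed")
            for key in ("years", "region_counts"):
                if key in syn and isinstance(syn[key], list):
                    syn[key] = tuple(syn[key])
            syn = SyntheticConfig(**syn)
        if "spatial_years" in payload and isinstance(payload["spatial_years"], list):
            payload["spatial_years"] = tuple(payload["spatial_years"])
        return cls(synthetic=syn, **payload).validate()


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("load")
def _load(cfg: RunConfig):
    if cfg.synthetic is not None:
        ds = generate_panel(cfg.synthetic)
        return ds.panel, ds.geometry
    panel = read_panel(cfg.panel_path)
    geoms = read_city_geometry(cfg.geometry_path) if cfg.geometry_path else None
    return panel, geoms


@_stage("impute")
def _impute(panel: IndicatorPanel, cfg: RunConfig) -> IndicatorPanel:
    return impute_missing(panel, policy=cfg.impute_policy)


@_stage("score")
def _score(panel: IndicatorPanel, cfg: RunConfig):
    scheme = build_weight_scheme()
    std = minmax_standardize(panel, scheme, pool=cfg.pool)
    return composite_score(std, scheme, missing="propagate"), scheme


def _national_series(panel: IndicatorPanel) -> NationalTables:
    """Aggregate the city panel to national urban/rural tables: quantity
    indicators sum over cities (mean for the days-of-stay indicator),
    proportions average over cities."""
    df = panel.data
    tabs = {}
    for area in AREAS:
        sub = df[df["area"] == area]
        cells = {}
        for ind, g in sub.groupby("indicator"):
            agg = g.groupby("year")["value"]
            if ind in QUANTITY_IDS and ind != "avg_days_in_care":
                cells[ind] = agg.sum(min_count=1)
            else:
                cells[ind] = agg.mean()
        tabs[area] = pd.DataFrame(cells).T
    return NationalTables(urban=tabs["urban"], rural=tabs["rural"])


@_stage("differences")
def _differences(panel: IndicatorPanel):
    national = _national_series(panel)
    return time_ratio_table(national), proportion_diff_table(national)


@_stage("spatial")
def _spatial(scores, geoms, regions, cfg: RunConfig):
    years = sorted(scores.data["year"].unique())
    sp_years = cfg.spatial_years or (years[0], years[-1])
    W = build_knn_weights(geoms, k=cfg.knn_k, row_standardize=True)
    rng = np.random.default_rng(cfg.seed)
    moran_rows, lisa_frames, count_frames = [], [], []
    for area in AREAS:
        for year in sp_years:
            z = scores.series(area, year).reindex(W.ids)
            filled, flags = impute_missing_zero(z)
            seed_g, seed_l = int(rng.integers(2 ** 31)), int(rng.integers(2 ** 31))
            gm = global_moran(filled, W, n_perm=cfg.n_perm, seed=seed_g)
            lisa = local_moran(filled, W, n_perm=cfg.n_perm, seed=seed_l,
                               imputed_zero=flags.reindex(W.ids).to_numpy())
            lisa = classify_lisa(lisa, alpha=cfg.alpha)
            moran_rows.append({"area": area, "year": year, "I": gm.I,
                               "expected": gm.expected, "variance": gm.variance,
                               "z_score": gm.z_score, "pseudo_p": gm.pseudo_p,
                               "n_perm": gm.n_perm})
            lf = lisa.data.copy()
            lf.insert(0, "year", year)
            lf.insert(0, "area", area)
            lisa_frames.append(lf)
            ct = count_categories(lisa, regions).reset_index()
            ct.insert(0, "year", year)
            ct.insert(0, "area", area)
            count_frames.append(ct)
    return (pd.DataFrame(moran_rows), pd.concat(lisa_frames, ignore_index=True),
            pd.concat(count_frames, ignore_index=True))


def _secondary_table(scores, years) -> pd.DataFrame:
    """Mean primary-dimension scores by area for the first and last year
    (published comparison layout; values on the 0-100 scale)."""
    df = scores.data
    pri_cols = [c for c in df.columns if c.startswith("pri_")]
    rows = []
    for year in years:
        for area in AREAS:
            sub = df[(df["year"] == year) & (df["area"] == area)]
            rows.append({"year": year, "area": area,
                         **{c.removeprefix("pri_"): round_display(100 * sub[c].mean(), 2)
                            for c in pri_cols}})
    return pd.DataFrame(rows)


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    panel, geoms = _load(cfg)
    panel = _impute(panel, cfg)
    scores, scheme = _score(panel, cfg)
    t_table, p_table = _differences(panel)

    years = sorted(scores.data["year"].unique())
    regions = panel.regions()
    band_year = years[-1]
    band_frames = []
    for area in AREAS:
        s = scores.series(area, band_year)
        if len(s.dropna()) == 0:
            continue
        bands = regional_bands(s.dropna(), regions)
        tab = bands.shares.reset_index(names="band")
        tab.insert(0, "area", area)
        band_frames.append(tab)
    bands_table = pd.concat(band_frames, ignore_index=True)

    spatial_ok = geoms is not None and len(scores.data["city_id"].unique()) >= 3
    if spatial_ok:
        moran_table, lisa_table, counts_table = _spatial(scores, geoms, regions, cfg)
    else:
        logger.warning("spatial stage skipped: needs geometry and >= 3 cities")
        moran_table = pd.DataFrame(columns=["area", "year", "I", "expected",
                                            "variance", "z_score", "pseudo_p", "n_perm"])
        lisa_table = pd.DataFrame(columns=["area", "year", "city_id", "value", "z",
                                           "lag", "I", "p", "category", "imputed_zero"])
        counts_table = pd.DataFrame(columns=["area", "year", "region"])

    float_fmt = "%.10g"
    scores.data.to_csv(outdir / "composite_scores.csv", index=False, float_format=float_fmt)
    bands_table.to_csv(outdir / "regional_bands.csv", index=False, float_format="%.2f")
    _secondary_table(scores, (years[0], years[-1])).to_csv(
        outdir / "secondary_scores.csv", index=False, float_format="%.2f")
    t_table.to_csv(outdir / "time_ratios.csv", float_format="%.2f")
    p_table.to_csv(outdir / "proportion_diffs.csv", float_format="%.2f")
    moran_table.to_csv(outdir / "global_moran.csv", index=False, float_format=float_fmt)
    lisa_table.to_csv(outdir / "lisa.csv", index=False, float_format=float_fmt)
    counts_table.to_csv(outdir / "lisa_counts.csv", index=False)

    manifest = {
        "package": "carescape",
        "version": __version__,
        "seed": cfg.seed,
        "config": _jsonable(cfg),
        "reports": list(REPORT_FILES),
        "n_cities": int(scores.data["city_id"].nunique()),
        "years": [int(y) for y in years],
        "spatial_stage": bool(spatial_ok),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)

    def conv(v):
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v
    return conv(d)


def compare_tables(produced: pd.DataFrame, reference: pd.DataFrame,
                   dp: int = 2) -> pd.DataFrame:
    """Cell-level diff of two congruent tables after rounding to ``dp``.

    Returns a DataFrame (row, column, produced, reference); empty = pass.
    """
    if produced.shape != reference.shape:
        raise ValueError(f"shape mismatch: {produced.shape} vs {reference.shape}")
    prod = produced.copy()
    prod.index, prod.columns = reference.index, reference.columns
    diffs = []
    for idx in reference.index:
        for col in reference.columns:
            a = round_display(float(prod.loc[idx, col]), dp)
            b = round_display(float(reference.loc[idx, col]), dp)
            if not (np.isnan(a) and np.isnan(b)) and abs(a - b) > 10.0 ** -dp / 2:
                diffs.append({"row": idx, "column": col, "produced": a, "reference": b})
    return pd.DataFrame(diffs, columns=["row", "column", "produced", "reference"])
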