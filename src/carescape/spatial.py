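"""Spatial weights, global and local Moran's I, and LISA classification.

Global Moran's I for values x on n spatial units with weights W is

    I = (n / S0) * sum_ij W_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with S0 = sum_ij W_ij, expectation E[I] = -1/(n-1) under spatial randomness,
and variance taken under the randomization (permutation) assumption.
Significance is permutation-first: pseudo p-values are
(1 + #more-extreme permutations) / (1 + n_perm).

Local Moran's I decomposes the global statistic: I_i = z_i * sum_j W_ij z_j
where z uses the population (n-denominator) standard deviation, which makes
sum_i I_i = S0 * I hold exactly. Units with a significant I_i classify by the
quadrant of (z_i, spatial lag) into High-High / High-Low / Low-High / Low-Low;
the rest are insignificant. Cities whose composite score is unavailable are
assigned a score of zero before the analysis and flagged, so contiguous
zero-filled blocks (which surface as artificial Low-Low clusters) can be
excluded from interpretation downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .indicators import REGIONS

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "LisaResult",
    "build_knn_weights",
    "great_circle_km",
    "global_moran",
    "permutation_pseudo_p",
    "local_moran",
    "classify_lisa",
    "impute_missing_zero",
    "count_categories",
    "LISA_CATEGORIES",
]

logger = logging.getLogger("carescape.spatial")

LISA_CATEGORIES = ("insignificant", "high_high", "high_low", "low_high", "low_low")

EARTH_RADIUS_KM = 6371.0088


@dataclass
class SpatialWeights:
    """Sparse n x n spatial weight structure over an ordered city list."""

    ids: list[str]
    matrix: sp.csr_matrix = field(repr=False)
    row_standardized: bool = False

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def S0(self) -> float:
        return float(self.matrix.sum())

    def neighbors(self, i: int) -> np.ndarray:
        return self.matrix.indices[self.matrix.indptr[i]:self.matrix.indptr[i + 1]]

    def validate(self) -> "SpatialWeights":
        if self.matrix.diagonal().any():
            raise ValueError("spatial weights must have a zero diagonal")
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")
        if self.row_standardized:
            rows = np.asarray(self.matrix.sum(axis=1)).ravel()
            nonisland = np.diff(self.matrix.indptr) > 0
            if not np.allclose(rows[nonisland], 1.0, atol=1e-9):
                raise ValueError("row-standardized weights must have unit row sums")
        return self


def great_circle_km(lon, lat) -> np.ndarray:
    """Pairwise haversine distance matrix (km) for coordinate vectors."""
    lam, phi = np.radians(np.asarray(lon, float)), np.radians(np.asarray(lat, float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def build_knn_weights(geoms: pd.DataFrame, k: int = 5,
                      row_standardize: bool = True) -> SpatialWeights:
    """Binary k-nearest-neighbour weights on great-circle distance.

    ``geoms`` needs columns city_id, longitude, latitude; cities are ordered
    by city_id. Distance ties are broken by city order, guaranteeing a
    deterministic graph. k-NN graphs have no islands by construction.
    """
    geoms = geoms.sort_values("city_id").reset_index(drop=True)
    n = len(geoms)
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n (k={k}, n={n})")
    dist = great_circle_km(geoms["longitude"].to_numpy(), geoms["latitude"].to_numpy())
    off = ~np.eye(n, dtype=bool)
    if (dist[off] == 0).any():
        logger.warning("duplicate coordinates; nearest-neighbour ties broken by city order")
    rows, cols = [], []
    order_idx = np.arange(n)
    for i in range(n):
        # lexsort: distance first, city order second; drop self
        ranked = np.lexsort((order_idx, dist[i]))
        ranked = ranked[ranked != i][:k]
        rows.extend([i] * k)
        cols.extend(ranked.tolist())
    data = np.ones(len(rows))
    W = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    if row_standardize:
        inv = 1.0 / np.asarray(W.sum(axis=1)).ravel()
        W = sp.diags(inv) @ W
    return SpatialWeights(ids=geoms["city_id"].tolist(), matrix=W.tocsr(),
                          row_standardized=row_standardize).validate()


# -- global statistic -------------------------------------------------------

def _as_vector(x, W: SpatialWeights) -> np.ndarray:
    if isinstance(x, pd.Series):
        missing = [c for c in W.ids if c not in x.index]
        if missing:
            raise KeyError(f"values missing for cities: {missing[:5]}...")
        x = x.loc[W.ids].to_numpy()
    x = np.asarray(x, dtype=float)
    if len(x) != W.n:
        raise ValueError("value vector length does not match weights")
    if np.isnan(x).any():
        raise ValueError("NaN in values; apply impute_missing_zero first")
    return x


def _moran_stat(x: np.ndarray, W: SpatialWeights) -> float:
    z = x - x.mean()
    ss = float(z @ z)
    if ss == 0:
        raise ValueError("constant values: Moran's I undefined (zero variance)")
    return W.n / W.S0 * float(z @ (W.matrix @ z)) / ss


def _randomization_variance(x: np.ndarray, W: SpatialWeights) -> float:
    """Variance of I under random permutation of the observed values."""
    n = W.n
    M = W.matrix
    S0 = W.S0
    WT = M.T.tocsr()
    S1 = 0.5 * float((M + WT).power(2).sum())
    rc = np.asarray(M.sum(axis=1)).ravel() + np.asarray(M.sum(axis=0)).ravel()
    S2 = float((rc ** 2).sum())
    z = x - x.mean()
    m2 = float((z ** 2).sum()) / n
    m4 = float((z ** 4).sum()) / n
    b2 = m4 / m2 ** 2
    num = (n * ((n ** 2 - 3 * n + 3) * S1 - n * S2 + 3 * S0 ** 2)
           - b2 * ((n ** 2 - n) * S1 - 2 * n * S2 + 6 * S0 ** 2))
    den = (n - 1) * (n - 2) * (n - 3) * S0 ** 2
    EI = -1.0 / (n - 1)
    return num / den - EI ** 2


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z_score: float
    pseudo_p: float | None = None
    n_perm: int | None = None
    seed: int | None = None
    n: int = 0


def global_moran(x, W: SpatialWeights, n_perm: int | None = None,
                 seed: int | None = None,
                 alternative: str = "greater") -> MoranResult:
    """Global Moran's I with expectation, randomization variance, z-score and
    (when ``n_perm`` is given) a permutation pseudo p-value."""
    xv = _as_vector(x, W)
    n = W.n
    if n < 3:
        raise ValueError("global Moran's I needs at least 3 units")
    I = _moran_stat(xv, W)
    EI = -1.0 / (n - 1)
    var = _randomization_variance(xv, W)
    z = (I - EI) / np.sqrt(var) if var > 0 else np.nan
    result = MoranResult(I=I, expected=EI, variance=var, z_score=z, n=n)
    if n_perm is not None:
        result.pseudo_p = permutation_pseudo_p(xv, W, n_perm=n_perm, seed=seed,
                                               alternative=alternative)
        result.n_perm, result.seed = n_perm, seed
    return result


def permutation_pseudo_p(x, W: SpatialWeights, n_perm: int = 999,
                         seed: int | None = None,
                         alternative: str = "greater") -> float:
    """Permutation pseudo p-value for global Moran's I.

    ``greater`` counts permuted I >= observed; ``two_sided`` counts
    |permuted - E[I]| >= |observed - E[I]|. The attainable minimum is
    1/(n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    if alternative not in {"greater", "two_sided"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    xv = _as_vector(x, W)
    obs = _moran_stat(xv, W)
    rng = np.random.default_rng(seed)
    n = W.n
    X = rng.permuted(np.tile(xv, (n_perm, 1)), axis=1)
    Xc = X - X.mean(axis=1, keepdims=True)
    lag = (W.matrix @ Xc.T).T
    sims = n / W.S0 * (Xc * lag).sum(axis=1) / (Xc ** 2).sum(axis=1)
    if alternative == "greater":
        extreme = int((sims >= obs).sum())
    else:
        EI = -1.0 / (n - 1)
        extreme = int((np.abs(sims - EI) >= abs(obs - EI)).sum())
    return (extreme + 1) / (n_perm + 1)


# -- local statistic --------------------------------------------------------

@dataclass
class LisaResult:
    """Per-city local Moran's I with permutation inference.

    ``data`` columns: city_id, value, z, lag, I, p, category, imputed_zero.
    """

    data: pd.DataFrame = field(repr=False)
    alpha: float | None = None
    n_perm: int | None = None
    seed: int | None = None

    @property
    def I_sum(self) -> float:
        return float(self.data["I"].sum())


def _sample_without_replacement(rng: np.random.Generator, n_perm: int,
                                k: int, m: int) -> np.ndarray:
    """(n_perm, k) integer samples from range(m) without replacement per row,
    by rejection (k << m, so redraws are rare)."""
    idx = rng.integers(0, m, size=(n_perm, k))
    if k > 1:
        while True:
            s = np.sort(idx, axis=1)
            bad = (s[:, 1:] == s[:, :-1]).any(axis=1)
            if not bad.any():
                break
            idx[bad] = rng.integers(0, m, size=(int(bad.sum()), k))
    return idx


def local_moran(x, W: SpatialWeights, n_perm: int = 999,
                seed: int | None = None,
                imputed_zero: np.ndarray | None = None) -> LisaResult:
    """Local Moran's I per city with conditional-permutation pseudo p-values.

    z-scores use the population (n) denominator. For city i's p-value, the
    remaining n-1 values are randomly reassigned to its neighbour positions
    (value i held fixed); the one-sided count in the direction observed is
    folded so p always refers to the nearer tail.
    """
    xv = _as_vector(x, W)
    n = W.n
    if n < 3:
        raise ValueError("local Moran's I needs at least 3 units")
    sigma = xv.std(ddof=0)
    if sigma == 0:
        raise ValueError("constant values: local Moran's I undefined")
    z = (xv - xv.mean()) / sigma
    lag = W.matrix @ z
    Ii = z * lag

    rng = np.random.default_rng(seed)
    M = W.matrix
    p = np.ones(n)
    for i in range(n):
        lo, hi = M.indptr[i], M.indptr[i + 1]
        kcard = hi - lo
        if kcard == 0:  # island: lag 0, leave p = 1
            continue
        w_row = M.data[lo:hi]
        z_others = np.delete(z, i)
        idx = _sample_without_replacement(rng, n_perm, kcard, n - 1)
        sims = (z_others[idx] * w_row).sum(axis=1) * z[i]
        larger = int((sims >= Ii[i]).sum())
        p[i] = (min(larger, n_perm - larger) + 1) / (n_perm + 1)

    flags = (np.zeros(n, dtype=bool) if imputed_zero is None
             else np.asarray(imputed_zero, dtype=bool))
    df = pd.DataFrame({
        "city_id": W.ids, "value": xv, "z": z, "lag": lag, "I": Ii,
        "p": p, "category": "insignificant", "imputed_zero": flags,
    })
    return LisaResult(data=df, n_perm=n_perm, seed=seed)


def classify_lisa(lisa: LisaResult, alpha: float = 0.05) -> LisaResult:
    """Assign the five LISA categories from significance and the quadrant of
    (z, spatial lag). Non-significant cities (p >= alpha), islands, and
    boundary cases with z == 0 or lag == 0 are 'insignificant'."""
    df = lisa.data.copy()
    sig = df["p"] < alpha
    cat = np.full(len(df), "insignificant", dtype=object)
    zpos, lpos = df["z"] > 0, df["lag"] > 0
    zneg, lneg = df["z"] < 0, df["lag"] < 0
    cat[np.where(sig & zpos & lpos)] = "high_high"
    cat[np.where(sig & zpos & lneg)] = "high_low"
    cat[np.where(sig & zneg & lpos)] = "low_high"
    cat[np.where(sig & zneg & lneg)] = "low_low"
    df["category"] = cat
    return LisaResult(data=df, alpha=alpha, n_perm=lisa.n_perm, seed=lisa.seed)


def impute_missing_zero(x: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Replace missing scores by zero ahead of spatial analysis, returning the
    completed series and a boolean flag series (True = zero-assigned)."""
    flags = x.isna()
    if flags.all():
        logger.warning("all values missing; zero-assignment yields a constant field")
    elif flags.any():
        logger.warning("assigned zero to %d cities with missing scores", int(flags.sum()))
    return x.fillna(0.0), flags


def count_categories(lisa: LisaResult, regions: pd.Series) -> pd.DataFrame:
    """Region x LISA-category contingency counts (all cities, totals = n)."""
    df = lisa.data
    reg = df["city_id"].map(regions)
    tab = pd.crosstab(reg, df["category"]).reindex(
        index=list(REGIONS), columns=list(LISA_CATEGORIES), fill_value=0)
    tab.index.name = "region"
    return tab
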