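"""Per-cell driver attribution of inter-annual LAI dynamics.

For each grid cell the annual LAI series is regressed on up to ten candidate
predictors (water-related, energy-related, land-cover and annual-extreme
variables).  Because the predictors are collinear, no single OLS fit is
trusted: all 2^p predictor subsets are fitted, models within a small AIC
distance of the best one and with satisfactory adjusted R-squared form an
ensemble, each predictor's explained-variance share within a model is
computed by Lindeman-Merenda-Gold (LMG) partitioning, and shares are averaged
across the ensemble with Akaike weights.  The predictor with the largest
weighted share is the cell's dominant driver.

The all-subsets search and the LMG partition share one pass over subset
R-squared values: for a model with predictor set S, the LMG share of
predictor k is the average over all orderings of S of the sequential
R-squared increase when k enters, which reduces to a sum over subsets
T of S without k weighted by |T|!(|S|-|T|-1)!/|S|!.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import factorial
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "CANONICAL_PREDICTORS",
    "WATER_VARIABLES",
    "AttributionConfig",
    "ModelRecord",
    "AttributionCell",
    "normalize_predictors",
    "fit_all_subsets",
    "select_models",
    "akaike_weights",
    "lmg_importance",
    "attribute_cell",
    "attribute_grid",
]

# Canonical predictor set: annual means of water- and energy-related
# variables and land-cover fractions, plus the annual soil-moisture minimum
# and temperature maximum standing in for droughts and heat waves.
CANONICAL_PREDICTORS = (
    "soil_moisture",
    "precipitation",
    "vpd",
    "temperature",
    "net_radiation",
    "shortwave_radiation",
    "tree_cover",
    "crop_fraction",
    "soil_moisture_annual_min",
    "temperature_annual_max",
)

# Water variables used for the "highest-ranked water variable" map. Whether
# the annual soil-moisture minimum counts as a water variable is
# configurable; by default it does not.
WATER_VARIABLES = ("soil_moisture", "precipitation", "vpd")

STATUS_ATTRIBUTED = 0
STATUS_NO_MODEL = 1
STATUS_INSUFFICIENT = 2


class NormalizationError(ValueError):
    """A predictor column cannot be divide-by-max normalized."""


@dataclass(frozen=True)
class AttributionConfig:
    """Thresholds of the model-ensemble attribution.

    delta_aic
        Models whose AIC exceeds the best by at least this much are dropped
        (strict ``< delta_aic``).
    adjr2_min
        Minimum adjusted R-squared (strict ``>``) for a model to count as
        having satisfactory predictive power.
    use_aicc
        Rank by small-sample corrected AICc instead of AIC.
    tie_tol
        Two predictors whose weighted importances differ by less than this
        are reported as tied.
    renormalize_absent
        If True, a predictor's importance is averaged only over models that
        contain it (weights renormalized); default treats absence as zero
        importance.
    """

    delta_aic: float = 2.0
    adjr2_min: float = 0.36
    use_aicc: bool = False
    tie_tol: float = 1e-9
    water_variables: tuple[str, ...] = WATER_VARIABLES
    renormalize_absent: bool = False
    min_obs: int = 12
    max_predictors: int = 12


@dataclass
class ModelRecord:
    """One OLS subset fit."""

    predictors: tuple[str, ...]
    mask: int  # bitmask over the fitted predictor columns
    params: np.ndarray  # intercept followed by coefficients
    rss: float
    r2: float
    adj_r2: float
    aic: float
    delta_aic: float | None = None
    akaike_weight: float | None = None
    lmg: dict[str, float] | None = None


@dataclass
class NormalizedPredictors:
    """Divide-by-max normalized predictor matrix plus bookkeeping."""

    matrix: pd.DataFrame
    maxima: pd.Series
    dropped_constant: list[str]
    rejected_nonpositive: list[str]
    n_rows_dropped: int


@dataclass
class AttributionCell:
    """Attribution outcome for one grid cell."""

    status: int
    importance: dict[str, float] = field(default_factory=dict)
    dominant: str | None = None
    tie: bool = False
    ranking: tuple[str, ...] = ()
    water_rank: int | None = None
    best_adj_r2: float = np.nan
    n_models: int = 0


def normalize_per_cell(values: np.ndarray) -> np.ndarray:
    """Divide a (lat, lon, year) array by its per-cell maximum over years."""
    mx = np.nanmax(values, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = values / mx
    out[np.broadcast_to(mx <= 0, out.shape)] = np.nan
    return out


def normalize_predictors(raw: pd.DataFrame) -> NormalizedPredictors:
    """Normalize each predictor column to (0, 1] by dividing by its maximum.

    Rows with any missing value are dropped (listwise) before taking maxima.
    Columns whose maximum is not strictly positive cannot be mapped into
    (0, 1] by this scheme and are rejected with a diagnostic suggesting a
    unit shift (e.g. temperature in Kelvin rather than Celsius); constant
    columns are normalized to all-ones, flagged and dropped from the model
    search.
    """
    n0 = len(raw)
    kept = raw.dropna(axis=0, how="any")
    rejected = [c for c in kept.columns if not (kept[c].max() > 0)]
    if rejected:
        raise NormalizationError(
            f"predictor column(s) {rejected} have non-positive maxima and cannot "
            "be divide-by-max normalized to (0, 1]; convert units so values are "
            "positive (e.g. temperature in Kelvin)"
        )
    maxima = kept.max(axis=0)
    matrix = kept / maxima
    constant = [c for c in matrix.columns if matrix[c].nunique() <= 1]
    return NormalizedPredictors(
        matrix=matrix.drop(columns=constant),
        maxima=maxima,
        dropped_constant=constant,
        rejected_nonpositive=[],
        n_rows_dropped=n0 - len(kept),
    )


# ---------------------------------------------------------------------------
# All-subsets OLS via the Gram matrix

_TINY_RSS = 1e-30  # floor so exact fits keep a finite (very negative) AIC


@lru_cache(maxsize=32)
def _subset_index(p: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subsets of {0..p-1} grouped by size: (masks, column-index array).

    Column index 0 is the intercept; predictor j maps to column j+1.  Entry s
    of the returned list holds all size-s subsets as an (n_subsets, s+1)
    index array into the design's Gram matrix.
    """
    masks_by_size: list[list[int]] = [[] for _ in range(p + 1)]
    for mask in range(2**p):
        masks_by_size[bin(mask).count("1")].append(mask)
    out = []
    for size, masks in enumerate(masks_by_size):
        idx = np.zeros((len(masks), size + 1), dtype=np.intp)
        for row, mask in enumerate(masks):
            cols = [0] + [j + 1 for j in range(p) if mask >> j & 1]
            idx[row] = cols
        out.append((np.asarray(masks, dtype=np.int64), idx))
    return out


def _fit_subsets(y: np.ndarray, X: np.ndarray):
    """Fit all 2^p subsets (plus intercept) by batched Gram-matrix solves.

    Returns (r2, rss, ok, params) where r2/rss/ok are arrays indexed by the
    subset bitmask and params maps bitmask -> coefficient vector
    (intercept first).  Rank-deficient subsets are marked not ok.
    """
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    G = Z.T @ Z
    c = Z.T @ y
    yy = float(y @ y)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        raise ValueError("response has zero variance")

    r2 = np.full(2**p, np.nan)
    rss = np.full(2**p, np.nan)
    ok = np.zeros(2**p, dtype=bool)
    params: dict[int, np.ndarray] = {}
    for masks, idx in _subset_index(p):
        sub_G = G[idx[:, :, None], idx[:, None, :]]
        sub_c = c[idx]
        try:
            beta = np.linalg.solve(sub_G, sub_c[..., None])[..., 0]
            good = np.ones(len(masks), dtype=bool)
        except np.linalg.LinAlgError:
            beta = np.full_like(sub_c, np.nan)
            good = np.zeros(len(masks), dtype=bool)
            for row in range(len(masks)):
                try:
                    beta[row] = np.linalg.solve(sub_G[row], sub_c[row])
                    good[row] = True
                except np.linalg.LinAlgError:
                    pass
        res = yy - np.einsum("ij,ij->i", beta, sub_c)
        res = np.clip(res, 0.0, None)
        # guard against ill-conditioned solves slipping through
        good &= np.isfinite(res)
        for row, mask in enumerate(masks):
            if good[row]:
                params[int(mask)] = beta[row]
        rss[masks[good]] = res[good]
        r2[masks[good]] = 1.0 - res[good] / tss
        ok[masks[good]] = True
    return r2, rss, ok, params, tss


def _aic(n: int, rss: np.ndarray, k: np.ndarray, use_aicc: bool) -> np.ndarray:
    aic = n * np.log(np.maximum(rss, _TINY_RSS) / n) + 2 * k
    if use_aicc:
        with np.errstate(divide="ignore"):
            corr = 2.0 * k * (k + 1) / np.maximum(n - k - 1, 0)
        corr = np.where(n - k - 1 > 0, corr, np.inf)
        aic = aic + corr
    return aic


def fit_all_subsets(
    y: Sequence[float] | np.ndarray,
    X: pd.DataFrame,
    config: AttributionConfig | None = None,
) -> list[ModelRecord]:
    """Fit every predictor subset (including intercept-only), sorted by AIC.

    AIC = n ln(RSS/n) + 2k with k counting the intercept, the slope
    coefficients and the residual variance.  Rank-deficient subsets are
    skipped with their mask absent from the result.
    """
    config = config or AttributionConfig()
    y = np.asarray(y, dtype=float)
    n, p = len(y), X.shape[1]
    if n < config.min_obs:
        raise ValueError(f"need >= {config.min_obs} observations, got {n}")
    if p > config.max_predictors:
        raise ValueError(f"at most {config.max_predictors} predictors supported, got {p}")
    names = list(X.columns)
    r2, rss, ok, params, _ = _fit_subsets(y, X.to_numpy(dtype=float))

    records = []
    for mask in range(2**p):
        if not ok[mask]:
            continue
        preds = tuple(names[j] for j in range(p) if mask >> j & 1)
        npred = len(preds)
        k = npred + 2  # intercept + slopes + residual variance
        denom = n - npred - 1
        adj = 1.0 - (1.0 - r2[mask]) * (n - 1) / denom if denom > 0 else np.nan
        aic = float(_aic(n, np.array([rss[mask]]), np.array([k]), config.use_aicc)[0])
        records.append(
            ModelRecord(
                predictors=preds,
                mask=mask,
                params=params[mask],
                rss=float(rss[mask]),
                r2=float(r2[mask]),
                adj_r2=float(adj),
                aic=aic,
            )
        )
    records.sort(key=lambda r: (r.aic, r.mask))
    best = records[0].aic
    for rec in records:
        rec.delta_aic = rec.aic - best
    return records


def select_models(
    records: Sequence[ModelRecord],
    delta_aic: float = 2.0,
    adjr2_min: float = 0.36,
) -> list[ModelRecord]:
    """Ensemble selection: strict dAIC < delta_aic AND adjusted R2 > adjr2_min.

    Both inequalities are strict, so a model exactly at either boundary is
    excluded.  The result may be empty (no satisfactory model).
    """
    if not records:
        raise ValueError("empty record list")
    best = min(r.aic for r in records)
    return [
        r
        for r in records
        if (r.aic - best) < delta_aic and np.isfinite(r.adj_r2) and r.adj_r2 > adjr2_min
    ]


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Normalized evidence weights w_i = exp(-d_i/2) / sum_j exp(-d_j/2)."""
    aics = np.asarray(aics, dtype=float)
    if aics.size == 0:
        raise ValueError("empty AIC list")
    if not np.all(np.isfinite(aics)):
        raise ValueError("AIC values must be finite")
    rel = np.exp(-0.5 * (aics - aics.min()))
    return rel / rel.sum()


def _lmg_shares(r2_by_mask: np.ndarray, model_mask: int, p: int) -> dict[int, float]:
    """LMG shares (by predictor column index) for the model ``model_mask``.

    share(k) = sum over T subset of S\\{k} of |T|!(s-|T|-1)!/s! *
    (R2(T+k) - R2(T)); shares telescope to R2(S).
    """
    members = [j for j in range(p) if model_mask >> j & 1]
    s = len(members)
    weights = [factorial(t) * factorial(s - t - 1) / factorial(s) for t in range(s)]
    shares: dict[int, float] = {}
    for k in members:
        rest = model_mask & ~(1 << k)
        # iterate all submasks T of rest
        total = 0.0
        T = rest
        while True:
            size = bin(T).count("1")
            total += weights[size] * (r2_by_mask[T | (1 << k)] - r2_by_mask[T])
            if T == 0:
                break
            T = (T - 1) & rest
        shares[k] = total
    return shares


def lmg_importance(y: Sequence[float] | np.ndarray, X_subset: pd.DataFrame) -> dict[str, float]:
    """LMG explained-variance share per predictor of one model.

    Equal to the average over all orderings of the predictors of each one's
    sequential R-squared contribution; the shares sum to the model's full
    R-squared.
    """
    y = np.asarray(y, dtype=float)
    p = X_subset.shape[1]
    if p > 12:
        raise ValueError("LMG enumeration limited to 12 predictors")
    r2, _, ok, _, _ = _fit_subsets(y, X_subset.to_numpy(dtype=float))
    if not ok.all():
        raise np.linalg.LinAlgError("collinear predictor subset in LMG computation")
    names = list(X_subset.columns)
    shares = _lmg_shares(r2, 2**p - 1, p)
    return {names[j]: shares[j] for j in range(p)}


def attribute_cell(
    y: Sequence[float] | np.ndarray,
    X: pd.DataFrame,
    config: AttributionConfig | None = None,
) -> AttributionCell:
    """Full attribution for one cell: subset search, selection, LMG, weighting.

    ``X`` is the already-normalized predictor matrix.  Weighted importance of
    predictor k is the Akaike-weighted mean of its LMG share over the
    selected models (share zero where k is absent, unless
    ``renormalize_absent``).  If the selection reduces to a single
    one-predictor model, that predictor's importance is its R-squared and it
    is dominant by construction.
    """
    config = config or AttributionConfig()
    y = np.asarray(y, dtype=float)
    valid = np.isfinite(y) & np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    if valid.sum() < config.min_obs or X.shape[1] == 0:
        return AttributionCell(status=STATUS_INSUFFICIENT)
    y = y[valid]
    X = X.loc[valid]
    if np.ptp(y) == 0:
        return AttributionCell(status=STATUS_INSUFFICIENT)

    names = list(X.columns)
    p = len(names)
    r2_by_mask, rss, ok, params, _ = _fit_subsets(y, X.to_numpy(dtype=float))
    records = []
    n = len(y)
    for mask in range(2**p):
        if not ok[mask]:
            continue
        npred = bin(mask).count("1")
        denom = n - npred - 1
        adj = 1.0 - (1.0 - r2_by_mask[mask]) * (n - 1) / denom if denom > 0 else np.nan
        aic = float(
            _aic(n, np.array([rss[mask]]), np.array([npred + 2]), config.use_aicc)[0]
        )
        records.append(
            ModelRecord(
                predictors=tuple(names[j] for j in range(p) if mask >> j & 1),
                mask=mask,
                params=params[mask],
                rss=float(rss[mask]),
                r2=float(r2_by_mask[mask]),
                adj_r2=float(adj),
                aic=aic,
            )
        )
    records.sort(key=lambda r: (r.aic, r.mask))
    best_aic = records[0].aic
    for rec in records:
        rec.delta_aic = rec.aic - best_aic

    selected = select_models(records, config.delta_aic, config.adjr2_min)
    best_adj = max((r.adj_r2 for r in records if np.isfinite(r.adj_r2)), default=np.nan)
    if not selected:
        return AttributionCell(status=STATUS_NO_MODEL, best_adj_r2=best_adj)

    w = akaike_weights([r.aic for r in selected])
    importance = {name: 0.0 for name in names}
    present_weight = {name: 0.0 for name in names}
    for weight, rec in zip(w, selected):
        rec.akaike_weight = float(weight)
        shares = _lmg_shares(r2_by_mask, rec.mask, p)
        rec.lmg = {names[j]: float(v) for j, v in shares.items()}
        for j, v in shares.items():
            importance[names[j]] += weight * v
            present_weight[names[j]] += weight
    if config.renormalize_absent:
        importance = {
            k: (v / present_weight[k] if present_weight[k] > 0 else 0.0)
            for k, v in importance.items()
        }

    ranking = tuple(sorted(names, key=lambda k: (-importance[k], k)))
    top = importance[ranking[0]]
    tie = sum(1 for k in names if top - importance[k] <= config.tie_tol) >= 2
    water = [v for v in config.water_variables if v in names]
    water_rank = None
    if water:
        water_rank = 1 + min(ranking.index(v) for v in water)
    return AttributionCell(
        status=STATUS_ATTRIBUTED,
        importance=importance,
        dominant=ranking[0],
        tie=tie,
        ranking=ranking,
        water_rank=water_rank,
        best_adj_r2=max(r.adj_r2 for r in selected),
        n_models=len(selected),
    )


def attribute_grid(
    lai: xr.DataArray,
    drivers: Mapping[str, xr.DataArray],
    config: AttributionConfig | None = None,
    years: tuple[int, int] | None = None,
    focus_boxes: Sequence | None = None,
) -> tuple[xr.Dataset, pd.DataFrame]:
    """Cell-wise attribution over a grid plus dominant-driver area coverage.

    Returns a dataset with the dominant-predictor code (index into the
    driver name order, -1 where undefined), tie flag, water-variable rank,
    best adjusted R-squared and status, and a coverage table of the
    area-weighted share of attributed cells per dominant driver (overall and
    within each focus box).
    """
    from .grid import GridSpec, cos_lat_weights

    config = config or AttributionConfig()
    names = [n for n in CANONICAL_PREDICTORS if n in drivers]
    names += [n for n in drivers if n not in names]
    if years is not None:
        sel = {"year": slice(years[0], years[1])}
        lai = lai.sel(**sel)
        drivers = {k: v.sel(**sel) for k, v in drivers.items()}

    nlat, nlon = lai.sizes["lat"], lai.sizes["lon"]
    dominant = np.full((nlat, nlon), -1, dtype=np.int16)
    tie = np.zeros((nlat, nlon), dtype=bool)
    water_rank = np.full((nlat, nlon), np.nan)
    best_adj = np.full((nlat, nlon), np.nan)
    status = np.full((nlat, nlon), STATUS_INSUFFICIENT, dtype=np.int8)

    raw = np.stack([drivers[n].values for n in names], axis=-1)  # lat, lon, yr, p
    y_all = lai.values
    for i in range(nlat):
        for j in range(nlon):
            df = pd.DataFrame(raw[i, j], columns=names)
            try:
                norm = normalize_predictors(df)
            except NormalizationError:
                continue
            ysel = y_all[i, j][df.dropna(how="any").index.to_numpy()]
            cell = attribute_cell(ysel, norm.matrix, config)
            status[i, j] = cell.status
            best_adj[i, j] = cell.best_adj_r2
            if cell.status == STATUS_ATTRIBUTED:
                dominant[i, j] = names.index(cell.dominant)
                tie[i, j] = cell.tie
                water_rank[i, j] = cell.water_rank if cell.water_rank else np.nan

    ds = xr.Dataset(
        {
            "dominant": (("lat", "lon"), dominant),
            "tie": (("lat", "lon"), tie),
            "water_rank": (("lat", "lon"), water_rank),
            "best_adj_r2": (("lat", "lon"), best_adj),
            "status": (("lat", "lon"), status),
        },
        coords={"lat": lai["lat"].values, "lon": lai["lon"].values},
    )
    ds["dominant"].attrs["codes"] = " ".join(f"{i}:{n}" for i, n in enumerate(names))
    ds["status"].attrs["codes"] = "0:attributed 1:no_satisfactory_model 2:insufficient_data"

    w = cos_lat_weights(ds["lat"]).values[:, None] * np.ones((1, nlon))
    rows = []
    regions: list[tuple[str, np.ndarray]] = [("global", np.ones((nlat, nlon), bool))]
    gridspec = GridSpec(ds["lat"].values, ds["lon"].values, lai["year"].values)
    for b, box in enumerate(focus_boxes or []):
        regions.append((f"box_{b}", box.mask(gridspec)))
    for region, rmask in regions:
        attributed = (status == STATUS_ATTRIBUTED) & rmask
        denom = float((w * attributed).sum())
        for code, name in enumerate(names):
            sel = attributed & (dominant == code) & ~tie
            rows.append(
                {
                    "region": region,
                    "dominant": name,
                    "area_share": float((w * sel).sum()) / denom if denom else np.nan,
                }
            )
        rows.append(
            {
                "region": region,
                "dominant": "tie",
                "area_share": float((w * (attributed & tie)).sum()) / denom
                if denom
                else np.nan,
            }
        )
    return ds, pd.DataFrame(rows)
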