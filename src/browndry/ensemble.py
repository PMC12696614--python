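"""Across-ensemble summaries of per-member categorical maps.

Each Earth-system-model-like member produces its own greenness, drying and
dominant-driver maps; this module votes across members per cell: the most
frequent trend category (requiring data from at least five members), the
fraction of members simulating drying, and the modal dominant driver
(flagged when fewer than three members agree).  Ties (two or more categories
sharing the maximal count) are a distinct status from low agreement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "modal_trend_category",
    "drying_model_fraction",
    "modal_dominant_driver",
    "multimodel_mean_summary",
    "ENSEMBLE_STATUS",
]

ENSEMBLE_STATUS = {
    "ok": 0,
    "insufficient_models": 1,
    "tie": 2,
    "low_agreement": 3,
}


def _check_grids(maps: list[xr.DataArray]) -> None:
    if not maps:
        raise ValueError("need at least one member map")
    ref = maps[0]
    for m in maps[1:]:
        if m.sizes != ref.sizes or not np.array_equal(m["lat"], ref["lat"]) or not np.array_equal(m["lon"], ref["lon"]):
            raise ValueError("ensemble member maps are on inconsistent grids")


def _vote(stack: np.ndarray, has_data: np.ndarray):
    """Per-cell modal category, modal count and tie flag.

    ``stack`` is (member, lat, lon) of integer codes with negative codes
    meaning no data for that member.
    """
    nlat, nlon = stack.shape[1:]
    modal = np.full((nlat, nlon), -1, dtype=np.int16)
    modal_count = np.zeros((nlat, nlon), dtype=np.int16)
    tie = np.zeros((nlat, nlon), dtype=bool)
    for i in range(nlat):
        for j in range(nlon):
            cell = stack[:, i, j]
            cell = cell[has_data[:, i, j]]
            if cell.size == 0:
                continue
            codes, counts = np.unique(cell, return_counts=True)
            top = counts.max()
            winners = codes[counts == top]
            modal[i, j] = winners.min()  # deterministic representative
            modal_count[i, j] = top
            tie[i, j] = winners.size >= 2
    return modal, modal_count, tie


def modal_trend_category(
    per_model: list[xr.DataArray],
    min_models: int = 5,
    no_data_code: int = 0,
) -> xr.Dataset:
    """Most frequent greenness category across members, per cell.

    A member provides data at a cell when its category differs from
    ``no_data_code`` (the masked code).  Cells with data from fewer than
    ``min_models`` members get status ``insufficient_models``; equal maximal
    counts get status ``tie``.
    """
    _check_grids(per_model)
    stack = np.stack([m.values for m in per_model]).astype(np.int16)
    has_data = stack != no_data_code
    n_models = has_data.sum(axis=0).astype(np.int16)
    modal, modal_count, tie = _vote(stack, has_data)

    status = np.where(
        n_models < min_models,
        ENSEMBLE_STATUS["insufficient_models"],
        np.where(tie, ENSEMBLE_STATUS["tie"], ENSEMBLE_STATUS["ok"]),
    ).astype(np.int8)
    ds = xr.Dataset(
        {
            "n_models": (("lat", "lon"), n_models),
            "modal_category": (("lat", "lon"), np.where(status == ENSEMBLE_STATUS["ok"], modal, -1).astype(np.int16)),
            "modal_count": (("lat", "lon"), modal_count),
            "status": (("lat", "lon"), status),
        },
        coords={"lat": per_model[0]["lat"].values, "lon": per_model[0]["lon"].values},
        attrs={"min_models": min_models},
    )
    ds["status"].attrs["codes"] = " ".join(f"{v}:{k}" for k, v in ENSEMBLE_STATUS.items())
    return ds


def drying_model_fraction(per_model: list[xr.Dataset]) -> xr.DataArray:
    """Fraction of members (with data) simulating drying at each cell."""
    flags = [m["drying"] if isinstance(m, xr.Dataset) else m for m in per_model]
    _check_grids(flags)
    valid = [
        m["valid"] if isinstance(m, xr.Dataset) and "valid" in m else xr.ones_like(f, dtype=bool)
        for m, f in zip(per_model, flags)
    ]
    n_data = sum(v.astype(np.int16) for v in valid)
    n_dry = sum((f & v).astype(np.int16) for f, v in zip(flags, valid))
    frac = (n_dry / n_data.where(n_data > 0)).rename("drying_model_fraction")
    frac.attrs["n_members"] = len(flags)
    return frac


def modal_dominant_driver(
    per_model: list[xr.DataArray],
    min_agree: int = 3,
) -> xr.Dataset:
    """Modal dominant-driver code across members, per cell.

    A member provides data where its dominant code is non-negative.  If the
    winning count is below ``min_agree`` the status is ``low_agreement``
    (taking precedence over a tie at such low counts); equal maximal counts
    at or above ``min_agree`` are a ``tie``.
    """
    _check_grids(per_model)
    stack = np.stack([m.values for m in per_model]).astype(np.int16)
    has_data = stack >= 0
    n_models = has_data.sum(axis=0).astype(np.int16)
    modal, modal_count, tie = _vote(stack, has_data)

    status = np.where(
        n_models == 0,
        ENSEMBLE_STATUS["insufficient_models"],
        np.where(
            modal_count < min_agree,
            ENSEMBLE_STATUS["low_agreement"],
            np.where(tie, ENSEMBLE_STATUS["tie"], ENSEMBLE_STATUS["ok"]),
        ),
    ).astype(np.int8)
    ds = xr.Dataset(
        {
            "n_models": (("lat", "lon"), n_models),
            "modal_driver": (("lat", "lon"), np.where(status == ENSEMBLE_STATUS["ok"], modal, -1).astype(np.int16)),
            "modal_count": (("lat", "lon"), modal_count),
            "status": (("lat", "lon"), status),
        },
        coords={"lat": per_model[0]["lat"].values, "lon": per_model[0]["lon"].values},
        attrs={"min_agree": min_agree},
    )
    ds["status"].attrs["codes"] = " ".join(f"{v}:{k}" for k, v in ENSEMBLE_STATUS.items())
    return ds


def multimodel_mean_summary(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise mean of per-member browning-by-drying area tables."""
    if not tables:
        raise ValueError("need at least one table")
    ref = tables[0]
    for t in tables[1:]:
        if not t.index.equals(ref.index) or list(t.columns) != list(ref.columns):
            raise ValueError("tables do not share the same class structure")
    return sum(tables) / len(tables)
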