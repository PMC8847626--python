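"""Gridded retention fractions from fitted site-level regressions.

Two wirings of the site regressions onto the predictor rasters are
offered:

``chained`` (default)
    The allocation chain: predict the ecosystem loss fraction and the
    organic-layer retention directly, split what remains between plants
    and mineral soil with the predicted plant:(plant+mineral) ratio,
    and take the woody sub-share of the plant term from the predicted
    woody share.  Sum-to-100 holds by construction.

``regression``
    Predict each pool fraction (plant, organic, mineral, loss) from its
    own selected model, clip to [0, 100] and renormalize the four to
    sum 100 proportionally.

Both produce a per-form retention map set with layers
``frac_plant/frac_wood/frac_org/frac_min/frac_loss`` in percent, plus
an extrapolation mask flagging cells outside the predictor hull of the
fitting sites.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .massbalance import TracerForm
from .retention import (
    CANDIDATE_PREDICTORS,
    RegressionFit,
    select_best,
)

__all__ = [
    "CHAINED_RESPONSES",
    "REGRESSION_RESPONSES",
    "forest_mask",
    "fit_retention_models",
    "chained_allocation",
    "predict_fractions_chained",
    "predict_fractions_regression",
    "predict_fractions",
    "extrapolation_mask",
]

#: Responses fitted in chained mode (the allocation chain).
CHAINED_RESPONSES = ("loss", "rec_org", "plant_ratio", "rec_wood_share")
#: Responses fitted in regression (per-pool) mode.
REGRESSION_RESPONSES = ("rec_plant", "rec_org", "rec_min", "loss", "rec_wood_share")

FRACTION_LAYERS = ("frac_plant", "frac_wood", "frac_org", "frac_min", "frac_loss")

#: Forest definition: canopy-cover fraction above this threshold.  The
#: headline analysis uses 0.2; a 0.1 variant is used for sink mapping.
DEFAULT_FOREST_THRESHOLD = 0.2


def forest_mask(world: xr.Dataset, threshold: float = DEFAULT_FOREST_THRESHOLD) -> xr.DataArray:
    """Boolean forest mask: cover strictly greater than ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"forest threshold must lie in [0, 1], got {threshold}")
    if "forest_cover" not in world:
        raise KeyError("world has no forest_cover layer")
    mask = world["forest_cover"] > threshold
    mask.attrs["threshold"] = threshold
    return mask


def fit_retention_models(
    site_table: pd.DataFrame,
    form: str | TracerForm,
    mode: str = "chained",
    candidates=CANDIDATE_PREDICTORS,
    vif_cutoff: float = 3.0,
) -> dict[str, RegressionFit]:
    """Select the best subset model for every response of one mode.

    ``site_table`` is the long-format table (one row per site and form);
    only the rows of ``form`` are used.  Returns response -> winning
    :class:`RegressionFit`.
    """
    form = TracerForm(form).value
    sub = site_table[site_table["form"] == form]
    if sub.empty:
        raise ValueError(f"no rows for form {form!r}")
    responses = CHAINED_RESPONSES if mode == "chained" else REGRESSION_RESPONSES
    models = {}
    for resp in responses:
        best, _ = select_best(sub, resp, candidates, vif_cutoff=vif_cutoff)
        models[resp] = best
    return models


def chained_allocation(loss_pct, org_pct, plant_ratio, wood_share):
    """Allocate the tracer budget given the chain's four quantities.

    All arguments broadcast; ``plant_ratio`` and ``wood_share`` are
    fractions in [0, 1], the others percent.  Where clipped loss + org
    exceeds 100 the pair is rescaled to sum 100 (warning) and nothing
    remains for plants or mineral soil.

    Returns ``(plant, mineral, wood, loss, org)`` in percent, summing
    (plant + mineral + org + loss) to exactly 100.
    """
    loss = np.clip(np.asarray(loss_pct, dtype=float), 0.0, 100.0)
    org = np.clip(np.asarray(org_pct, dtype=float), 0.0, 100.0)
    ratio = np.clip(np.asarray(plant_ratio, dtype=float), 0.0, 1.0)
    share = np.clip(np.asarray(wood_share, dtype=float), 0.0, 1.0)
    tot = loss + org
    over = tot > 100.0
    if np.any(over):
        warnings.warn(
            f"{int(np.count_nonzero(over))} cell(s) with loss + organic "
            "predictions above 100%; rescaled, nothing allocated to "
            "plant/mineral there",
            stacklevel=2,
        )
        scale = np.where(over, 100.0 / np.where(tot > 0, tot, 1.0), 1.0)
        loss = loss * scale
        org = org * scale
    available = np.maximum(100.0 - loss - org, 0.0)
    plant = ratio * available
    mineral = (1.0 - ratio) * available
    wood = share * plant
    return plant, mineral, wood, loss, org


def _predict_layer(fit: RegressionFit, world: xr.Dataset) -> xr.DataArray:
    missing = [p for p in fit.predictors if p not in world]
    if missing:
        raise KeyError(f"world is missing predictor layer(s) {missing}")
    out = fit.predict(world)
    if not isinstance(out, xr.DataArray):
        # intercept-only models predict a scalar; broadcast to the grid
        arr = np.broadcast_to(
            np.asarray(out, dtype=float), (world.sizes["lat"], world.sizes["lon"])
        )
        out = xr.DataArray(arr.copy(), dims=("lat", "lon"))
    return out


def _as_mapset(form, plant, wood, org, mineral, loss) -> xr.Dataset:
    layers = {
        "frac_plant": plant,
        "frac_wood": wood,
        "frac_org": org,
        "frac_min": mineral,
        "frac_loss": loss,
    }
    ds = xr.Dataset(
        {
            name: arr
            if isinstance(arr, xr.DataArray)
            else xr.DataArray(np.asarray(arr, dtype=float), dims=("lat", "lon"))
            for name, arr in layers.items()
        }
    )
    for v in ds.data_vars:
        ds[v].attrs["units"] = "%"
    ds.attrs["form"] = TracerForm(form).value
    return ds


def predict_fractions_chained(
    models: dict[str, RegressionFit], world: xr.Dataset, form: str | TracerForm
) -> xr.Dataset:
    """Retention map set via the allocation chain."""
    missing = [r for r in CHAINED_RESPONSES if r not in models]
    if missing:
        raise KeyError(f"chained mode needs models for {missing}")
    loss = _predict_layer(models["loss"], world)
    org = _predict_layer(models["rec_org"], world)
    ratio = _predict_layer(models["plant_ratio"], world)
    share = _predict_layer(models["rec_wood_share"], world) / 100.0
    plant, mineral, wood, loss, org = chained_allocation(loss, org, ratio, share)
    return _as_mapset(form, plant, wood, org, mineral, loss)


def predict_fractions_regression(
    models: dict[str, RegressionFit], world: xr.Dataset, form: str | TracerForm
) -> xr.Dataset:
    """Retention map set via independent per-pool regressions.

    Pool predictions are clipped to [0, 100] and the four budget terms
    proportionally renormalized to sum 100; cells where every term is
    zero are assigned 100% loss.  The woody fraction is the predicted
    woody share applied to the plant fraction, capped at it.
    """
    missing = [r for r in REGRESSION_RESPONSES if r not in models]
    if missing:
        raise KeyError(f"regression mode needs models for {missing}")
    raw = {
        r: np.clip(_predict_layer(models[r], world), 0.0, 100.0)
        for r in ("rec_plant", "rec_org", "rec_min", "loss")
    }
    total = raw["rec_plant"] + raw["rec_org"] + raw["rec_min"] + raw["loss"]
    scale = xr.where(total > 0, 100.0 / total, 0.0)
    plant = raw["rec_plant"] * scale
    org = raw["rec_org"] * scale
    mineral = raw["rec_min"] * scale
    loss = xr.where(total > 0, raw["loss"] * scale, 100.0)
    share = np.clip(_predict_layer(models["rec_wood_share"], world), 0.0, 100.0)
    wood = np.minimum(share * plant / 100.0, plant)
    return _as_mapset(form, plant, wood, org, mineral, loss)


def predict_fractions(
    models: dict[str, RegressionFit],
    world: xr.Dataset,
    form: str | TracerForm,
    mode: str = "chained",
) -> xr.Dataset:
    if mode == "chained":
        return predict_fractions_chained(models, world, form)
    if mode == "regression":
        return predict_fractions_regression(models, world, form)
    raise ValueError(f"unknown upscale mode {mode!r}")


def extrapolation_mask(
    models: dict[str, RegressionFit],
    world: xr.Dataset,
    site_table: pd.DataFrame,
) -> xr.DataArray:
    """Cells where any predictor used by any model leaves the site hull.

    The hull is the per-predictor [min, max] across the fitting sites;
    predictions there are extrapolations and are flagged, not blocked.
    """
    used = sorted({p for m in models.values() for p in m.predictors})
    flagged = None
    for p in used:
        lo, hi = site_table[p].min(), site_table[p].max()
        out = (world[p] < lo) | (world[p] > hi)
        flagged = out if flagged is None else (flagged | out)
    if flagged is None:
        flagged = xr.zeros_like(world["forest_cover"], dtype=bool)
    flagged.name = "extrapolation"
    flagged.attrs["long_name"] = "predictor outside the site-table range"
    return flagged
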