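"""Synthetic site tables and gridded worlds for the upscaling pipeline.

The generator emulates the statistical structure the analysis assumes,
so every downstream stage (regression selection, upscaling, carbon-sink
scaling, Monte Carlo) can be exercised without any external data
product.

Site tables
-----------
Thirteen paired-labelling sites by default, each with nine environmental
predictors drawn uniformly from realistic forest ranges (MAP 700–2500
mm, MAT 3–22 °C, N deposition 6–54 kg N ha⁻¹ yr⁻¹, ...).  Per tracer
form the four fractions are generated from linear relations plus
Gaussian noise and back-computed into pool recoveries that sum to 100:

* ecosystem loss declines with mineral-soil C/N,
* organic-layer retention rises with organic-layer mass,
* the plant share of (plant + mineral soil) declines with NPP,
* the woody share of plant retention rises with woody biomass,

with form offsets making nitrate more plant-bound and ammonium more
soil-bound, as the tracer experiments show.

Worlds
------
Coarse, spatially autocorrelated raster stacks (smoothed Gaussian noise
rescaled into the site predictor ranges) with a forest-cover fraction,
an ensemble of NHₓ/NO_y deposition maps, wood/organic/mineral C/N
layers, per-cell spherical areas, and latitude-band biome labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .massbalance import TracerForm
from .retention import CANDIDATE_PREDICTORS

__all__ = [
    "SiteGeneratorConfig",
    "WorldGeneratorConfig",
    "make_site_table",
    "make_world",
    "cell_area_ha",
    "biome_of_lat",
    "BIOME_NAMES",
]

EARTH_RADIUS_KM = 6371.0

#: Latitude-band biome classes used for aggregate reporting.
BIOME_NAMES = ("tropical", "temperate", "boreal")
_TROPICAL_LAT = 23.5
_BOREAL_LAT = 50.0

#: Uniform sampling ranges for the nine site predictors.
DEFAULT_PREDICTOR_RANGES: dict[str, tuple[float, float]] = {
    "mat": (3.0, 22.0),          # °C
    "map": (700.0, 2500.0),      # mm yr⁻¹
    "soil_cn": (10.0, 25.0),     # mineral soil 0–30 cm, mass ratio
    "clay": (5.0, 45.0),         # %
    "leaf_cn": (20.0, 50.0),     # mass ratio
    "n_dep": (6.0, 54.0),        # kg N ha⁻¹ yr⁻¹
    "org_mass": (10.0, 80.0),    # Mg ha⁻¹
    "wood_biomass": (50.0, 350.0),  # Mg ha⁻¹
    "npp": (400.0, 1400.0),      # g C m⁻² yr⁻¹
}


@dataclass(frozen=True)
class Relation:
    """One generative linear relation ``response = intercept + slope·x + ε``."""

    predictor: str
    intercept: float
    slope: float
    noise_sd: float

    def mean(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _default_relations() -> dict[str, Relation]:
    # Centred so that at mid-range predictors the ammonium means are
    # loss 31, organic 33, plant 12, mineral 24 (recoveries in percent)
    # and the woody share of plant spans roughly 20–60%.
    return {
        "loss": Relation("soil_cn", 57.25, -1.5, 7.0),
        "rec_org": Relation("org_mass", 17.25, 0.35, 4.5),
        "plant_ratio": Relation("npp", 0.648, -3.5e-4, 0.075),
        "rec_wood_share": Relation("wood_biomass", 16.0, 0.12, 4.2),
    }


def _default_form_offsets() -> dict[str, dict[str, float]]:
    # Additive response offsets per tracer form: nitrate reaches plants
    # more (higher plant ratio, slightly higher loss), ammonium is held
    # in the organic layer more.
    return {
        TracerForm.ammonium.value: {
            "loss": 0.0,
            "rec_org": 0.0,
            "plant_ratio": 0.0,
            "rec_wood_share": 0.0,
        },
        TracerForm.nitrate.value: {
            "loss": 2.0,
            "rec_org": -8.0,
            "plant_ratio": 0.155,
            "rec_wood_share": 0.0,
        },
    }


@dataclass
class SiteGeneratorConfig:
    """Configuration of the site-table generator."""

    n_sites: int = 13
    relations: dict[str, Relation] = field(default_factory=_default_relations)
    form_offsets: dict[str, dict[str, float]] = field(
        default_factory=_default_form_offsets
    )
    predictor_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PREDICTOR_RANGES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 5:
            raise ValueError("n_sites must be >= 5")
        for name, rel in self.relations.items():
            if rel.noise_sd < 0:
                raise ValueError(f"relation {name!r}: noise_sd must be >= 0")
            if rel.predictor not in self.predictor_ranges:
                raise ValueError(
                    f"relation {name!r} uses unknown predictor {rel.predictor!r}"
                )
        for name, (lo, hi) in self.predictor_ranges.items():
            if not hi > lo:
                raise ValueError(f"degenerate range for predictor {name!r}")


def make_site_table(cfg: SiteGeneratorConfig | None = None) -> pd.DataFrame:
    """Generate the long-format site table, one row per (site, form).

    Columns: ``site_id``, ``biome``, ``form``, the nine predictors, and
    the responses ``rec_plant``, ``rec_wood_share`` (% of plant
    retention), ``rec_org``, ``rec_min``, ``loss`` (all percent of the
    added tracer).  Per row the four fractions satisfy
    ``rec_plant + rec_org + rec_min + loss == 100``.
    """
    cfg = cfg or SiteGeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    preds = {
        name: rng.uniform(lo, hi, cfg.n_sites)
        for name, (lo, hi) in cfg.predictor_ranges.items()
    }
    mat = preds["mat"]
    biome = np.where(mat >= 17.0, "tropical", np.where(mat >= 10.0, "subtropical", "temperate"))

    rows = []
    for form in (TracerForm.ammonium.value, TracerForm.nitrate.value):
        offs = cfg.form_offsets[form]
        resp = {}
        for name, rel in cfg.relations.items():
            x = preds[rel.predictor]
            resp[name] = (
                rel.mean(x)
                + offs.get(name, 0.0)
                + rng.normal(0.0, rel.noise_sd, cfg.n_sites)
            )
        loss = np.clip(resp["loss"], 0.0, 100.0)
        org = np.clip(resp["rec_org"], 0.0, 100.0)
        # where loss + org would exceed 100, rescale both so they share it
        tot = loss + org
        over = tot > 100.0
        scale = np.where(over, 100.0 / np.where(tot > 0, tot, 1.0), 1.0)
        loss, org = loss * scale, org * scale
        ratio = np.clip(resp["plant_ratio"], 0.0, 1.0)
        wood_share = np.clip(resp["rec_wood_share"], 0.0, 100.0)
        available = 100.0 - loss - org
        plant = ratio * available
        mineral = (1.0 - ratio) * available
        frame = pd.DataFrame(
            {
                "site_id": [f"S{i:02d}" for i in range(cfg.n_sites)],
                "biome": biome,
                "form": form,
                **{k: v for k, v in preds.items()},
                "rec_plant": plant,
                "rec_wood_share": wood_share,
                "rec_org": org,
                "rec_min": mineral,
                "loss": loss,
            }
        )
        rows.append(frame)
    table = pd.concat(rows, ignore_index=True)
    # plant share of plant + mineral soil, the chained-allocation response
    denom = table["rec_plant"] + table["rec_min"]
    table["plant_ratio"] = np.where(denom > 0, table["rec_plant"] / denom, 0.0)
    return table


@dataclass
class WorldGeneratorConfig:
    """Configuration of the coarse synthetic world generator."""

    nx: int = 36
    ny: int = 18
    lat_span: tuple[float, float] = (-60.0, 70.0)
    lon_span: tuple[float, float] = (-180.0, 180.0)
    n_deposition_maps: int = 4
    n_wood_cn_sets: int = 6
    forest_cover_range: tuple[float, float] = (0.0, 1.0)
    predictor_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PREDICTOR_RANGES)
    )
    smooth_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nx < 4 or self.ny < 4:
            raise ValueError("grid must be at least 4 x 4")
        if self.n_deposition_maps < 1 or self.n_wood_cn_sets < 1:
            raise ValueError("ensemble axis counts must be >= 1")
        lo, hi = self.forest_cover_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("forest_cover_range must lie within [0, 1]")
        if not self.lat_span[1] > self.lat_span[0]:
            raise ValueError("degenerate latitude span")


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Spatially autocorrelated field rescaled to [0, 1]."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    lo, hi = z.min(), z.max()
    if hi == lo:
        return np.full(shape, 0.5)
    return (z - lo) / (hi - lo)


def cell_area_ha(lat_edges: np.ndarray, lon_edges: np.ndarray) -> np.ndarray:
    """Spherical cell areas in hectares for a regular lat/lon grid.

    For a band between latitudes φ₁ < φ₂ and a longitude width Δλ the
    area is R²·Δλ·(sin φ₂ − sin φ₁); 1 km² = 100 ha.
    """
    lat_edges = np.radians(np.asarray(lat_edges, dtype=float))
    lon_edges = np.radians(np.asarray(lon_edges, dtype=float))
    band = np.sin(lat_edges[1:]) - np.sin(lat_edges[:-1])        # (ny,)
    width = np.diff(lon_edges)                                    # (nx,)
    km2 = EARTH_RADIUS_KM**2 * band[:, None] * width[None, :]
    return km2 * 100.0


def biome_of_lat(lat: np.ndarray) -> np.ndarray:
    """Latitude-band biome index: 0 tropical, 1 temperate, 2 boreal."""
    alat = np.abs(np.asarray(lat, dtype=float))
    return np.where(alat < _TROPICAL_LAT, 0, np.where(alat < _BOREAL_LAT, 1, 2)).astype(
        np.int32
    )


def make_world(cfg: WorldGeneratorConfig | None = None) -> xr.Dataset:
    """Generate the co-registered synthetic raster stack.

    Returns an :class:`xarray.Dataset` with dimensions ``(lat, lon)``
    plus a ``model`` axis for the deposition ensemble and a ``cn_set``
    axis for the wood C/N sets:

    * one layer per predictor, within the configured ranges;
    * ``forest_cover`` fraction in [0, 1];
    * ``nhx_dep``/``noy_dep`` (model, lat, lon), kg N ha⁻¹ yr⁻¹, whose
      per-model sum equals a perturbed version of the total-deposition
      field;
    * ``cn_wood`` (cn_set, lat, lon) plus ``cn_org``/``cn_min`` layers;
    * ``area_ha`` per cell and an integer ``biome`` band layer.
    """
    cfg = cfg or WorldGeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.ny, cfg.nx)

    lat_edges = np.linspace(cfg.lat_span[0], cfg.lat_span[1], cfg.ny + 1)
    lon_edges = np.linspace(cfg.lon_span[0], cfg.lon_span[1], cfg.nx + 1)
    lat = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    lon = 0.5 * (lon_edges[:-1] + lon_edges[1:])

    data = {}
    units = {
        "mat": "degC",
        "map": "mm yr-1",
        "soil_cn": "1",
        "clay": "%",
        "leaf_cn": "1",
        "n_dep": "kg N ha-1 yr-1",
        "org_mass": "Mg ha-1",
        "wood_biomass": "Mg ha-1",
        "npp": "g C m-2 yr-1",
    }
    for name, (lo, hi) in cfg.predictor_ranges.items():
        f = _smooth_field(rng, shape, cfg.smooth_sigma)
        data[name] = xr.DataArray(
            lo + (hi - lo) * f, dims=("lat", "lon"), attrs={"units": units.get(name, "1")}
        )

    lo, hi = cfg.forest_cover_range
    cover = lo + (hi - lo) * _smooth_field(rng, shape, cfg.smooth_sigma)
    data["forest_cover"] = xr.DataArray(
        cover, dims=("lat", "lon"), attrs={"units": "1"}
    )

    # deposition ensemble: smooth NHx share of the total, then one
    # multiplicative perturbation field per model
    total_dep = data["n_dep"].values
    nhx_share = 0.4 + 0.3 * _smooth_field(rng, shape, cfg.smooth_sigma)
    nhx_maps, noy_maps = [], []
    for _ in range(cfg.n_deposition_maps):
        perturb = 0.85 + 0.3 * _smooth_field(rng, shape, cfg.smooth_sigma)
        tot = total_dep * perturb
        nhx_maps.append(tot * nhx_share)
        noy_maps.append(tot * (1.0 - nhx_share))
    dep_attrs = {"units": "kg N ha-1 yr-1"}
    data["nhx_dep"] = xr.DataArray(
        np.stack(nhx_maps), dims=("model", "lat", "lon"), attrs=dep_attrs
    )
    data["noy_dep"] = xr.DataArray(
        np.stack(noy_maps), dims=("model", "lat", "lon"), attrs=dep_attrs
    )

    # stoichiometry layers: smooth base fields; wood C/N additionally
    # carries an ensemble axis of multiplicative sets
    cn_wood_base = 250.0 + 200.0 * _smooth_field(rng, shape, cfg.smooth_sigma)
    factors = np.linspace(0.75, 1.25, cfg.n_wood_cn_sets)
    data["cn_wood"] = xr.DataArray(
        cn_wood_base[None, :, :] * factors[:, None, None],
        dims=("cn_set", "lat", "lon"),
        attrs={"units": "1"},
    )
    data["cn_org"] = xr.DataArray(
        20.0 + 20.0 * _smooth_field(rng, shape, cfg.smooth_sigma),
        dims=("lat", "lon"),
        attrs={"units": "1"},
    )
    data["cn_min"] = xr.DataArray(
        8.0 + 10.0 * _smooth_field(rng, shape, cfg.smooth_sigma),
        dims=("lat", "lon"),
        attrs={"units": "1"},
    )

    area = cell_area_ha(lat_edges, lon_edges)
    data["area_ha"] = xr.DataArray(
        np.broadcast_to(area, shape).copy(), dims=("lat", "lon"), attrs={"units": "ha"}
    )
    biome = np.broadcast_to(biome_of_lat(lat)[:, None], shape).copy()
    data["biome"] = xr.DataArray(
        biome,
        dims=("lat", "lon"),
        attrs={"flag_values": "0 1 2", "flag_meanings": " ".join(BIOME_NAMES)},
    )

    ds = xr.Dataset(
        data,
        coords={
            "lat": ("lat", lat, {"units": "degrees_north"}),
            "lon": ("lon", lon, {"units": "degrees_east"}),
            "model": ("model", np.arange(cfg.n_deposition_maps, dtype=np.int32)),
            "cn_set": ("cn_set", np.arange(cfg.n_wood_cn_sets, dtype=np.int32)),
            "lat_edge": ("lat_edge", lat_edges, {"units": "degrees_north"}),
            "lon_edge": ("lon_edge", lon_edges, {"units": "degrees_east"}),
        },
        attrs={"seed": cfg.seed, "title": "synthetic forest world"},
    )
    return ds
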