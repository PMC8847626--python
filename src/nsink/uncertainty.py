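"""Monte Carlo propagation of site, deposition and stoichiometry uncertainty.

Per retention draw, a random subset of the labelling sites (default 10
of 13, without replacement) is refitted through the full best-subset
selection and re-upscaled to retention maps.  Every retention draw is
then crossed with every deposition map and every wood-C/N set, and each
member runs the stoichiometric sink scaling, so the member count is

    draws × deposition maps × wood C/N sets × soil C/N sets.

Summaries report the ensemble mean and empirical percentile confidence
bounds of the global and biome sinks and efficiencies; per-cell
standard deviations of the retention fractions across draws provide the
retention-map uncertainty fields.  A master seed spawns one independent
substream per draw, so runs are reproducible and draws individually
replayable; draws whose selection fails are skipped and logged, never
imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .carbon import StoichiometrySet, aggregate, csink_cell, DEFAULT_F_BREAKPOINTS
from .identities import ensemble_member_count
from .massbalance import TracerForm
from .retention import CANDIDATE_PREDICTORS, SelectionError
from .synthetic import BIOME_NAMES
from .upscale import (
    DEFAULT_FOREST_THRESHOLD,
    FRACTION_LAYERS,
    fit_retention_models,
    forest_mask,
    predict_fractions,
)

__all__ = [
    "EnsembleConfig",
    "SummaryStats",
    "EnsembleSummary",
    "summarize",
    "run_ensemble",
]

_FORMS = (TracerForm.ammonium.value, TracerForm.nitrate.value)


@dataclass
class EnsembleConfig:
    """Size and seeding of the uncertainty ensemble.

    The reference analysis uses 1000 retention draws of 10-of-13 sites
    crossed with 4 deposition maps and 6 wood-C/N sets (24,000
    members); the desk-scale default keeps the crossing but runs 50
    draws.
    """

    n_retention_draws: int = 50
    n_sites_per_draw: int = 10
    n_deposition_maps: int = 4
    n_wood_cn_sets: int = 6
    n_soil_cn_sets: int = 1
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_retention_draws,
            self.n_deposition_maps,
            self.n_wood_cn_sets,
            self.n_soil_cn_sets,
        ) < 1:
            raise ValueError("all ensemble axis counts must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")

    @property
    def member_count(self) -> int:
        return ensemble_member_count(
            self.n_retention_draws,
            self.n_deposition_maps,
            self.n_wood_cn_sets,
            self.n_soil_cn_sets,
        )


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    lower: float
    upper: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "lower": self.lower,
            "upper": self.upper,
            "n": self.n,
        }


@dataclass
class EnsembleSummary:
    """Summary statistics plus the full member and draw ledgers."""

    quantities: dict[str, SummaryStats]
    member_count: int
    completed_draws: int
    skipped_draws: int
    members: pd.DataFrame
    draw_ledger: pd.DataFrame
    retention_sd: dict[str, xr.Dataset] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "member_count": self.member_count,
            "completed_draws": self.completed_draws,
            "skipped_draws": self.skipped_draws,
            "quantities": {k: v.to_dict() for k, v in self.quantities.items()},
        }


def summarize(members, ci_level: float = 0.95) -> SummaryStats:
    """Mean, SD and empirical percentile CI of an ensemble quantity.

    Bounds sit at the (1 ± ci)/2 percentiles; the result depends only
    on the multiset of members (permutation invariant).
    """
    # sorting makes the summary depend only on the multiset of members
    values = np.sort(np.asarray(list(members), dtype=float))
    if values.size < 2:
        raise ValueError("need at least 2 ensemble members to summarize")
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must lie in (0, 1)")
    alpha = 100.0 * (1.0 - ci_level) / 2.0
    lower, upper = np.percentile(values, [alpha, 100.0 - alpha])
    return SummaryStats(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        lower=float(lower),
        upper=float(upper),
        n=int(values.size),
    )


class _RunningMoments:
    """Per-cell running mean/SD accumulator for the retention layers."""

    def __init__(self):
        self.n = 0
        self.sum = None
        self.sumsq = None

    def add(self, ds: xr.Dataset) -> None:
        arr = {v: ds[v].values.astype(float) for v in FRACTION_LAYERS}
        if self.sum is None:
            self.sum = {v: np.zeros_like(a) for v, a in arr.items()}
            self.sumsq = {v: np.zeros_like(a) for v, a in arr.items()}
        for v, a in arr.items():
            self.sum[v] += a
            self.sumsq[v] += a * a
        self.n += 1

    def sd_dataset(self, template: xr.Dataset) -> xr.Dataset:
        out = {}
        for v in FRACTION_LAYERS:
            mean = self.sum[v] / self.n
            var = np.maximum(self.sumsq[v] / self.n - mean**2, 0.0)
            sd = np.sqrt(var) if self.n > 1 else np.zeros_like(mean)
            out[v + "_sd"] = xr.DataArray(
                sd, dims=template[v].dims, attrs={"units": "%"}
            )
        ds = xr.Dataset(out)
        ds.attrs["n_draws"] = self.n
        return ds


def run_ensemble(
    site_table: pd.DataFrame,
    world: xr.Dataset,
    cfg: EnsembleConfig | None = None,
    *,
    mode: str = "chained",
    forest_threshold: float = DEFAULT_FOREST_THRESHOLD,
    soil_immobilization: float = 0.8,
    f_breakpoints=DEFAULT_F_BREAKPOINTS,
    candidates=CANDIDATE_PREDICTORS,
    vif_cutoff: float = 3.0,
) -> EnsembleSummary:
    """Run the crossed uncertainty ensemble end to end.

    Returns an :class:`EnsembleSummary` whose ``quantities`` cover the
    global sink (total and per form, Pg C yr⁻¹), the C-gain
    efficiencies (kg C per kg N), the forest deposition total (Tg N
    yr⁻¹) and the biome sink totals.
    """
    cfg = cfg or EnsembleConfig()
    sites = np.asarray(sorted(site_table["site_id"].unique()))
    if cfg.n_sites_per_draw > sites.size:
        raise ValueError(
            f"n_sites_per_draw={cfg.n_sites_per_draw} exceeds the "
            f"{sites.size} available sites"
        )
    if cfg.n_deposition_maps > world.sizes.get("model", 0):
        raise ValueError("world has fewer deposition maps than requested")
    if cfg.n_wood_cn_sets > world.sizes.get("cn_set", 0):
        raise ValueError("world has fewer wood C/N sets than requested")

    mask = forest_mask(world, forest_threshold)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_retention_draws)

    member_rows: list[dict] = []
    draw_rows: list[dict] = []
    moments = {form: _RunningMoments() for form in _FORMS}
    skipped = 0

    for d, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        subset = np.sort(rng.choice(sites, size=cfg.n_sites_per_draw, replace=False))
        sub = site_table[site_table["site_id"].isin(subset)]
        try:
            models = {
                form: fit_retention_models(
                    sub, form, mode=mode, candidates=candidates, vif_cutoff=vif_cutoff
                )
                for form in _FORMS
            }
        except SelectionError as err:
            skipped += 1
            draw_rows.append(
                {"draw": d, "sites": ",".join(subset), "status": f"skipped: {err}"}
            )
            continue
        fractions = {
            form: predict_fractions(models[form], world, form, mode=mode)
            for form in _FORMS
        }
        for form in _FORMS:
            moments[form].add(fractions[form])
        draw_rows.append(
            {
                "draw": d,
                "sites": ",".join(subset),
                "status": "ok",
                **{
                    f"{form}:{resp}": "+".join(fit.predictors)
                    for form in _FORMS
                    for resp, fit in models[form].items()
                },
            }
        )

        for m in range(cfg.n_deposition_maps):
            nhx = world["nhx_dep"].isel(model=m)
            noy = world["noy_dep"].isel(model=m)
            total = nhx + noy
            for w in range(cfg.n_wood_cn_sets):
                stoich = StoichiometrySet(
                    cn_wood=world["cn_wood"].isel(cn_set=w),
                    cn_org=world["cn_org"],
                    cn_min=world["cn_min"],
                    soil_immobilization=soil_immobilization,
                    f_breakpoints=f_breakpoints,
                )
                res_nhx = aggregate(
                    csink_cell(nhx, fractions[TracerForm.ammonium.value], stoich, total),
                    world,
                    mask,
                    n_dep=nhx,
                )
                res_noy = aggregate(
                    csink_cell(noy, fractions[TracerForm.nitrate.value], stoich, total),
                    world,
                    mask,
                    n_dep=noy,
                )
                total_pg = res_nhx.global_pg + res_noy.global_pg
                dep_tg = res_nhx.deposition_tg + res_noy.deposition_tg
                row = {
                    "draw": d,
                    "dep_model": m,
                    "cn_set": w,
                    "sink_nhx_pg": res_nhx.global_pg,
                    "sink_noy_pg": res_noy.global_pg,
                    "sink_total_pg": total_pg,
                    "dep_nhx_tg": res_nhx.deposition_tg,
                    "dep_noy_tg": res_noy.deposition_tg,
                    "dep_total_tg": dep_tg,
                    "eff_nhx": res_nhx.efficiency_kg_per_kg,
                    "eff_noy": res_noy.efficiency_kg_per_kg,
                    "eff_total": total_pg * 1e12 / (dep_tg * 1e9) if dep_tg > 0 else np.nan,
                }
                for name in BIOME_NAMES:
                    row[f"sink_{name}_pg"] = (
                        res_nhx.biome_pg[name] + res_noy.biome_pg[name]
                    )
                member_rows.append(row)

    members = pd.DataFrame(member_rows)
    draw_ledger = pd.DataFrame(draw_rows)
    completed = cfg.n_retention_draws - skipped
    quantities: dict[str, SummaryStats] = {}
    if len(members) >= 2:
        for col in members.columns:
            if col in ("draw", "dep_model", "cn_set"):
                continue
            quantities[col] = summarize(members[col], cfg.ci_level)
    template = xr.Dataset(
        {
            v: xr.DataArray(
                np.zeros((world.sizes["lat"], world.sizes["lon"])), dims=("lat", "lon")
            )
            for v in FRACTION_LAYERS
        }
    )
    retention_sd = {
        form: acc.sd_dataset(template) for form, acc in moments.items() if acc.n > 0
    }
    return EnsembleSummary(
        quantities=quantities,
        member_count=completed
        * cfg.n_deposition_maps
        * cfg.n_wood_cn_sets
        * cfg.n_soil_cn_sets,
        completed_draws=completed,
        skipped_draws=skipped,
        members=members,
        draw_ledger=draw_ledger,
        retention_sd=retention_sd,
    )
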