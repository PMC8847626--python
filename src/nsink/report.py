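"""End-to-end pipeline runs and the headline summary report.

``run_pipeline`` wires the stages together on synthetic inputs: build
the site table and world, fit the retention regressions on all sites,
upscale to per-form retention maps, scale to the C sink with the
central deposition and stoichiometry, and run the crossed Monte Carlo
ensemble.  The report carries the headline quantities (global and biome
sinks, per-form efficiencies, ensemble CI) together with the internal
consistency identities — biome sinks summing to the global sink, the
efficiency equalling sink over deposition, the global sink rebuilt from
per-form efficiencies, and the factorial member count — each computed
from the run's own outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .carbon import DEFAULT_F_BREAKPOINTS, StoichiometrySet, aggregate, csink_cell
from .identities import (
    efficiency_from_totals,
    ensemble_member_count,
    global_deposition_from_biomes,
    sink_from_form_efficiencies,
)
from .io import config_hash
from .massbalance import TracerForm
from .retention import CANDIDATE_PREDICTORS
from .synthetic import (
    SiteGeneratorConfig,
    WorldGeneratorConfig,
    make_site_table,
    make_world,
)
from .uncertainty import EnsembleConfig, run_ensemble
from .upscale import (
    DEFAULT_FOREST_THRESHOLD,
    fit_retention_models,
    forest_mask,
    predict_fractions,
)

__all__ = ["PipelineConfig", "run_pipeline"]

_FORMS = (TracerForm.ammonium.value, TracerForm.nitrate.value)


@dataclass
class PipelineConfig:
    """Everything a full synthetic pipeline run needs."""

    seed: int = 0
    n_sites: int = 13
    nx: int = 36
    ny: int = 18
    forest_threshold: float = DEFAULT_FOREST_THRESHOLD
    mode: str = "chained"
    vif_cutoff: float = 3.0
    soil_immobilization: float = 0.8
    f_breakpoints: tuple = DEFAULT_F_BREAKPOINTS
    n_retention_draws: int = 50
    n_sites_per_draw: int = 10
    n_deposition_maps: int = 4
    n_wood_cn_sets: int = 6
    ci_level: float = 0.95

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**mapping)
        if "f_breakpoints" in mapping:
            cfg.f_breakpoints = tuple(tuple(p) for p in mapping["f_breakpoints"])
        return cfg


def _spawn_seeds(seed: int, n: int) -> list[int]:
    # independent 31-bit child seeds for the generator stages
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def run_pipeline(cfg: PipelineConfig | None = None) -> dict:
    """Run the full synthetic pipeline and assemble the report dict."""
    cfg = cfg or PipelineConfig()
    site_seed, world_seed, ens_seed = _spawn_seeds(cfg.seed, 3)

    sites = make_site_table(SiteGeneratorConfig(n_sites=cfg.n_sites, seed=site_seed))
    world = make_world(
        WorldGeneratorConfig(
            nx=cfg.nx,
            ny=cfg.ny,
            n_deposition_maps=cfg.n_deposition_maps,
            n_wood_cn_sets=cfg.n_wood_cn_sets,
            seed=world_seed,
        )
    )
    mask = forest_mask(world, cfg.forest_threshold)

    # central estimate: all sites, ensemble-mean deposition, mid stoichiometry
    models = {
        form: fit_retention_models(sites, form, mode=cfg.mode, vif_cutoff=cfg.vif_cutoff)
        for form in _FORMS
    }
    fractions = {
        form: predict_fractions(models[form], world, form, mode=cfg.mode)
        for form in _FORMS
    }
    nhx = world["nhx_dep"].mean("model")
    noy = world["noy_dep"].mean("model")
    total_dep = nhx + noy
    stoich = StoichiometrySet(
        cn_wood=world["cn_wood"].mean("cn_set"),
        cn_org=world["cn_org"],
        cn_min=world["cn_min"],
        soil_immobilization=cfg.soil_immobilization,
        f_breakpoints=cfg.f_breakpoints,
    )
    dep_by_form = {"nhx": nhx, "noy": noy}
    frac_by_form = {"nhx": fractions[_FORMS[0]], "noy": fractions[_FORMS[1]]}
    central = {}
    for key in ("nhx", "noy"):
        sink = csink_cell(dep_by_form[key], frac_by_form[key], stoich, total_dep)
        central[key] = aggregate(sink, world, mask, n_dep=dep_by_form[key])

    global_pg = central["nhx"].global_pg + central["noy"].global_pg
    dep_tg = central["nhx"].deposition_tg + central["noy"].deposition_tg
    biome_pg = {
        b: central["nhx"].biome_pg[b] + central["noy"].biome_pg[b]
        for b in central["nhx"].biome_pg
    }
    biome_dep_tg = {
        b: central["nhx"].biome_deposition_tg[b] + central["noy"].biome_deposition_tg[b]
        for b in central["nhx"].biome_deposition_tg
    }
    eff_by_form = {
        k: central[k].efficiency_kg_per_kg for k in ("nhx", "noy")
    }
    dep_by_form_tg = {k: central[k].deposition_tg for k in ("nhx", "noy")}

    ens_cfg = EnsembleConfig(
        n_retention_draws=cfg.n_retention_draws,
        n_sites_per_draw=min(cfg.n_sites_per_draw, cfg.n_sites),
        n_deposition_maps=cfg.n_deposition_maps,
        n_wood_cn_sets=cfg.n_wood_cn_sets,
        ci_level=cfg.ci_level,
        seed=ens_seed,
    )
    ensemble = run_ensemble(
        sites,
        world,
        ens_cfg,
        mode=cfg.mode,
        forest_threshold=cfg.forest_threshold,
        soil_immobilization=cfg.soil_immobilization,
        f_breakpoints=cfg.f_breakpoints,
        vif_cutoff=cfg.vif_cutoff,
    )

    cfg_dict = asdict(cfg)
    report = {
        "provenance": {
            "package_version": __version__,
            "seed": cfg.seed,
            "config_hash": config_hash(cfg_dict),
            "config": cfg_dict,
        },
        "selected_models": {
            form: {
                resp: {"predictors": list(fit.predictors), "r2": fit.r2, "aicc": fit.aicc}
                for resp, fit in models[form].items()
            }
            for form in _FORMS
        },
        "central": {
            "global_sink_pg": global_pg,
            "biome_sink_pg": biome_pg,
            "forest_deposition_tg": dep_tg,
            "biome_deposition_tg": biome_dep_tg,
            "deposition_by_form_tg": dep_by_form_tg,
            "efficiency_by_form_kg_per_kg": eff_by_form,
            "efficiency_kg_per_kg": efficiency_from_totals(global_pg, dep_tg),
        },
        "ensemble": ensemble.to_dict(),
        "identities": {
            "biome_sink_sum_pg": sum(biome_pg.values()),
            "global_sink_pg": global_pg,
            "deposition_from_biomes_tg": global_deposition_from_biomes(
                biome_dep_tg.values()
            ),
            "sink_from_form_efficiencies_pg": sink_from_form_efficiencies(
                eff_by_form, dep_by_form_tg
            ),
            "member_count": ensemble_member_count(
                ens_cfg.n_retention_draws,
                ens_cfg.n_deposition_maps,
                ens_cfg.n_wood_cn_sets,
                ens_cfg.n_soil_cn_sets,
            ),
        },
    }
    return report
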