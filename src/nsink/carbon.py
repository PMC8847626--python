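"""Stoichiometric scaling of retained N deposition to a forest C sink.

Retained nitrogen builds carbon in proportion to the C/N ratio of the
compartment it ends up in.  Per cell and deposition form,

    sink = N_dep · [ fo·(C/N)_org·s + fm·(C/N)_min·s + fw·(C/N)_wood·f ]

where fo/fm/fw are the organic-layer, mineral-soil and woody retention
fractions, s is the share of soil-retained N immobilized in persistent
soil organic matter (default 0.8), and f in [0, 1] downweights the wood
term as N deposition saturates tree growth (1 below 15, 0.5 at 30, 0 at
and above 100 kg N ha⁻¹ yr⁻¹, piecewise linear).  Non-woody plant
retention (foliage, fine roots) turns over quickly and contributes no
sink.  By default f is evaluated from the total (NHₓ + NO_y) load even
when a single form's sink is computed, since growth saturation responds
to the whole N input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .synthetic import BIOME_NAMES

__all__ = [
    "StoichiometrySet",
    "CSinkResult",
    "f_wood",
    "csink_cell",
    "aggregate",
]

KG_PER_PG = 1e12
KG_PER_TG = 1e9

DEFAULT_F_BREAKPOINTS = ((15.0, 1.0), (30.0, 0.5), (100.0, 0.0))


@dataclass
class StoichiometrySet:
    """C/N ratios and soil-immobilization assumptions for the sink.

    ``cn_wood``/``cn_org``/``cn_min`` may be scalars or co-registered
    layers.  ``soil_immobilization`` multiplies both soil terms.
    ``f_breakpoints`` anchor the wood-growth saturation factor.
    """

    cn_wood: float | xr.DataArray
    cn_org: float | xr.DataArray
    cn_min: float | xr.DataArray
    soil_immobilization: float = 0.8
    f_breakpoints: tuple[tuple[float, float], ...] = DEFAULT_F_BREAKPOINTS

    def __post_init__(self) -> None:
        for name in ("cn_wood", "cn_org", "cn_min"):
            val = getattr(self, name)
            if np.any(np.asarray(val) <= 0):
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.soil_immobilization <= 1.0:
            raise ValueError("soil_immobilization must lie in [0, 1]")
        _validate_breakpoints(self.f_breakpoints)


def _validate_breakpoints(breakpoints) -> tuple[np.ndarray, np.ndarray]:
    bp = [(float(x), float(f)) for x, f in breakpoints]
    if not bp:
        raise ValueError("empty f breakpoints")
    xs = np.array([x for x, _ in bp])
    fs = np.array([f for _, f in bp])
    if np.any(np.diff(xs) <= 0):
        raise ValueError("f breakpoints must be strictly increasing in n_dep")
    if np.any(np.diff(fs) > 0):
        raise ValueError("f breakpoints must be non-increasing in f")
    if np.any((fs < 0) | (fs > 1)):
        raise ValueError("f values must lie in [0, 1]")
    return xs, fs


def f_wood(n_dep, breakpoints=DEFAULT_F_BREAKPOINTS):
    """Wood-growth saturation factor f as a function of N deposition.

    Piecewise linear through the anchor points, constant beyond the
    first and last; continuous and non-increasing.  ``n_dep`` in kg N
    ha⁻¹ yr⁻¹, broadcasting over arrays.
    """
    xs, fs = _validate_breakpoints(breakpoints)
    n_dep_arr = np.asarray(n_dep, dtype=float)
    if np.any(n_dep_arr < 0):
        raise ValueError("n_dep must be >= 0")
    out = np.interp(n_dep_arr, xs, fs)
    if isinstance(n_dep, xr.DataArray):
        return xr.DataArray(out, coords=n_dep.coords, dims=n_dep.dims)
    return out if out.ndim else float(out)


def csink_cell(
    n_dep,
    fractions: xr.Dataset,
    stoich: StoichiometrySet,
    n_dep_total=None,
):
    """N-induced C sink, kg C ha⁻¹ yr⁻¹, broadcasting over cells.

    ``n_dep`` is the deposition of the form whose sink is computed;
    ``n_dep_total`` (default: ``n_dep``) is the load used to evaluate
    the wood saturation factor f.
    """
    if np.any(np.asarray(n_dep) < 0):
        raise ValueError("n_dep must be >= 0")
    if n_dep_total is None:
        n_dep_total = n_dep
    f = f_wood(n_dep_total, stoich.f_breakpoints)
    s = stoich.soil_immobilization
    per_kg = (
        fractions["frac_org"] / 100.0 * stoich.cn_org * s
        + fractions["frac_min"] / 100.0 * stoich.cn_min * s
        + fractions["frac_wood"] / 100.0 * stoich.cn_wood * f
    )
    sink = n_dep * per_kg
    if isinstance(sink, xr.DataArray):
        sink.name = "c_sink"
        sink.attrs["units"] = "kg C ha-1 yr-1"
    return sink


@dataclass
class CSinkResult:
    """Aggregated sink with the unit chain kg C ha⁻¹ yr⁻¹ → Pg C yr⁻¹."""

    sink_map: xr.DataArray
    global_pg: float
    biome_pg: dict[str, float]
    deposition_tg: float | None = None
    efficiency_kg_per_kg: float | None = None
    biome_deposition_tg: dict[str, float] = field(default_factory=dict)


def aggregate(
    sink_map: xr.DataArray,
    world: xr.Dataset,
    mask: xr.DataArray,
    n_dep: xr.DataArray | None = None,
) -> CSinkResult:
    """Area-weight the per-cell sink to biome and global totals.

    Each cell contributes sink · area · forest_cover over the masked
    (forest) cells; totals are reported in Pg C yr⁻¹ and are exactly
    conserved across the biome partition.  When a deposition layer is
    given, the N total over the same weighting (Tg N yr⁻¹) and the
    C-gain efficiency (kg C per kg N deposited) are also reported.
    """
    for layer in ("area_ha", "forest_cover", "biome"):
        if layer not in world:
            raise KeyError(f"world has no {layer} layer")
    weight = world["area_ha"] * world["forest_cover"] * mask
    cell_kg = (sink_map * weight).values
    biome_idx = world["biome"].values
    global_pg = float(np.nansum(cell_kg)) / KG_PER_PG
    biome_pg = {}
    for i, name in enumerate(BIOME_NAMES):
        biome_pg[name] = float(np.nansum(np.where(biome_idx == i, cell_kg, 0.0))) / KG_PER_PG

    dep_tg = eff = None
    biome_dep = {}
    if n_dep is not None:
        dep_kg = (n_dep * weight).values
        total_dep_kg = float(np.nansum(dep_kg))
        dep_tg = total_dep_kg / KG_PER_TG
        for i, name in enumerate(BIOME_NAMES):
            biome_dep[name] = (
                float(np.nansum(np.where(biome_idx == i, dep_kg, 0.0))) / KG_PER_TG
            )
        eff = float(np.nansum(cell_kg)) / total_dep_kg if total_dep_kg > 0 else np.nan
    return CSinkResult(
        sink_map=sink_map,
        global_pg=global_pg,
        biome_pg=biome_pg,
        deposition_tg=dep_tg,
        efficiency_kg_per_kg=eff,
        biome_deposition_tg=biome_dep,
    )
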