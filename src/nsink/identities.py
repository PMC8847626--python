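"""Arithmetic consistency identities between published budget totals.

Global N-deposition/C-sink budgets are usually reported as a set of
mutually constrained numbers: biome depositions that must sum to the
global total, a C-gain efficiency that must equal sink over deposition,
per-form efficiencies that must reconstruct the global sink, and an
ensemble size fixed by its factorial crossing.  These helpers compute
each identity from the input totals so a reported budget can be checked
for internal consistency; the pipeline's own report runs the same
checks on its computed outputs.

Unit conventions: sinks in Pg C yr⁻¹, depositions in Tg N yr⁻¹,
efficiencies in kg C per kg N.
"""

from __future__ import annotations

from typing import Mapping, Sequence

__all__ = [
    "global_deposition_from_biomes",
    "efficiency_from_totals",
    "share_of_reference_sink",
    "ensemble_member_count",
    "sink_from_form_efficiencies",
]

KG_PER_PG = 1e12
KG_PER_TG = 1e9


def global_deposition_from_biomes(biome_deposition_tg: Sequence[float]) -> float:
    """Global forest N deposition (Tg N yr⁻¹) as the sum over biomes."""
    return float(sum(biome_deposition_tg))


def efficiency_from_totals(sink_pg: float, deposition_tg: float) -> float:
    """C-gain efficiency, kg C per kg N, from global totals."""
    if deposition_tg <= 0:
        raise ValueError("deposition must be positive")
    return sink_pg * KG_PER_PG / (deposition_tg * KG_PER_TG)


def share_of_reference_sink(sink_pg: float, reference_sink_pg: float) -> float:
    """The sink as a percentage of a reference (e.g. terrestrial) sink."""
    if reference_sink_pg <= 0:
        raise ValueError("reference sink must be positive")
    return 100.0 * sink_pg / reference_sink_pg


def ensemble_member_count(
    n_retention_draws: int,
    n_deposition_maps: int,
    n_wood_cn_sets: int,
    n_soil_cn_sets: int = 1,
) -> int:
    """Members in the fully crossed uncertainty ensemble."""
    counts = (n_retention_draws, n_deposition_maps, n_wood_cn_sets, n_soil_cn_sets)
    if any(c < 1 for c in counts):
        raise ValueError("all ensemble axis counts must be >= 1")
    n = 1
    for c in counts:
        n *= int(c)
    return n


def sink_from_form_efficiencies(
    efficiency_kg_per_kg: Mapping[str, float],
    deposition_tg: Mapping[str, float],
) -> float:
    """Global sink (Pg C yr⁻¹) rebuilt from per-form efficiencies.

    sink = Σ_form efficiency_form · deposition_form, which must equal
    the directly reported global sink (and implies that the overall
    efficiency is the deposition-weighted mean of the per-form ones).
    """
    if set(efficiency_kg_per_kg) != set(deposition_tg):
        raise ValueError("efficiency and deposition forms differ")
    total_kg = sum(
        efficiency_kg_per_kg[f] * deposition_tg[f] * KG_PER_TG for f in deposition_tg
    )
    return total_kg / KG_PER_PG
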