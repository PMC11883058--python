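"""Per-leaf-layer annual carbon budgets and the canopy-trimming optimality.

Each leaf layer's net carbon export (NCE) over a year is

    nce = assimilation − maintenance respiration − construction cost

all in kg C per m² of leaf per year. Construction amortizes the carbon
cost of building a unit of leaf area (1/SLA) over the leaf lifespan.
A cohort trims its target leaf biomass down when the deepest retained
layer exports negative carbon, and relaxes the trim back up when it is
positive — an annual one-step controller that drives the canopy toward
the LAI of maximum net canopy export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forcing import ForcingSeries
from .physiology import (
    PFTParams,
    arrhenius,
    _co2_limitation,
    heskel_factor,
    kn,
    layer_grid,
    nscaler,
    rdark_top,
    KINETICS,
)

__all__ = [
    "LayerBudget",
    "light_profile",
    "annual_layer_budgets",
    "net_canopy_export",
    "trim_update",
    "optimal_lai",
    "construction_cost",
    "t10_series",
    "budgets_to_frame",
    "UMOL_TO_KGC",
    "DEFAULT_K_LIGHT",
    "DEFAULT_TRIM_INCREMENT",
    "DEFAULT_TRIM_MIN",
]

#: kg C per μmol CO₂ (12 g C mol⁻¹).
UMOL_TO_KGC = 12.0e-9
#: Beer–Lambert extinction coefficient for PAR (spherical leaf angles).
DEFAULT_K_LIGHT = 0.5
DEFAULT_TRIM_INCREMENT = 0.05
DEFAULT_TRIM_MIN = 0.3
SECONDS_PER_HOUR = 3600.0
DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class LayerBudget:
    """Annual carbon budget of one leaf layer (kg C m⁻² leaf yr⁻¹).

    The identity ``nce = assim_annual − rdark_annual − construction_annual``
    holds exactly by construction.
    """

    layer_index: int
    layer_thickness: float
    assim_annual: float
    rdark_annual: float
    construction_annual: float

    @property
    def nce(self) -> float:
        return self.assim_annual - self.rdark_annual - self.construction_annual


def light_profile(par_top: float, cum_lai_edges, k_light: float = DEFAULT_K_LIGHT):
    """Absorbed PAR per layer (per m² ground) from Beer–Lambert attenuation.

    Incident PAR at cumulative depth L is par_top·exp(−k·L); a layer
    absorbs the difference of incident PAR across its boundaries, so
    absorbed + transmitted below the canopy = incident exactly.
    """
    if k_light <= 0:
        raise ValueError("k_light must be > 0")
    if np.any(np.asarray(par_top) < 0):
        raise ValueError("par_top must be >= 0")
    edges = np.asarray(cum_lai_edges, dtype=float)
    incident = par_top * np.exp(-k_light * edges)
    return -np.diff(incident)


def t10_series(air_temp: np.ndarray) -> np.ndarray:
    """Daily 10-day running-mean temperature, window pre-filled with day 0."""
    temps = np.asarray(air_temp, dtype=float)
    padded = np.concatenate([np.full(9, temps[0]), temps])
    csum = np.concatenate([[0.0], np.cumsum(padded)])
    return (csum[10:] - csum[:-10]) / 10.0


def construction_cost(pft: PFTParams) -> float:
    """Leaf construction cost, kg C m⁻² leaf yr⁻¹: (1/SLA)/lifespan."""
    return 1.0 / (pft.sla * pft.leaf_lifespan)


def annual_layer_budgets(
    pft: PFTParams,
    scenario_b_rdark: float,
    total_lai: float,
    forcing_year: ForcingSeries,
    layer_thickness: float = 1.0,
    k_light: float = DEFAULT_K_LIGHT,
    charge_growth_respiration: bool = False,
    cum_lai_offset: float = 0.0,
    kinetics=KINETICS,
) -> list[LayerBudget]:
    """Integrate daily assimilation and R_dark per leaf layer over one year.

    Assimilation runs for ``day_length`` hours per day at the daytime-mean
    PAR; maintenance respiration runs 24 h per day. With
    ``charge_growth_respiration`` the 0.11 growth surcharge on each layer's
    positive net assimilation is folded into its construction cost
    (default off: growth respiration is charged at the whole-plant level).
    ``cum_lai_offset`` is the patch LAI overlying this canopy (understory
    cohorts): nitrogen scaling starts at that depth, while the forcing's
    ``par_top`` is taken as already attenuated to the canopy's own top.
    """
    if total_lai < 0:
        raise ValueError("total_lai must be >= 0")
    if scenario_b_rdark <= 0:
        raise ValueError("scenario_b_rdark must be > 0")
    if cum_lai_offset < 0:
        raise ValueError("cum_lai_offset must be >= 0")
    edges, mids, thick = layer_grid(total_lai, layer_thickness)
    if len(mids) == 0:
        return []

    t = forcing_year.air_temp
    par = forcing_year.par_top
    dayh = forcing_year.day_length
    t10 = t10_series(t)

    kn_v = kn(pft.vcmax25_top, pft.kn_a, pft.kn_b_default)
    kn_r = kn(pft.vcmax25_top, pft.kn_a, scenario_b_rdark)
    vc25 = pft.vcmax25_top * nscaler(cum_lai_offset + mids, kn_v)  # (layers,)
    ns_r = nscaler(cum_lai_offset + mids, kn_r)

    # Static attenuation fractions: absorbed fraction of par_top per layer.
    absorbed_frac = light_profile(1.0, edges, k_light) / thick  # per m² leaf

    arr_v = arrhenius(t, kinetics.ea_vcmax)  # (days,)
    cc = _co2_limitation(t, pft, kinetics)
    hf = heskel_factor(t)
    rd_top = np.array([rdark_top(pft, x) for x in t10])

    ac = vc25[None, :] * (arr_v * cc)[:, None]
    aj = pft.quantum_yield * absorbed_frac[None, :] * par[:, None]
    a_gross = np.minimum(ac, aj)  # (days, layers), μmol m⁻² leaf s⁻¹

    assim = (
        UMOL_TO_KGC
        * SECONDS_PER_HOUR
        * forcing_year.diurnal_factor
        * (a_gross * dayh[:, None]).sum(axis=0)
    )
    rdark = UMOL_TO_KGC * SECONDS_PER_HOUR * 24.0 * (rd_top * hf).sum() * ns_r

    constr = np.full(len(mids), construction_cost(pft))
    if charge_growth_respiration:
        constr = constr + 0.11 * np.maximum(0.0, assim - rdark)

    return [
        LayerBudget(i, float(thick[i]), float(assim[i]), float(rdark[i]), float(constr[i]))
        for i in range(len(mids))
    ]


def net_canopy_export(budgets: list[LayerBudget]) -> float:
    """Sum of per-layer NCE weighted by layer thickness (ground basis)."""
    return float(sum(b.nce * b.layer_thickness for b in budgets))


def trim_update(
    current_trim: float,
    budgets: list[LayerBudget],
    trim_increment: float = DEFAULT_TRIM_INCREMENT,
    trim_min: float = DEFAULT_TRIM_MIN,
) -> float:
    """Annual one-step adjustment of the leaf-biomass trim scalar.

    If the deepest retained layer exported negative carbon the trim
    decreases by one increment (never below ``trim_min``); if it exported
    positive carbon and the trim is below 1 it recovers by one increment
    (never above 1). An empty canopy leaves the trim unchanged.
    """
    if not (trim_min - 1e-12 <= current_trim <= 1.0 + 1e-12):
        raise ValueError(f"trim {current_trim} outside [{trim_min}, 1]")
    if not budgets:
        return current_trim
    bottom = budgets[-1].nce
    if bottom < 0.0:
        return max(trim_min, current_trim - trim_increment)
    if bottom > 0.0 and current_trim < 1.0:
        return min(1.0, current_trim + trim_increment)
    return current_trim


def optimal_lai(
    pft: PFTParams,
    scenario_b_rdark: float,
    forcing_year: ForcingSeries,
    lai_max: float,
    layer_thickness: float = 1.0,
    k_light: float = DEFAULT_K_LIGHT,
    charge_growth_respiration: bool = False,
) -> float:
    """LAI maximizing net canopy carbon export, scanned in layer steps.

    Exhaustive scan of candidate LAIs 0, Δ, 2Δ, …, lai_max (Δ the layer
    thickness); ties break toward the smaller LAI.
    """
    if lai_max <= 0:
        raise ValueError("lai_max must be > 0")
    candidates = np.arange(0.0, lai_max + 1e-9, layer_thickness)
    if candidates[-1] < lai_max - 1e-9:
        candidates = np.append(candidates, lai_max)
    exports = [
        net_canopy_export(
            annual_layer_budgets(
                pft,
                scenario_b_rdark,
                lai,
                forcing_year,
                layer_thickness,
                k_light,
                charge_growth_respiration,
            )
        )
        for lai in candidates
    ]
    return float(candidates[int(np.argmax(exports))])


def budgets_to_frame(budgets: list[LayerBudget], year: int = 0) -> pd.DataFrame:
    """Tabulate per-layer budgets (year, layer_index, cum_lai, fluxes, nce)."""
    cum = np.cumsum([b.layer_thickness for b in budgets])
    return pd.DataFrame(
        {
            "year": year,
            "layer_index": [b.layer_index for b in budgets],
            "cum_lai": cum,
            "assim": [b.assim_annual for b in budgets],
            "rdark": [b.rdark_annual for b in budgets],
            "construction": [b.construction_annual for b in budgets],
            "nce": [b.nce for b in budgets],
        }
    )
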