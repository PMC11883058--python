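"""Leaf physiology: dark respiration and carboxylation vertical profiles.

Implements the respiration scheme in which top-of-canopy leaf maintenance
(dark) respiration is a linear function of leaf nitrogen and the 10-day
running-mean air temperature,

    R_dark,top = r0 + r1 · lnc_top + r2 · t10          (μmol CO₂ m⁻² s⁻¹)

and both R_dark and V_cmax decay exponentially with overlying cumulative
leaf area index (LAI) via a nitrogen extinction coefficient

    rate(z) = rate_top · nscaler(z),   nscaler = exp(−k_n · LAI),
    k_n = exp(a · V_cmax,25,top − b).

The experiments in this package perturb only ``b`` for R_dark (scenario
multipliers 1.2…0.5 of the default), holding the V_cmax profile fixed, so
the ratio R_dark25/V_cmax25 stays constant with depth only when the two
decay parameters coincide and declines with depth when the R_dark ``b`` is
smaller (steeper gradient).

Instantaneous temperature sensitivity of respiration uses a decelerating
log-polynomial (normalized to 1 at 25 °C); gross photosynthesis uses a
simplified Farquhar form, min(Rubisco-limited, light-limited), with a fixed
ratio of intercellular to ambient CO₂.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

__all__ = [
    "PFTParams",
    "AcclimationState",
    "CanopyProfile",
    "PhotosynthesisConstants",
    "KINETICS",
    "update_t10",
    "rdark_top",
    "heskel_factor",
    "kn",
    "nscaler",
    "arrhenius",
    "gross_assimilation",
    "build_profile",
    "layer_grid",
    "read_pft_table",
    "write_pft_table",
]

# Universal gas constant, J mol⁻¹ K⁻¹
_RGAS = 8.314462618

# Decelerating instantaneous temperature response of respiration:
# ln(R_T / R_ref) = B·(T − T_ref) − C·(T² − T_ref²), reference 25 °C.
HESKEL_B = 0.1012
HESKEL_C = 0.0005005
HESKEL_TREF = 25.0


@dataclass(frozen=True)
class PhotosynthesisConstants:
    """Rubisco kinetic constants at 25 °C with Arrhenius activation energies.

    Standard C3 values; concentrations in μmol mol⁻¹ (Kc, Γ*) and
    mmol mol⁻¹ (Ko, O₂); energies in J mol⁻¹.
    """

    kc25: float = 404.9
    ko25: float = 278.4
    gamma_star25: float = 42.75
    ea_kc: float = 79430.0
    ea_ko: float = 36380.0
    ea_gamma_star: float = 37830.0
    ea_vcmax: float = 65330.0
    o2: float = 209.46
    ca: float = 400.0


KINETICS = PhotosynthesisConstants()


@dataclass(frozen=True)
class PFTParams:
    """Physiological, allometric and demographic constants of one PFT.

    Units: r0 μmol CO₂ m⁻² s⁻¹; r1 μmol CO₂ m⁻² s⁻¹ (gN m⁻²)⁻¹;
    r2 μmol CO₂ m⁻² s⁻¹ °C⁻¹; lnc_top gN m⁻²; vcmax25_top μmol m⁻² s⁻¹;
    sla m² leaf (kg C)⁻¹; leaf_lifespan yr; mortality rates yr⁻¹;
    recruitment_rate individuals ha⁻¹ yr⁻¹. Allometries are power laws:
    height = h1·dbh^h2 (m, dbh in cm); crown area = c1·dbh^c2 (m²);
    target leaf carbon = trim·l1·dbh^l2 (kg C); structural carbon
    = s1·dbh^s2 (kg C).
    """

    name: str
    r0: float
    lnc_top: float
    vcmax25_top: float
    r1: float = 0.2061
    r2: float = -0.0402
    kn_a: float = 0.00963
    kn_b_default: float = 2.43
    sla: float = 15.0
    leaf_lifespan: float = 1.5
    h1: float = 2.0
    h2: float = 0.6
    c1: float = 0.2
    c2: float = 1.3
    l1: float = 0.08
    l2: float = 1.3
    s1: float = 0.07
    s2: float = 2.5
    background_mort_rate: float = 0.014
    cstarv_mort_max: float = 0.2
    storage_target_fraction: float = 1.0
    recruitment_rate: float = 100.0
    ci_over_ca: float = 0.7
    quantum_yield: float = 0.08
    stem_maint_rate: float = 1e-6  # yr⁻¹ per kg structural C; near-zero default

    def __post_init__(self) -> None:
        positive = [
            "r1", "kn_a", "kn_b_default", "vcmax25_top", "sla", "leaf_lifespan",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"PFT {self.name!r}: {name} must be > 0")
        if not (0.0 < self.ci_over_ca < 1.0):
            raise ValueError(f"PFT {self.name!r}: ci_over_ca must lie in (0, 1)")
        if not (0.0 < self.quantum_yield <= 0.125):
            raise ValueError(
                f"PFT {self.name!r}: quantum_yield must lie in (0, 0.125]"
            )


@dataclass
class AcclimationState:
    """Rolling 10-day temperature window driving thermal acclimation.

    ``t10`` is always the arithmetic mean of the buffer contents.
    """

    temp_buffer: deque = field(default_factory=lambda: deque(maxlen=10))

    @property
    def t10(self) -> float:
        if not self.temp_buffer:
            raise ValueError("acclimation buffer is empty; no t10 defined")
        return float(sum(self.temp_buffer) / len(self.temp_buffer))

    @classmethod
    def initialized(cls, first_temp: float) -> "AcclimationState":
        """Pre-fill the window with the first day's temperature."""
        state = cls()
        state.temp_buffer.extend([float(first_temp)] * 10)
        return state


def update_t10(state: AcclimationState, todays_temp: float) -> AcclimationState:
    """Append today's temperature to the 10-day window (evicting day −10)."""
    if not math.isfinite(todays_temp):
        raise ValueError("todays_temp must be finite")
    new = AcclimationState(deque(state.temp_buffer, maxlen=10))
    new.temp_buffer.append(float(todays_temp))
    return new


def rdark_top(pft: PFTParams, t10: float) -> float:
    """Top-of-canopy dark respiration at the 25 °C reference, acclimated to t10.

    Linear in leaf nitrogen and the 10-day mean temperature; clamped at
    zero because the linear form can go negative in hot, low-nitrogen
    corners of parameter space.
    """
    if pft.lnc_top <= 0:
        raise ValueError("lnc_top must be > 0")
    return max(0.0, pft.r0 + pft.r1 * pft.lnc_top + pft.r2 * t10)


def heskel_factor(t_inst, t_ref: float = HESKEL_TREF):
    """Instantaneous temperature multiplier for respiration.

    Decelerating response: strictly increasing in temperature but with a
    declining sensitivity at high temperature (the log of the factor is
    concave in T). Equals 1 at ``t_ref``. Accepts scalars or arrays.
    """
    t = np.asarray(t_inst, dtype=float)
    if np.any((t <= -50.0) | (t >= 60.0)):
        raise ValueError("t_inst outside physiological range (-50, 60) °C")
    out = np.exp(HESKEL_B * (t - t_ref) - HESKEL_C * (t**2 - t_ref**2))
    return float(out) if np.isscalar(t_inst) else out


def kn(vcmax25_top: float, a: float, b: float) -> float:
    """Canopy extinction coefficient k_n = exp(a·V_cmax,25,top − b)."""
    if vcmax25_top <= 0 or b <= 0:
        raise ValueError("vcmax25_top and b must be > 0")
    return math.exp(a * vcmax25_top - b)


def nscaler(cum_lai, kn_value: float):
    """Exponential decay of top-of-canopy rates with cumulative LAI."""
    lai = np.asarray(cum_lai, dtype=float)
    if np.any(lai < 0):
        raise ValueError("cum_lai must be >= 0")
    if kn_value <= 0:
        raise ValueError("kn_value must be > 0")
    out = np.exp(-kn_value * lai)
    return float(out) if np.isscalar(cum_lai) else out


def arrhenius(t_celsius, ea: float, t_ref: float = 25.0):
    """Arrhenius temperature factor normalized to 1 at ``t_ref``."""
    tk = np.asarray(t_celsius, dtype=float) + 273.15
    tk_ref = t_ref + 273.15
    out = np.exp(ea / _RGAS * (1.0 / tk_ref - 1.0 / tk))
    return float(out) if np.isscalar(t_celsius) else out


def _co2_limitation(t_inst, pft: PFTParams, k: PhotosynthesisConstants = KINETICS):
    """(C_i − Γ*)/(C_i + K_m) at temperature ``t_inst``; clamped at 0."""
    ci = pft.ci_over_ca * k.ca
    kc = k.kc25 * arrhenius(t_inst, k.ea_kc)
    ko = k.ko25 * arrhenius(t_inst, k.ea_ko)
    gamma = k.gamma_star25 * arrhenius(t_inst, k.ea_gamma_star)
    km = kc * (1.0 + k.o2 / ko)
    return np.maximum(0.0, (ci - gamma) / (ci + km))


def gross_assimilation(
    vcmax25_layer,
    apar_layer,
    t_inst,
    pft: PFTParams,
    kinetics: PhotosynthesisConstants = KINETICS,
):
    """Gross CO₂ assimilation of one leaf layer, μmol CO₂ m⁻² leaf s⁻¹.

    Co-limited minimum of the Rubisco-limited rate
    A_c = V_cmax(T)·(C_i − Γ*)/(C_i + K_m) and the light-limited rate
    A_j = quantum_yield·APAR. Zero when either capacity or light is zero;
    non-decreasing in both.
    """
    v = np.asarray(vcmax25_layer, dtype=float)
    i = np.asarray(apar_layer, dtype=float)
    if np.any(v < 0) or np.any(i < 0):
        raise ValueError("vcmax25_layer and apar_layer must be >= 0")
    ac = v * arrhenius(t_inst, kinetics.ea_vcmax) * _co2_limitation(
        t_inst, pft, kinetics
    )
    aj = pft.quantum_yield * i
    out = np.minimum(ac, aj)
    if np.isscalar(vcmax25_layer) and np.isscalar(apar_layer):
        return float(out)
    return out


def layer_grid(total_lai: float, layer_thickness: float = 1.0):
    """Discretize a canopy of ``total_lai`` into layers of ``layer_thickness``.

    Returns (edges, mids, thicknesses); the deepest layer may be partial.
    ``total_lai = 0`` yields empty arrays.
    """
    if total_lai < 0:
        raise ValueError("total_lai must be >= 0")
    if layer_thickness <= 0:
        raise ValueError("layer_thickness must be > 0")
    if total_lai == 0:
        z = np.zeros(0)
        return np.zeros(1), z, z
    n_full = int(total_lai / layer_thickness)
    edges = np.arange(n_full + 1, dtype=float) * layer_thickness
    if total_lai - edges[-1] > 1e-12 * max(1.0, total_lai):
        edges = np.append(edges, total_lai)
    mids = 0.5 * (edges[:-1] + edges[1:])
    return edges, mids, np.diff(edges)


@dataclass
class CanopyProfile:
    """Per-leaf-layer vertical profiles through one canopy.

    All per-layer arrays are indexed from the canopy top. ``apar`` is
    absorbed PAR per unit leaf area (μmol photons m⁻² leaf s⁻¹); ``rdark``
    is at the current instantaneous temperature.
    """

    layer_thickness: np.ndarray
    cum_lai_at_layer_mid: np.ndarray
    nscaler_rdark: np.ndarray
    nscaler_vcmax: np.ndarray
    vcmax25: np.ndarray
    rdark: np.ndarray
    apar: np.ndarray

    @property
    def n_layers(self) -> int:
        return len(self.cum_lai_at_layer_mid)


def build_profile(
    pft: PFTParams,
    scenario_b_rdark: float,
    total_lai: float,
    t10: float,
    t_inst: float,
    par_top: float,
    layer_thickness: float = 1.0,
    k_light: float = 0.5,
    cum_lai_offset: float = 0.0,
) -> CanopyProfile:
    """Build the vertical profile of V_cmax25, R_dark and absorbed PAR.

    V_cmax25 decays with the default extinction parameter ``kn_b_default``;
    R_dark decays with the scenario's perturbed ``b``. The instantaneous
    temperature factor is applied uniformly over depth (isothermal canopy
    air). ``cum_lai_offset`` places the profile below overlying canopy
    layers: nitrogen scaling depends on cumulative LAI from the very top
    of the patch canopy, so an understory cohort's uppermost leaves start
    at the offset, while ``par_top`` is the (already attenuated) PAR
    incident at the cohort's own top.
    """
    if scenario_b_rdark <= 0:
        raise ValueError("scenario_b_rdark must be > 0")
    if cum_lai_offset < 0:
        raise ValueError("cum_lai_offset must be >= 0")
    from .canopy import light_profile  # local import avoids module cycle

    edges, mids, thick = layer_grid(total_lai, layer_thickness)
    if len(mids) == 0:
        empty = np.zeros(0)
        return CanopyProfile(empty, empty, empty, empty, empty, empty, empty)

    kn_v = kn(pft.vcmax25_top, pft.kn_a, pft.kn_b_default)
    kn_r = kn(pft.vcmax25_top, pft.kn_a, scenario_b_rdark)
    ns_v = nscaler(cum_lai_offset + mids, kn_v)
    ns_r = nscaler(cum_lai_offset + mids, kn_r)
    vc25 = pft.vcmax25_top * ns_v
    rd = rdark_top(pft, t10) * ns_r * heskel_factor(t_inst)
    absorbed = light_profile(par_top, edges, k_light)  # per m² ground
    apar = absorbed / thick  # per m² leaf
    return CanopyProfile(thick, cum_lai_offset + mids, ns_r, ns_v, vc25, rd, apar)


# ---------------------------------------------------------------------------
# PFT parameter table I/O

_PFT_COLUMNS = [f.name for f in dc_fields(PFTParams)]


def write_pft_table(pfts: dict[str, PFTParams], path) -> None:
    """Write a PFT parameter table as CSV, one row per PFT."""
    rows = [{c: getattr(p, c) for c in _PFT_COLUMNS} for p in pfts.values()]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_pft_table(path) -> dict[str, PFTParams]:
    """Read a PFT parameter CSV, validating ranges row by row.

    A validation failure names the offending row and column.
    """
    df = pd.read_csv(path)
    missing = [c for c in _PFT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PFT table {path} missing columns: {missing}")
    out: dict[str, PFTParams] = {}
    for idx, row in df.iterrows():
        kwargs = {c: row[c] for c in _PFT_COLUMNS}
        kwargs["name"] = str(kwargs["name"])
        for col, val in kwargs.items():
            if col != "name" and not math.isfinite(float(val)):
                raise ValueError(
                    f"PFT table {path}, row {idx}, column {col!r}: "
                    f"non-finite value {val!r}"
                )
        try:
            out[kwargs["name"]] = PFTParams(**kwargs)
        except ValueError as err:
            raise ValueError(f"PFT table {path}, row {idx}: {err}") from err
    return out
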