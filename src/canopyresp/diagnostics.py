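"""Annual diagnostics of patch state and carbon fluxes.

Computes the reporting metrics of the analysis: LAI split into canopy
(layer 1) and understory (layers 2–3) components, understory canopy area
(closure at 1 m² crown per m² ground), vegetation carbon, GPP/NPP and
carbon use efficiency (CUE = NPP/GPP), the understory carbon-starvation
mortality rate, and annual carbon allocated to leaf biomass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path as FsPath

import pandas as pd

from .demography import FluxLedger, Patch
from .physiology import PFTParams

__all__ = ["AnnualDiagnostics", "compute_diagnostics", "write_outputs",
           "patch_state_frame", "diagnostics_frame"]

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class AnnualDiagnostics:
    """One year of patch-level metrics.

    LAI components are m² m⁻²; carbon stocks kg C m⁻²; fluxes
    kg C m⁻² yr⁻¹; cue is NPP/GPP (NaN when GPP = 0, e.g. a bare patch);
    starvation_mort_understory is the density-weighted mean starvation
    mortality component among understory cohorts, yr⁻¹.
    """

    year: int
    lai_total: float
    lai_canopy: float
    lai_understory: float
    canopy_area_understory: float
    veg_carbon: float
    gpp: float
    npp: float
    maint_resp: float
    growth_resp: float
    cue: float
    starvation_mort_understory: float
    leaf_alloc: float
    closure_rel: float


def compute_diagnostics(
    patch: Patch, ledger: FluxLedger, pfts: dict[str, PFTParams]
) -> AnnualDiagnostics:
    """Compute the annual metrics for a layered patch and its flux ledger."""
    if not getattr(patch, "layered", True):
        raise ValueError("patch has not been layered this year")
    lai_canopy = 0.0
    lai_under = 0.0
    area_under = 0.0
    starv_num = 0.0
    starv_den = 0.0
    for c in patch.cohorts:
        p = pfts[c.pft]
        leaf_area = c.leaf_c * p.sla * c.n_per_ha / patch.area
        if c.canopy_layer == 1:
            lai_canopy += leaf_area
        else:
            lai_under += leaf_area
            area_under += c.crown_area_each(p) * c.n_per_ha / patch.area
            starv_num += c.starv_mort_rate * c.n_per_ha
            starv_den += c.n_per_ha
    cue = ledger.npp / ledger.gpp if ledger.gpp > 0 else math.nan
    return AnnualDiagnostics(
        year=patch.year,
        lai_total=lai_canopy + lai_under,
        lai_canopy=lai_canopy,
        lai_understory=lai_under,
        canopy_area_understory=area_under,
        veg_carbon=patch.veg_carbon(),
        gpp=ledger.gpp,
        npp=ledger.npp,
        maint_resp=ledger.maint_resp,
        growth_resp=ledger.growth_resp,
        cue=cue,
        starvation_mort_understory=(
            starv_num / starv_den if starv_den > 0 else 0.0
        ),
        leaf_alloc=ledger.leaf_alloc,
        closure_rel=ledger.closure_relative,
    )


def diagnostics_frame(rows: list[AnnualDiagnostics]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in rows])


def patch_state_frame(patch: Patch, pfts: dict[str, PFTParams]) -> pd.DataFrame:
    """Tabulate the cohort state of a patch (one row per cohort)."""
    rows = []
    for i, c in enumerate(patch.cohorts):
        p = pfts[c.pft]
        rows.append(
            {
                "year": patch.year,
                "cohort": i,
                "pft": c.pft,
                "dbh": c.dbh,
                "n_per_ha": c.n_per_ha,
                "layer": c.canopy_layer,
                "height": c.height(p),
                "leaf_c": c.leaf_c,
                "struct_c": c.struct_c,
                "storage_c": c.storage_c,
                "trim": c.trim,
            }
        )
    cols = ["year", "cohort", "pft", "dbh", "n_per_ha", "layer", "height",
            "leaf_c", "struct_c", "storage_c", "trim"]
    return pd.DataFrame(rows, columns=cols)


def write_outputs(
    diagnostics: dict[str, pd.DataFrame],
    out_dir,
    patch_states: dict[str, pd.DataFrame] | None = None,
    layer_budgets: dict[str, pd.DataFrame] | None = None,
    netcdf: bool = False,
) -> None:
    """Write per-scenario delimited-text outputs (and optionally NetCDF).

    One subdirectory per scenario label with annual_diagnostics.csv, plus
    patch_state.csv and layer_budgets.csv where provided. Numeric
    formatting is fixed so identical runs give byte-identical files. The
    optional NetCDF bundle uses dimensions (scenario, year).
    """
    out = FsPath(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise OSError(f"cannot create output directory {out}: {err}") from err
    for label, df in diagnostics.items():
        d = out / label
        d.mkdir(exist_ok=True)
        df.to_csv(d / "annual_diagnostics.csv", index=False, float_format=_FLOAT_FMT)
        if patch_states and label in patch_states:
            patch_states[label].to_csv(
                d / "patch_state.csv", index=False, float_format=_FLOAT_FMT
            )
        if layer_budgets and label in layer_budgets:
            layer_budgets[label].to_csv(
                d / "layer_budgets.csv", index=False, float_format=_FLOAT_FMT
            )
    if netcdf:
        import xarray as xr

        ds = xr.Dataset(
            {
                var: (
                    ("scenario", "year"),
                    [df[var].to_numpy() for df in diagnostics.values()],
                )
                for var in next(iter(diagnostics.values())).columns
                if var != "year"
            },
            coords={
                "scenario": list(diagnostics),
                "year": next(iter(diagnostics.values()))["year"].to_numpy(),
            },
        )
        ds.to_netcdf(out / "diagnostics.nc", engine="scipy")
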