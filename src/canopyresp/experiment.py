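"""Scenario construction and the two experiment drivers.

The gradient-perturbation ensemble varies the canopy-extinction parameter
``b`` of the R_dark profile from 1.2× to 0.5× its default in steps of 0.1
(scenarios V1…V8; smaller b = steeper vertical decay of respiration),
holding the V_cmax profile fixed. The single-PFT driver runs each scenario
on its own patch (no inter-PFT competition, prescribed seed rain); the
two-PFT coexistence driver runs scenarios V1/V3/V5/V7 with a light-
demanding and a shade-tolerant PFT competing on one patch through shared
canopy layering and NPP-linked recruitment.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, replace as dc_replace
from importlib import resources
from pathlib import Path as FsPath

import pandas as pd
import yaml

from .canopy import budgets_to_frame, annual_layer_budgets
from .demography import Patch, SimSettings, step_year
from .diagnostics import (
    compute_diagnostics,
    diagnostics_frame,
    patch_state_frame,
    write_outputs,
)
from .forcing import (
    ClimatologyParams,
    ForcingSeries,
    generate_forcing,
    read_forcing_csv,
)
from .physiology import PFTParams, read_pft_table

__all__ = [
    "Scenario",
    "RunConfig",
    "ConfigError",
    "build_scenarios",
    "preset_pfts",
    "load_config",
    "run_gradient_ensemble",
    "run_coexistence",
    "equilibrium_mean",
    "DEFAULT_KN_B",
    "COEXISTENCE_SCENARIOS",
]

DEFAULT_KN_B = 2.43
#: Multipliers 1.2 … 0.5 in steps of 0.1, labelled V1 … V8.
SCENARIO_MULTIPLIERS = [round(1.2 - 0.1 * i, 10) for i in range(8)]
COEXISTENCE_SCENARIOS = ["V1", "V3", "V5", "V7"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass(frozen=True)
class Scenario:
    """One ensemble member: a multiplier on the R_dark decay parameter."""

    label: str
    b_multiplier: float
    b_rdark: float
    years: int = 150
    seed: int = 0
    pft_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.b_rdark <= 0:
            raise ValueError("b_rdark must be > 0")


def build_scenarios(
    kn_b_default: float = DEFAULT_KN_B,
    years: int = 150,
    seed: int = 0,
    pft_set: tuple[str, ...] = (),
) -> list[Scenario]:
    """The eight gradient scenarios V1 (shallowest) … V8 (steepest)."""
    if kn_b_default <= 0:
        raise ValueError("kn_b_default must be > 0")
    return [
        Scenario(
            label=f"V{i + 1}",
            b_multiplier=m,
            b_rdark=m * kn_b_default,
            years=years,
            seed=seed,
            pft_set=pft_set,
        )
        for i, m in enumerate(SCENARIO_MULTIPLIERS)
    ]


def preset_pfts() -> dict[str, PFTParams]:
    """The shipped tropical PFT parameter table."""
    with resources.as_file(
        resources.files("canopyresp.data") / "tropical_pfts.csv"
    ) as path:
        return read_pft_table(path)


@dataclass
class RunConfig:
    """Fully resolved configuration of one experiment run."""

    pfts: dict[str, PFTParams]
    climate: ClimatologyParams
    years: int = 150
    seed: int = 0
    scenario_labels: list[str] = field(default_factory=list)
    settings: SimSettings = field(default_factory=SimSettings)
    forcing_path: str | None = None
    light_demander: str | None = None  # coexistence runs only
    out_dir: str | None = None
    netcdf: bool = False
    equilibrium_years: int = 10

    def forcing(self) -> ForcingSeries:
        if self.forcing_path is not None:
            series = read_forcing_csv(
                self.forcing_path, diurnal_factor=self.climate.diurnal_factor
            )
            if series.n_years < self.years:
                raise ConfigError(
                    f"forcing file covers {series.n_years} years; "
                    f"run needs {self.years} (key: run.years)"
                )
            return series
        return generate_forcing(
            dc_replace(self.climate, seed=self.seed), self.years
        )


def load_config(path, **overrides) -> RunConfig:
    """Load a YAML run configuration, applying defaults and validating.

    Sections: ``forcing`` (climatology overrides or a ``file`` path),
    ``pfts`` (``table`` path or ``names`` subset of the shipped presets),
    ``scenarios`` (list of labels), ``run`` (years, seed, numerical
    settings), ``output`` (dir, netcdf). Validation failures name the key.
    """
    raw = yaml.safe_load(FsPath(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path}: top level must be a mapping")
    known = {"forcing", "pfts", "scenarios", "run", "output"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"config {path}: unknown section(s) {sorted(unknown)}")

    forcing_sec = dict(raw.get("forcing") or {})
    forcing_path = forcing_sec.pop("file", None)
    try:
        climate = ClimatologyParams(**forcing_sec)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"config {path}, section 'forcing': {err}") from err

    pft_sec = dict(raw.get("pfts") or {})
    if "table" in pft_sec:
        pfts = read_pft_table(pft_sec["table"])
    else:
        pfts = preset_pfts()
    if "names" in pft_sec:
        missing = [n for n in pft_sec["names"] if n not in pfts]
        if missing:
            raise ConfigError(
                f"config {path}, key 'pfts.names': unknown PFT(s) {missing}"
            )
        pfts = {n: pfts[n] for n in pft_sec["names"]}
    light_demander = pft_sec.get("light_demander")

    run_sec = dict(raw.get("run") or {})
    years = int(run_sec.pop("years", 150))
    seed = int(run_sec.pop("seed", 0))
    if years < 1:
        raise ConfigError(f"config {path}, key 'run.years': must be >= 1")
    equilibrium_years = int(run_sec.pop("equilibrium_years", 10))
    try:
        settings = SimSettings(**run_sec)
    except TypeError as err:
        raise ConfigError(f"config {path}, section 'run': {err}") from err

    out_sec = dict(raw.get("output") or {})
    cfg = RunConfig(
        pfts=pfts,
        climate=climate,
        years=years,
        seed=seed,
        scenario_labels=list(raw.get("scenarios") or []),
        settings=settings,
        forcing_path=forcing_path,
        light_demander=light_demander,
        out_dir=out_sec.get("dir"),
        netcdf=bool(out_sec.get("netcdf", False)),
        equilibrium_years=equilibrium_years,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def _select(scenarios: list[Scenario], labels: list[str]) -> list[Scenario]:
    if not labels:
        return scenarios
    by_label = {s.label: s for s in scenarios}
    missing = [l for l in labels if l not in by_label]
    if missing:
        raise ConfigError(f"unknown scenario label(s) {missing}")
    return [by_label[l] for l in labels]


def _log(quiet: bool, msg: str) -> None:
    if not quiet:
        print(msg, file=sys.stderr)


def run_gradient_ensemble(
    config: RunConfig, quiet: bool = True
) -> dict[str, pd.DataFrame]:
    """Run every scenario on identical forcing; one patch per scenario.

    Scenarios are independent (fresh bare-ground patch each); all
    randomness comes from the configured seed through the forcing
    generator, so two runs of the same config are byte-identical.
    Returns a table of annual diagnostics per scenario label and, when
    the config names an output directory, writes CSV/NetCDF dumps.
    """
    if not config.pfts:
        raise ConfigError("config has no PFTs (key: pfts)")
    kn_b = {p.kn_b_default for p in config.pfts.values()}
    if len(kn_b) != 1:
        raise ConfigError("all PFTs must share kn_b_default for one ensemble")
    scenarios = _select(
        build_scenarios(kn_b.pop(), config.years, config.seed),
        config.scenario_labels,
    )
    forcing = config.forcing()
    results: dict[str, pd.DataFrame] = {}
    states: dict[str, pd.DataFrame] = {}
    budgets: dict[str, pd.DataFrame] = {}
    for scen in scenarios:
        _log(quiet, f"[{scen.label}] b_rdark={scen.b_rdark:.4g}")
        patch = Patch.bare_ground()
        rows = []
        for y in range(config.years):
            patch, ledger = step_year(
                patch, config.pfts, forcing.year(y), scen.b_rdark, config.settings
            )
            rows.append(compute_diagnostics(patch, ledger, config.pfts))
            _log(quiet, f"[{scen.label}] year {y + 1}: lai={rows[-1].lai_total:.2f}")
        results[scen.label] = diagnostics_frame(rows)
        states[scen.label] = patch_state_frame(patch, config.pfts)
        first_pft = next(iter(config.pfts.values()))
        budgets[scen.label] = budgets_to_frame(
            annual_layer_budgets(
                first_pft,
                scen.b_rdark,
                8.0,
                forcing.year(config.years - 1),
                config.settings.layer_thickness,
                config.settings.k_light,
            ),
            year=config.years,
        )
    if config.out_dir:
        write_outputs(results, config.out_dir, states, budgets, config.netcdf)
        _echo_config(config)
    return results


def run_coexistence(
    config: RunConfig, quiet: bool = True
) -> pd.DataFrame:
    """Two-PFT competition runs over scenarios V1, V3, V5 and V7.

    Both PFTs share one patch (full competition through the common PPA
    layering and light profile) with NPP-linked recruitment. Returns the
    annual structural (aboveground) biomass per PFT per scenario.
    """
    if len(config.pfts) != 2:
        raise ConfigError(
            f"coexistence needs exactly 2 PFTs, got {len(config.pfts)} "
            "(key: pfts.names)"
        )
    names = list(config.pfts)
    ld = config.light_demander or names[0]
    if ld not in config.pfts:
        raise ConfigError(f"unknown light_demander {ld!r} (key: pfts.light_demander)")
    st = next(n for n in names if n != ld)
    if config.pfts[ld].r0 <= config.pfts[st].r0:
        raise ConfigError(
            "light-demanding PFT must have the higher base respiration rate "
            f"r0 (got {ld}={config.pfts[ld].r0}, {st}={config.pfts[st].r0})"
        )
    kn_b = {p.kn_b_default for p in config.pfts.values()}
    if len(kn_b) != 1:
        raise ConfigError("both PFTs must share kn_b_default")
    labels = config.scenario_labels or COEXISTENCE_SCENARIOS
    scenarios = _select(
        build_scenarios(kn_b.pop(), config.years, config.seed), labels
    )
    settings = dc_replace(config.settings, recruitment_mode="npp")
    forcing = config.forcing()
    rows = []
    for scen in scenarios:
        _log(quiet, f"[{scen.label}] b_rdark={scen.b_rdark:.4g}")
        patch = Patch.bare_ground()
        for y in range(config.years):
            patch, ledger = step_year(
                patch, config.pfts, forcing.year(y), scen.b_rdark, settings
            )
            agb = {
                n: sum(
                    c.struct_c * c.n_per_ha
                    for c in patch.cohorts
                    if c.pft == n
                )
                / patch.area
                for n in names
            }
            for n in names:
                rows.append(
                    {
                        "scenario": scen.label,
                        "year": y + 1,
                        "pft": n,
                        "agb": agb[n],
                        "role": "light_demander" if n == ld else "shade_tolerant",
                        "closure_rel": ledger.closure_relative,
                    }
                )
    df = pd.DataFrame(rows)
    if config.out_dir:
        out = FsPath(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "coexistence_agb.csv", index=False, float_format="%.10g")
        _echo_config(config)
    return df


def biomass_share(coexist: pd.DataFrame, scenario: str, year: int) -> float:
    """Light-demander share of total structural biomass at one year."""
    sel = coexist[(coexist.scenario == scenario) & (coexist.year == year)]
    total = sel.agb.sum()
    if total <= 0:
        return 0.0
    return float(sel[sel.role == "light_demander"].agb.sum() / total)


def equilibrium_mean(
    diagnostics: pd.DataFrame, column: str, years: int = 10
) -> float:
    """Mean of a diagnostic over the final ``years`` simulation years."""
    return float(diagnostics[column].tail(years).mean())


def _echo_config(config: RunConfig) -> None:
    """Write the fully resolved configuration next to the outputs."""
    out = FsPath(config.out_dir)
    doc = {
        "forcing": {
            k: getattr(config.climate, k)
            for k in ClimatologyParams.__dataclass_fields__
        },
        "pfts": {
            name: {
                k: getattr(p, k) for k in PFTParams.__dataclass_fields__
            }
            for name, p in config.pfts.items()
        },
        "scenarios": config.scenario_labels or [s.label for s in build_scenarios()],
        "run": {
            "years": config.years,
            "seed": config.seed,
            "equilibrium_years": config.equilibrium_years,
            **{
                k: getattr(config.settings, k)
                for k in SimSettings.__dataclass_fields__
            },
        },
        "output": {"dir": str(config.out_dir), "netcdf": config.netcdf},
    }
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(doc, sort_keys=True)
    )
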