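"""Two-PFT competition under default versus steep respiration gradients.

A light-demanding pioneer (higher base respiration r0, higher V_cmax25,
cheap short-lived leaves, cheap wood, higher mortality) competes with a
shade-tolerant PFT (low respiration, long-lived leaves, dense wood) on
one patch, with recruitment scaled by each PFT's carbon balance. Because
the pioneer's respiration is higher everywhere, steepening the canopy
R_dark gradient removes more carbon cost from the pioneer than from the
shade tolerant, delaying the successional takeover. The shipped analyses
run 300 years; 120 here keeps the demo quick.
"""

from canopyresp import ClimatologyParams, RunConfig, biomass_share, preset_pfts
from canopyresp.experiment import run_coexistence

pfts = preset_pfts()
cfg = RunConfig(
    pfts={n: pfts[n] for n in ("light_demander", "shade_tolerant")},
    climate=ClimatologyParams(),
    years=120,
    seed=7,
    light_demander="light_demander",
    scenario_labels=["V3", "V7"],
)
trajectories = run_coexistence(cfg, quiet=True)

print("Light-demander share of structural biomass:")
print(f"{'year':>6} {'V3 (default)':>13} {'V7 (steep)':>11}")
for year in (30, 60, 90, 120):
    print(f"{year:>6} {biomass_share(trajectories, 'V3', year):>13.3f} "
          f"{biomass_share(trajectories, 'V7', year):>11.3f}")

print("\nUnder the default gradient the shade tolerant erodes the pioneer's"
      "\nearly dominance; under the steep V7 gradient the pioneer's larger"
      "\nabsolute respiration relief keeps it competitive for longer.")
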