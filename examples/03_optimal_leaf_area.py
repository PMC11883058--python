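"""The canopy-trimming optimum: LAI of maximum net canopy carbon export.

Each leaf layer's annual net carbon export (NCE) is assimilation minus
maintenance respiration minus the amortized cost of building the leaves.
A canopy should stop adding layers where NCE turns negative; steeper
vertical gradients of R_dark push that break-even point deeper, raising
the optimal LAI — the mechanistic core of the leaf-area response.
"""

from canopyresp import (
    ClimatologyParams,
    annual_layer_budgets,
    generate_forcing,
    optimal_lai,
    preset_pfts,
)

pft = preset_pfts()["broadleaf_evergreen_tropical"]
forcing = generate_forcing(
    ClimatologyParams(noise_sd_temp=0.0, noise_sd_par=0.0), 1
)

print("Per-layer annual budgets under the default gradient (kg C m⁻² leaf "
      "yr⁻¹):")
print(f"{'layer':>5} {'assim':>8} {'rdark':>8} {'constr':>8} {'nce':>8}")
for b in annual_layer_budgets(pft, pft.kn_b_default, 9.0, forcing):
    print(f"{b.layer_index:>5} {b.assim_annual:8.3f} {b.rdark_annual:8.3f} "
          f"{b.construction_annual:8.3f} {b.nce:8.3f}")

print("\nOptimal LAI versus gradient steepness (b multiplier on 2.43):")
for mult in (1.2, 1.1, 1.0, 0.9, 0.8, 0.7, 0.6, 0.5):
    lai = optimal_lai(pft, mult * pft.kn_b_default, forcing, lai_max=14.0)
    print(f"  ×{mult:<4} → optimal LAI {lai:4.1f}")
print("\nSteeper gradients (smaller multipliers) never lower the optimum:"
      "\nthe export-maximizing canopy deepens as understory leaves get "
      "cheaper to maintain.")
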