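"""Vertical profiles of leaf dark respiration under alternate gradients.

Top-of-canopy R_dark comes from the nitrogen- and temperature-acclimated
linear model; both R_dark and V_cmax25 decay exponentially with overlying
LAI through a canopy extinction coefficient k_n = exp(a·V_cmax,25,top − b).
Perturbing b only for R_dark (V1 = 1.2× default … V8 = 0.5× default)
changes the R_dark/V_cmax ratio at depth: under the default V3 the ratio
is constant, under steeper gradients it declines toward the ground.
"""

from canopyresp import build_profile, preset_pfts, rdark_top

pft = preset_pfts()["broadleaf_evergreen_tropical"]
t10 = 26.0   # 10-day mean temperature the base rate is acclimated to
print(f"PFT {pft.name}: Vcmax25,top = {pft.vcmax25_top}, "
      f"Rdark,top(25°C basis) = {rdark_top(pft, t10):.3f} μmol m⁻² s⁻¹, "
      f"top-of-canopy ratio = {rdark_top(pft, t10) / pft.vcmax25_top:.4f}")

for label, mult in [("V1", 1.2), ("V3", 1.0), ("V8", 0.5)]:
    b = mult * pft.kn_b_default
    prof = build_profile(pft, b, total_lai=7.0, t10=t10, t_inst=25.0,
                         par_top=1400.0)
    print(f"\n{label}  (b = {b:.3f})  — layer mid-depth, Rdark, "
          f"Rdark/Vcmax25:")
    for z, rd, vc in zip(prof.cum_lai_at_layer_mid, prof.rdark, prof.vcmax25):
        print(f"  LAI {z:4.1f}:  {rd:6.3f} μmol m⁻² s⁻¹   ratio {rd / vc:.4f}")

print("\nUnder V3 the ratio is depth-invariant; under V8 respiration at the"
      "\ncanopy bottom is a small fraction of the proportional value — the"
      "\nconfiguration observed in canopy profile measurements.")
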