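"""Generate seeded synthetic tropical forcing and inspect its statistics.

The generator produces daily air temperature (mean + weak seasonal
sinusoid + AR(1) noise) and daytime photosynthetically active radiation
(seasonal sinusoid with multiplicative noise, truncated at zero) — a
stand-in for station or reanalysis forcing over a lowland tropical site.
"""

import numpy as np

from canopyresp import ClimatologyParams, generate_forcing, write_forcing_csv

params = ClimatologyParams(seed=42)  # the default lowland-tropical preset
forcing = generate_forcing(params, years=10)

print(f"steps: {forcing.n_steps} days ({forcing.n_years} years)")
print(f"air temperature: mean {forcing.air_temp.mean():.2f} °C, "
      f"sd {forcing.air_temp.std():.2f} °C "
      f"(preset mean {params.mean_temp} °C)")
print(f"PAR: mean {forcing.par_top.mean():.0f} μmol m⁻² s⁻¹, "
      f"min {forcing.par_top.min():.0f} (never negative)")
lag1 = np.corrcoef(forcing.air_temp[:-1], forcing.air_temp[1:])[0, 1]
print(f"day-to-day temperature autocorrelation: {lag1:.2f} "
      f"(AR(1) coefficient {params.ar1_coefficient})")

write_forcing_csv(forcing, "forcing_demo.csv")
print("wrote forcing_demo.csv (columns: step, air_temp_C, par_umol_m2_s, "
      "day_length_h)")
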