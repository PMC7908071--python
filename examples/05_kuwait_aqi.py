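"""Kuwait AQI sub-indices and a daily overall AQI series.

Converts a few concentrations through the national breakpoint grid and
then builds the day-by-day AQI of a simulated station (gases converted
from mg/m3 to ppm first).
"""

import pandas as pd

import airimpute as ai

for pollutant, conc in [("O3", 0.03), ("CO", 22.95), ("SO2", 0.305),
                        ("PM10", 700.0)]:
    res = ai.concentration_to_aqi(pollutant, conc)
    print(f"{pollutant:>5} {conc:>8} -> I = {res.index:6.1f}  {res.category}")
# 0.03 ppm ozone sits exactly on the Good/Moderate knot (I = 50);
# 22.95 ppm CO is the midpoint of the Very Unhealthy segment (I = 250.5).

panel = ai.generate_study(ai.default_config(n_days=30, seed=9))[0]
conc = pd.DataFrame(index=panel.data.index)
for gas in ("CO", "NO2", "O3", "SO2"):
    conc[gas] = ai.mgm3_to_ppm(gas, panel.data[gas].to_numpy())
conc["PM10"] = (panel.data["PM10"] * 1000.0).clip(upper=1000.0)  # -> ug/m3

daily = ai.panel_aqi(conc)
print("\nfirst week of daily AQI (overall = max sub-index):")
print(daily.head(7).round(1))
print(f"\nmonth median AQI: {daily['AQI'].median():.0f}")
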