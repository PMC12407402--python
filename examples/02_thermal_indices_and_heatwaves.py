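"""Derived thermal quantities: wet-bulb temperatures, the Excess Heat
Factor, and heatwave events.

The wet bulb combines temperature and humidity (Stull's empirical fit);
the EHF flags spells that are hot relative to both the location's
long-term average and the preceding month; a heatwave is three or more
consecutive days of positive EHF.
"""

from datetime import date

import heatbands as hb
from heatbands import synthetic_data as sd

print("wet bulb at 35 degC:")
for rh in (20, 50, 80, 100):
    print(f"  RH {rh:3d}% -> {hb.wet_bulb_stull(35.0, rh):.1f} degC")
# Humid heat is far more oppressive: at 80 % RH a 35-degree day has a wet
# bulb above 31 degC, close to the limit of effective sweating.

w = sd.gen_weather(sd.TROPICAL, ["darwin_like"], (date(2000, 1, 1), date(2003, 12, 31)), seed=1)
w = hb.derive_daily_fields(w)
w = hb.excess_heat_factor(w)
events = hb.detect_heatwaves(w)
per_year = len(events) / 4
durations = [e.duration for e in events]
print(f"\n{len(events)} heatwaves in 4 tropical years ({per_year:.1f}/year), "
      f"mean duration {sum(durations) / len(durations):.1f} days")
print("first three events:")
for ev in events[:3]:
    print(f"  {ev.start_date} to {ev.end_date} ({ev.duration} days)")
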