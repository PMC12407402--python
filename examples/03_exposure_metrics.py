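"""Per-trimester exposure vectors for one pregnancy under all five metrics.

Gestation is dated from conception and split into trimesters of 12, 14 and
13 weeks; each metric summarises the 273-day weather history into a few
regressors (band day-counts, averages, or heatwave counts).
"""

from datetime import date

import pandas as pd

import heatbands as hb
from heatbands import synthetic_data as sd

w = sd.gen_weather(sd.TROPICAL, ["darwin_like"], (date(2000, 1, 1), date(2002, 12, 31)), seed=1)
w = hb.derive_daily_fields(w)
w = hb.excess_heat_factor(w)

birth = pd.DataFrame(
    {
        "birth_id": ["baby01"],
        "location_id": ["darwin_like"],
        "birth_date": [date(2001, 11, 5)],
        "gestational_weeks": [39],
    }
)
conc = hb.conception_date(date(2001, 11, 5), 39)
print(f"born 2001-11-05 at 39 weeks -> conceived {conc}")
wins = hb.trimester_windows(conc)
for k in (1, 2, 3):
    lo, hi = wins.window(k)
    print(f"  trimester {k}: [{lo}, {hi})  ({(hi - lo).days} days)")

for name, spec in hb.METRICS.items():
    expo = hb.build_exposures(birth, w, spec)
    nonzero = expo.loc["baby01"]
    nonzero = nonzero[nonzero != 0]
    print(f"\n{name} ({len(expo.columns)} regressors, "
          f"{len(expo.attrs['omitted'])} omitted reference bands):")
    print("  " + ", ".join(f"{k}={v:.0f}" if float(v).is_integer() else f"{k}={v:.1f}"
                           for k, v in nonzero.items()))
# Band counts within a trimester always sum to the trimester length
# (84/98/91 days) once the omitted reference band is included.
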