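"""Seasonal agrochemical doses from the weekly application schedule.

Treatment plots received tapering concentrations in 10 L of water, four
times a month for three months, over 4 m^2.  This converts the schedule to
total mass per area and compares the herbicide total against a standard
annual field application rate.
"""

import bloomnet as bn

for compound, schedule in bn.DEFAULT_SCHEDULES.items():
    total, _ = bn.total_application(schedule)
    print(f"{compound:>11}: {schedule.monthly_mg_per_l} mg/L "
          f"-> {total:g} g/m^2 per season")

_, pct = bn.total_application(bn.DEFAULT_SCHEDULES["glyphosate"],
                              reference_g_per_ha=1440.0)
print(f"\nglyphosate season total = {pct:.1f}% of a 1,440 g/ha field rate")
print("(the exposure is deliberately sub-agronomic: it alters floral "
      "chemistry without killing plants)")
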