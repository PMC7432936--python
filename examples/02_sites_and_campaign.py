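"""Place monitoring sites and simulate the three-season campaign.

41 gas (NO2/SO2) sites and 21 PM sites — a subset of the gas sites plus a
continuously measured reference site between the regions — each measured
over one 2-week period per season (winter, spring, summer). Records carry
the simulator's ground truth alongside the noisy measured value.
"""

from collections import Counter

import airlur as al

scene = al.generate_city(seed=1)
sites = al.place_sites(scene, seed=3)
truth = al.default_truth_model()
campaign = al.simulate_campaign(scene, truth, sites, seed=7)

print(f"{len(sites)} gas sites, "
      f"{sum(1 for s in sites if 'pm' in s.measures)} also measure PM")
print("site types:", dict(Counter(s.site_type for s in sites)))

rec = campaign.records
primaries = rec[rec["flag"] == ""]
print(f"{len(rec)} records total "
      f"({(rec['flag'] == 'blank').sum()} blanks, "
      f"{(rec['flag'] == 'duplicate').sum()} duplicates, "
      f"{rec['flag'].isin(['stolen', 'outlier']).sum()} lost to dropout)")

print("\nseason means of raw 2-week records (ug/m3):")
print(primaries.groupby(["pollutant", "season"])["value_ugm3"].mean()
      .unstack()[["summer", "spring", "winter"]].round(1))
# winter exceeds spring exceeds summer for every pollutant: stagnant winter
# conditions concentrate pollution, summer convection disperses it

ref = campaign.references["NO2"]
print(f"\nreference-site NO2: {len(ref.values)} contiguous periods, "
      f"annual mean {ref.annual_mean:.1f} ug/m3, "
      f"winter mean {ref.season_mean('winter'):.1f} ug/m3")
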