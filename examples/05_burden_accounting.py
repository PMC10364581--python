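"""From deaths and prevalence to YLLs, YLDs, DALYs and standardised rates.

Years of life lost are deaths times the standard remaining life
expectancy at the age of death; years lived with disability are sequela
prevalence times disability weight (comorbidity-corrected); DALYs are
their sum. Age-standardised rates weight age-specific rates by a standard
population built from locations above five million inhabitants.
"""

import numpy as np
import pandas as pd

from diabem import DrawSet, LifeTable, Sequela
from diabem.burden import age_standardise, build_standard_population, \
    compute_daly, compute_yld, compute_yll, rate_per_100k

ages = np.arange(0.0, 111.0)
life_table = LifeTable(ages=ages, ex=np.maximum((88.9 - ages) * 0.97, 2.0))

index = pd.DataFrame({
    "location": "A", "age_start": [45.0, 65.0], "age_end": [50.0, 70.0],
    "sex": "female", "year": 2021,
})
deaths = DrawSet.constant(index, np.array([120.0, 480.0]), 100)
prevalence = DrawSet.constant(index, np.array([0.09, 0.22]), 100)
population = index.copy()
population["value"] = [400_000.0, 250_000.0]

sequelae = [
    Sequela("neuropathy", 0.133, 0.20),
    Sequela("diabetic foot", 0.165, 0.06),
    Sequela("lower limb amputation", 0.164, 0.02),
    Sequela("vision loss due to retinopathy", 0.184, 0.04),
]

yll = compute_yll(deaths, life_table)
yld = compute_yld(prevalence, sequelae, population, background_ylds_per_capita=0.10)
daly = compute_daly(yll, yld)
print(f"YLLs : {yll.total().mean():>12,.0f}")
print(f"YLDs : {yld.total().mean():>12,.0f}")
print(f"DALYs: {daly.total().mean():>12,.0f}  (= YLL + YLD per draw and cell)")

rates = rate_per_100k(daly, population)
print("\ncrude DALY rates per 100 000:",
      np.round(rates.draws.mean(axis=1), 1))

std_pop = pd.DataFrame({
    "location": "big", "age_start": [45.0, 65.0], "value": [6e6, 2e6],
})
std = build_standard_population(std_pop)
as_rate = age_standardise(rates, std)
print(f"age-standardised DALY rate: {as_rate.draws.mean():.1f} per 100 000 "
      f"(weights {np.round(std.weights, 2)})")
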