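"""Generate a synthetic epidemiological world and export it as tidy CSV.

The world embeds a known truth (type-specific prevalence is the
illness-death solution of known rate curves) plus noisy observations:
survey prevalence under four case definitions and death counts with 55%
of deaths coded to unspecified diabetes type.
"""

from pathlib import Path

from diabem import WorldConfig, make_world, simulate_death_data, \
    simulate_prevalence_surveys
from diabem.io import write_table

out_dir = Path("scratch/world_export")
out_dir.mkdir(parents=True, exist_ok=True)

config = WorldConfig(n_locations=3, seed=7)
world = make_world(config)

surveys = simulate_prevalence_surveys(
    world, ["fpg_ref", "hba1c", "ogtt"], noise=0.02, years=[2000, 2021]
)
deaths = simulate_death_data(world, config.unspecified_death_fraction)

write_table(world.population, out_dir / "population.csv", measure="population")
write_table(surveys.drop(columns="is_outlier"), out_dir / "surveys.csv",
            measure="prevalence")
deaths.to_csv(out_dir / "deaths.csv", index=False)

truth = world.truth_table("total")
peak = truth[truth["year"] == 2021].groupby("age_start")["value"].mean()
print(f"locations: {world.locations}")
print(f"survey datapoints: {len(surveys)}  (definitions: fpg_ref, hba1c, ogtt)")
print(f"mean total prevalence at ages 75-79 in 2021: {peak.loc[75.0]:.1%}")
unspec = deaths["unspecified"].sum() / deaths["total"].sum()
print(f"deaths coded to unspecified type: {unspec:.1%} "
      "(the redistribution stage will reassign these)")
print(f"files written under {out_dir}/")
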