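"""Does surrounding high-intensity land use modify assemblage trends?

Simulates a community whose cold-associated (low-STI) assemblage declines
faster where more of the 2-km buffer is arable+urban (interaction -0.5
log-abundance per year per unit proportion), computes buffer metrics for
all land-use combinations at two radii, and lets AIC pick the land-use
definition and scale of effect before reporting the fitted interaction.
"""

from ctiscape import (
    HighIntensityCombo,
    community_index_table,
    filter_site_years,
    filter_sites,
    metrics_for_all_sites,
    select_best,
)
from ctiscape.experiments import bird_like_config
from ctiscape.synthetic import simulate_dataset

config = bird_like_config(
    seed=3,
    n_sites=50,
    n_species=40,
    landuse_interaction={"low": -0.5, "medium_low": 0.0, "medium_high": 0.0, "high": 0.0},
    sigma_slope=0.0,
)
ds = simulate_dataset(config)
community = community_index_table(
    filter_sites(filter_site_years(ds.abundance_table)), ds.sti_table
)
metrics = metrics_for_all_sites(
    ds.grid, ds.site_table,
    radii=(500.0, 2000.0),
    combos=HighIntensityCombo.all_combos(include_sea_variants=False),
)

table, best = select_best(
    community, metrics, ds.temperature_table, "low",
    combos=HighIntensityCombo.all_combos(include_sea_variants=False),
    radii=(500.0, 2000.0), site_table=ds.site_table,
)
print(table[["combo", "radius", "aic", "delta_aic"]].sort_values("delta_aic").head(5))
coef, se, z, p = best.interaction_landuse
print(f"\nbest model: {best.combo.label} at {best.radius / 1000:g} km")
print(f"Year x land-use interaction: {coef:+.3f} +/- {se:.3f} (z={z:.1f}, p={p:.2g})")
print(f"R2: marginal {best.marginal_r2:.3f}, conditional {best.conditional_r2:.3f}")
print("\nThe negative interaction means cold-associated abundance falls faster"
      "\nat sites surrounded by more high-intensity land; the generating"
      "\ncombination (arable+urban at 2 km) should top the AIC ranking.")
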