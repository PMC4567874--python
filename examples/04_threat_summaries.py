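"""Threat summaries: category occupancy, proximity, gradient overlap.

Summarises naive occupancy per fish-status category on a Nevada-style
survey, measures what fraction of frog observations lie within set
distances of streams, and quantifies how strongly two species overlap
along the shoreline-density gradient.
"""

from npmrocc import (
    gradient_overlap,
    moving_window_density,
    proximity_fractions,
    rasterize_line_length,
)
from npmrocc.presets import nevada_profile, nevada_surface
from npmrocc.simulate import LandscapeConfig, generate_landscape, generate_survey
from npmrocc.threats import category_occupancy

table = generate_survey(nevada_profile(), nevada_surface(), seed=1)
summary = category_occupancy(table, "fish_status")
print("occupancy by fish status:")
for _, row in summary.table.iterrows():
    print(f"  {row['category']:<10} rate={row['rate']:.3f} "
          f"share of occupied={row['share']:.3f} (n={row['n']})")

config = LandscapeConfig(observation_counts={"frog": 60, "bullfrog": 40})
bundle = generate_landscape(config, seed=1)
prox = proximity_fractions(bundle.observations["frog"], bundle.streams,
                           radii=[1.0, 5.0, 20.0])
print("\nfrog observations within distance of any stream:")
for radius, fraction in prox.as_dict().items():
    print(f"  {radius:>4.0f} km: {fraction:.0%}")

density = moving_window_density(rasterize_line_length(bundle.streams,
                                                      bundle.grid))
overlap = gradient_overlap(bundle.observations,
                           {"shoreline_density": density})
coef = overlap["shoreline_density"].overlaps[("bullfrog", "frog")]
print(f"\nfrog/bullfrog overlap along shoreline density: {coef:.2f}")
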