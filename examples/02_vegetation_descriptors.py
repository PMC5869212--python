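"""Field-based descriptors from one cover-board plot.

A plot is measured at 17 positions (centre + 4 per cardinal direction)
in 10 foliage height classes.  The script builds a plot with dense
understorey and a patchy canopy and prints the derived descriptors.
"""

import numpy as np

from greenmig import VegetationProfile, summarize_plot
from greenmig.field_vegetation import HEIGHT_CLASSES

rng = np.random.default_rng(1)

# touch probability profile: dense below 2 m, thinning towards the canopy
probs = np.array([0.9, 0.8, 0.6, 0.5, 0.4, 0.3, 0.2, 0.2, 0.4, 0.3])
touches = (rng.random((17, 10)) < probs).astype(int)

descriptors = summarize_plot(
    VegetationProfile(touches),
    ground_cover_pct=rng.uniform(60, 95, 17),
    canopy_cover_pct=rng.uniform(20, 60, 17),
    vegetation_height_m=rng.uniform(8, 18, 17),
    dbh_m=[0.12, 0.22, 0.34, 0.41, 0.28],
)

print("clutter per height class (proportion of 17 positions touched):")
for cls, c in zip(HEIGHT_CLASSES, descriptors.clutter):
    print(f"  {cls:>6} m : {c:.2f}")
print(f"vertical heterogeneity (Shannon H): {descriptors.vertical_heterogeneity:.3f} nats")
print(f"ground cover: {descriptors.ground_cover:.1f} %  canopy cover: {descriptors.canopy_cover:.1f} %")
print(f"trees (DBH > 0.16 m): {descriptors.tree_density}   large trees (> 0.30 m): {descriptors.n_large_trees}")
print(f"mean DBH of large trees: {descriptors.mean_dbh:.2f} m")
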