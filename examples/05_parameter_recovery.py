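"""Does the activity model recover the generator's coefficients?

Simulates one default study (180 sites, 9 green-space types), fits the
Gaussian mixed model for edge-space-forager activity on the generating
covariates, and compares the estimates with the known truth.
"""

import pandas as pd

from greenmig import fit_activity_model, log_activity, site_summaries
from greenmig.synthetic_data import (
    DEFAULT_GROUP_EFFECTS,
    GeneratorConfig,
    generate_bat_surveys,
    generate_design,
    _zscore,
)

cfg = GeneratorConfig(seed=12)
sites = generate_design(cfg)
records, nights = generate_bat_surveys(sites, cfg)
print(f"{len(sites)} sites, {len(nights)} survey nights, {len(records)} call records")

responses = sites[["site_id"]].merge(site_summaries(records), on="site_id", how="left").fillna(0)
X = pd.DataFrame(
    {
        "canopy_complexity": _zscore(sites["c_top"].to_numpy()),
        "ground_cover": _zscore(sites["g"].to_numpy()),
        "size_class": _zscore(sites["size_class"].to_numpy()),
    }
)
fit = fit_activity_model(
    log_activity(responses["activity_edge"]), X, sites["green_space_type"].to_numpy()
)

truth = DEFAULT_GROUP_EFFECTS["edge"]
print(f"\n{'term':<20}{'truth':>8}{'estimate':>10}{'SE':>8}")
for term, key in [("canopy_complexity", "mig_top"), ("ground_cover", "ground"),
                  ("size_class", "size")]:
    print(f"{term:<20}{truth[key]:>8.2f}{fit.params[term]:>10.3f}{fit.bse[term]:>8.3f}")
print(f"\nrandom-intercept variance (green-space type): {fit.random_intercept_variance:.3f}")
print("Estimates should sit within a few SE of the truth: the survey")
print("reduction (nightly medians, species allocation) preserves the model.")
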