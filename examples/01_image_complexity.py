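"""Mean information gain of two contrasting scenes.

Builds a smooth 'mown lawn' image and a spatially random 'dense canopy'
image and prints their MIG.  MIG is (H_joint - H_marginal) / ((k-1) ln M)
over 2x2 pixel neighbourhoods of the HSV value channel: near 0 for
uniform scenes, near 1 for spatially random ones.
"""

import numpy as np

from greenmig import mig_of_image

rng = np.random.default_rng(0)


def gray(v01):
    g = np.round(v01 * 255).astype(np.uint8)
    return np.repeat(g[:, :, None], 3, axis=2)


# a lawn: gentle vertical brightness gradient, no fine structure
yy = np.linspace(0.35, 0.65, 256)[:, None] * np.ones((1, 256))
lawn = gray(yy)

# a canopy: independent pixel-scale light/shadow speckle
canopy = gray(rng.random((256, 256)))

for name, img in [("lawn", lawn), ("canopy", canopy)]:
    res = mig_of_image(img, m=4)
    print(
        f"{name:>6}: MIG = {res.mig:.3f} "
        f"(H_marginal = {res.h_marginal:.3f}, H_joint = {res.h_joint:.3f} nats, M = {res.m})"
    )

print("\nThe lawn is nearly ordered (MIG ~ 0); the canopy speckle is")
print("spatially random (MIG ~ 1). Real vegetation photographs fall in between.")
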