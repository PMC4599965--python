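"""Recovery of a skewed latent distribution by the empirical histogram.

Simulates abilities from the standardized skew-normal (shape 10, skewness
~0.96), fits the 2PL with EH weights, and prints the estimated weights next
to the binned generating sample together with their Earth Mover's Distance,
and the same comparison for a deliberately misspecified MML fit (normal
weights held fixed).
"""

import numpy as np

from ehirt import (
    AbilitySpec,
    ConvergenceSettings,
    default_item_bank,
    fit,
    generate_responses,
    make_grid_points,
    normal_grid,
    sample_abilities,
)
from ehirt.metrics import emd, sample_to_grid

bank = default_item_bank()
abilities = sample_abilities(1000, AbilitySpec("skew_normal", shape=10.0), seed=21)
x = generate_responses(bank, abilities, seed=22).x.astype(float)
points = make_grid_points()
sample_w = sample_to_grid(abilities.z, points)

print("support:", np.array2string(points, precision=2))
print("sample :", np.array2string(sample_w, precision=3))
for method in ("eh", "mml"):
    res = fit(
        x, np.ones(bank.k), np.zeros(bank.k), normal_grid().weights,
        ConvergenceSettings(criterion=1e-3, method=method),
    )
    d = emd(res.grid.weights, sample_w, points)
    print(f"{method}    :", np.array2string(res.grid.weights, precision=3),
          f" EMD = {d:.3f}")

# The EH weights track the asymmetric sample histogram (mass piled left of
# zero, long right tail) and give the smaller EMD; the fixed normal weights
# of MML cannot adapt, so their distance to the skewed sample is larger.
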