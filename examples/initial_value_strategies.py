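"""Compare initial-value strategies on one dataset at two criteria.

Fits the empirical-histogram 2PL to the same response matrix under all
four latent-weight starting strategies, at the loose (1e-2) and tight
(1e-5) convergence criteria, and prints the test-level parameter errors,
cycle counts, and the Earth Mover's Distance between the estimated latent
distribution and the binned generating ability sample.
"""

import numpy as np

from ehirt import (
    AbilitySpec,
    default_item_bank,
    fit_path,
    generate_responses,
    init_items,
    init_weights,
    make_grid_points,
    sample_abilities,
)
from ehirt.metrics import emd, sample_to_grid

bank = default_item_bank()
abilities = sample_abilities(1000, AbilitySpec("normal"), seed=11)
x = generate_responses(bank, abilities, seed=12).x.astype(float)
points = make_grid_points()
true_w = sample_to_grid(abilities.z, points)

a0, b0 = init_items("default", x)  # CTT starts for the items throughout
rng = np.random.default_rng(13)

print(f"{'weights':>9} {'criterion':>10} {'cycles':>7} {'mae_a':>7} {'mae_b':>7} {'EMD':>7}")
for ild in ("uniform", "default", "est", "shortrun"):
    w0 = init_weights(ild, x, points, rng=rng)
    path = fit_path(x, a0, b0, w0, [1e-2, 1e-5], method="eh", points=points)
    for crit in (1e-2, 1e-5):
        res = path[crit]
        mae_a = np.abs(res.a_hat - bank.a).mean()
        mae_b = np.abs(res.b_hat - bank.b).mean()
        d = emd(res.grid.weights, true_w, points)
        print(f"{ild:>9} {crit:>10g} {res.n_cycles:>7d} {mae_a:>7.3f} {mae_b:>7.3f} {d:>7.3f}")

# Expected pattern: at 1e-2 the initial weights still show through (small
# EMD for 'default'/'est'); at 1e-5 all strategies converge to similar item
# parameters but the estimated latent histogram has drifted away from the
# generating sample, so EMD is larger.
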