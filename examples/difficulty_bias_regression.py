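"""Relate per-item difficulty bias to latent density and true difficulty.

Runs repeated EH fits under both true latent distributions, computes each
item's difficulty bias across replications, and regresses the pooled
per-item biases on the true latent density at the item's difficulty and on
the difficulty itself (the scale-expansion effect).  Prints the
correlations, coefficients and R-squared.
"""

import numpy as np
from scipy import stats

from ehirt import (
    AbilitySpec,
    ConvergenceSettings,
    default_item_bank,
    fit,
    generate_responses,
    init_items,
    normal_grid,
    sample_abilities,
)
from ehirt.metrics import bias
from ehirt.simulate import skew_normal_population_moments
from ehirt.study import bias_regression

N_REPS = 30
bank = default_item_bank()
w0 = normal_grid().weights

rows_bias, rows_density = [], []
for family in ("normal", "skew_normal"):
    spec = AbilitySpec(family, shape=10.0)
    estimates = []
    for rep in range(N_REPS):
        abilities = sample_abilities(1000, spec, seed=1000 + rep)
        x = generate_responses(bank, abilities, seed=2000 + rep).x.astype(float)
        a0, b0 = init_items("default", x)
        res = fit(x, a0, b0, w0, ConvergenceSettings(criterion=1e-2, method="eh"))
        estimates.append(res.b_hat)
    rows_bias.append(bias(np.array(estimates), bank.b).per_item)
    if family == "normal":
        rows_density.append(stats.norm.pdf(bank.b))
    else:
        # density of the standardized skew-normal at each difficulty
        mu, sd = skew_normal_population_moments(10.0)
        rows_density.append(stats.skewnorm.pdf(bank.b * sd + mu, 10.0) * sd)

b_bias = np.concatenate(rows_bias)
density = np.concatenate(rows_density)
b_true = np.tile(bank.b, 2)

print("r(bias, density)    =", round(np.corrcoef(b_bias, density)[0, 1], 2))
print("r(bias, difficulty) =", round(np.corrcoef(b_bias, b_true)[0, 1], 2))
params, r2 = bias_regression(b_bias, density, b_true)
print(params.round(3))
print("R^2 =", round(r2, 2))
print("Interpretation: the dominant signal is scale expansion - signed "
      "difficulty bias grows with the true difficulty, so extreme items "
      "drift outward. The density term captures any additional "
      "information effect of the generating distribution; its weight "
      "here is small once difficulty is in the model.")
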