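# ehirt

Monte Carlo machinery for studying how **initial values** and the **EM
convergence criterion** affect item parameter bias, item-characteristic-curve
(ICC) recovery, and recovery of the latent ability distribution in the
two-parameter logistic (2PL) IRT model — estimated either by standard
marginal maximum likelihood (MML, normal latent distribution assumed) or by
the **empirical histogram** (EH) method, in which the latent distribution is
a set of weights at fixed support points re-estimated in every EM cycle.

It is aimed at psychometricians and methodologists who want an open,
testable Bock–Aitkin EM implementation whose convergence control, starting
values and latent-distribution handling are all explicit and scriptable,
instead of buried in closed-source estimation software.

## The model and the study

The 2PL gives the probability of a correct response of testee *j* to item
*i* as

```
pi_i(z_j) = exp[a_i (z_j - b_i)] / (1 + exp[a_i (z_j - b_i)])
```

with discrimination *a_i*, difficulty *b_i*, ability *z_j*. Estimation is
Bock–Aitkin EM over Q = 10 equally spaced support points on [-4, 4]: the
E-step computes each testee's posterior over the support points, the M-step
refits each item by concave Newton iterations, and — in EH mode — replaces
the latent weights by the mean posterior. Stopping is controlled by the
largest between-cycle change in any item parameter (criteria 1e-2 … 1e-5,
cycle cap 10 000).

The full factorial experiment crosses

| factor | levels |
|---|---|
| initial item parameters (iip) | true, default (CTT), const (a=1, b=0), shortrun |
| initial latent weights (ild, EH only) | uniform, default (normal), est (CTT score histogram), shortrun |
| true latent distribution (tld) | standard normal, standardized skew-normal (shape 10, skewness ≈ 0.96) |
| sample size (n) | 250, 500, 1000 |
| convergence criterion | 1e-2, 1e-3, 1e-4, 1e-5 |

with seed sharing: every estimation-side condition inside one
(tld, n, replication) cell is fit to the identical response matrix.
Outcomes are per-item and test-level parameter bias, the area between true
and estimated ICCs on [-10, 10], and the Earth Mover's Distance (EMD)
between the estimated latent histogram and the binned generating ability
sample. Effect sizes are eta-squared from fixed-effects ANOVAs on per-cell
replication means (main effects + two-way interactions).

## Worked example

```python
import numpy as np
from ehirt import (AbilitySpec, ConvergenceSettings, default_item_bank, fit,
                   generate_responses, normal_grid, sample_abilities)

bank = default_item_bank()                       # 20 items, a in [0.5, 3.0], b in [-2.5, 2.5]
abilities = sample_abilities(1000, AbilitySpec("normal"), seed=1)
x = generate_responses(bank, abilities, seed=2).x.astype(float)

res = fit(x, np.ones(bank.k), np.zeros(bank.k), normal_grid().weights,
          ConvergenceSettings(criterion=1e-4, method="eh"))
print(res.n_cycles, np.abs(res.a_hat - bank.a).mean(), np.abs(res.b_hat - bank.b).mean())
```

prints `827 0.113... 0.134...`: the EH fit converged after 827 EM cycles
with mean absolute errors of about 0.11 (discrimination) and 0.13
(difficulty) at n = 1000 — typical recovery at this sample size. The
scripts in `examples/` walk through the other capabilities (initial-value
strategies, the factorial study with its EMD and eta-squared tables, the
difficulty-bias regression); each prints the numbers it computes and a line
on what they mean. A full-scale run is

```python
from ehirt.study import StudyConfig, run_study, summarize_tables
records = run_study(StudyConfig(n_reps=100, master_seed=0))   # hours, not minutes
tables = summarize_tables(records)
```

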