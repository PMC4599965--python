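# Methods

## Model and estimator

The two-parameter logistic model gives the probability of a correct
response as `pi_i(z) = expit(a_i (z - b_i))` with discrimination `a_i > 0`
and difficulty `b_i` on the latent scale. Item parameters are estimated by
marginal maximum likelihood via Bock–Aitkin EM on a fixed grid of Q equally
spaced support points (default Q = 10 on [-4, 4], spacing 8/9; the grid
range is a conventional default — the design only fixes "10 equally spaced
points", and [-4, 4] covers ±4 SD of a standardized latent trait).

Each EM cycle:

1. **E-step.** For every testee, the posterior over support points
   `P(z_q | x_j) ∝ W_q L_jq` is computed entirely in log space (the
   per-pattern likelihood `L_jq` underflows double precision for long
   tests otherwise). Expected counts `m_q = Σ_j P(z_q|x_j)` and
   `r_iq = Σ_j x_ij P(z_q|x_j)` follow.
2. **M-step, items.** Each item maximizes its expected complete-data
   Bernoulli log-likelihood over the grid. The problem is solved in the
   slope–intercept parameterization (`logit = alpha z + beta`), where the
   objective is concave, by Newton iterations (max 50) with per-item step
   halving (max 40 halvings) so the objective never decreases. Divergent
   items (expected counts all-correct/all-incorrect) are clamped to
   `a ∈ [0.05, 10]`, `b ∈ [-10, 10]` and flagged.
3. **M-step, weights (EH only).** `W_q ← mean_j P(z_q | x_j)`. Weights are
   never floored; zero weights are legitimate and handled in log space.

Standard MML keeps the weights fixed at their initial (normal) values.

**Stopping.** The run stops when the largest absolute between-cycle change
over the item parameters (weights excluded — the common reading of the
"largest parameter change" rule in IRT estimation software) falls below the
criterion, or at the cycle cap (default 10 000). Because the iteration is
deterministic given data and starts, a single pass that snapshots the state
at the first crossing of each of several nested criteria is exactly
equivalent to separate runs per criterion; `fit_path` exploits this and the
equivalence is asserted in the tests.

## Metric identification

In EH mode the likelihood constrains location and scale of the latent
metric only weakly (a near-ridge), so the metric drifts during iteration.
Estimates are reported on the identified mean-0/SD-1 metric: when a fit is
reported, `standardize_metric` transforms the items exactly
(`a ← a·s`, `b ← (b - m)/s`) and re-expresses the weights on the fixed
grid by monotone piecewise-linear interpolation of the transformed
cumulative weights (each transformed support point carries its mass as a
uniform cell; the CDF is read off at the original cell edges). This
rebinning is mass-preserving and reduces to the identity when the
distribution is already standard.

Standardization is applied **at reporting time, not inside every cycle**.
Re-expressing weights on a fixed grid is necessarily approximate, and doing
it inside the loop injects that approximation into the EM ascent: measured
perturbations of ~1e-5 per cycle in the log-likelihood, visibly breaking
monotonicity. Keeping the iteration pure preserves the exact EM guarantee
(the test suite asserts a non-decreasing log-likelihood trace within 1e-8
on every fit) while the reported estimates and weights are identical in
interpretation. The grid SD of a reported EH fit is 1 only up to rebinning
error on the coarse grid (typically a few percent).

## Initial values

*Items.* `true` copies the generating parameters; `const` uses a = 1,
b = 0; `default` builds classical-test-theory starts: the biserial
item-total correlation (point-biserial converted by
`r_bis = r_pb √(pq)/φ(Φ⁻¹(p))`, item included in the total, capped at
±0.999) gives `a0 = 1.7 r_bis/√(1-r_bis²)` floored at 0.3, and
`b0 = -logit(p)/a0` — the difficulty at which an average-ability testee
would match the observed proportion correct. The floor and the difficulty
rule are documented stand-ins: the reference software's exact CTT-to-(a,b)
transformation is not public.

*Weights.* `uniform` = 1/Q; `default` = standard-normal density at the
support points, normalized; `est` = relative frequencies of
CTT-discrimination-weighted sum scores, standardized to mean 0/SD 1 and
assigned to the nearest support point; `shortrun` = the weights of the
multi-start winner.

*Shortrun.* 50 independent random starts (`a ~ LogNormal(0, 0.5)`,
`b ~ N(0,1)`, weights ~ symmetric Dirichlet(1) — positive, dispersed,
proper), each run for exactly 10 EM cycles with no convergence check; the
candidate with the highest marginal log-likelihood wins. The short runs use
the same method (EH or MML) as the fit they seed.

## Synthetic data

The generator emulates a 20-item achievement test: the packaged fixture
bank spans easy to very difficult items (b from -2.5 to 2.5) and low to
very high discriminations (a from 0.5 to 3.0), anchored by one very highly
discriminating item (a = 3.00) and one very difficult item (b = 2.43) so
that single-item analyses of extreme-item sensitivity have their reference
items. The fixture is synthetic — the original test's parameters are not
public — so single-item results are qualitative, not item-for-item
comparable.

Abilities come from N(0,1) or from an Azzalini skew-normal with shape 10,
standardized by its **population** mean and SD (δ = α/√(1+α²),
μ = δ√(2/π), σ² = 1 - 2δ²/π), so the generating distribution itself is
exactly mean-0/SD-1 and its skewness is the analytic 0.9556 ("about
0.96"). Per-sample standardization would make every sample exactly
mean-0/SD-1 but distort the target distribution; the population convention
was chosen and is asserted in tests (sample moments concentrate at 0/1 at
the usual √n rate).

Responses: `x_ij = 1` iff `pi_i(z_j) > u_ij`, `u_ij ~ U(0,1)`.

**Seed sharing.** `condition_seed(tld, n, rep, master)` packs its arguments
injectively into one integer (21-bit fields). All estimation-side factors
(initial values, criterion, method) within a cell reuse the cell's dataset,
so their comparison is paired, never confounded with sampling noise.

What the generator does **not** emulate: guessing (no lower asymptote),
multidimensionality, local dependence, missing responses, or real item
banks' clustering of parameters. Passing tests therefore demonstrate
correctness of the estimator and the study machinery under the 2PL's own
assumptions, not robustness to their violation.

## Outcome measures

* **Bias** per item = mean signed error across replications; test-level =
  mean of absolute per-item biases.
* **ICC bias** = area between true and estimated ICC on [-10, 10]. Two 2PL
  curves cross at most once, so the integral splits into at most two signed
  pieces with a softplus antiderivative — computed in closed form (exact;
  verified against adaptive quadrature and a dense trapezoid oracle in
  tests).
* **EMD** between two histograms on the shared grid = spacing-weighted sum
  of absolute cumulative-weight differences (the 1-D optimal-transport
  closed form; verified against a linear-program oracle). The reference
  distribution is the **binned generating ability sample** (nearest support
  point), not the analytic density, so EMD measures recovery of the
  realized sample. A `scale_by_spacing=False` variant reports grid-step
  units.

## Analyses

Eta-squared tables come from fixed-effects OLS ANOVAs on the per-cell
replication means with main effects and all two-way interactions (no
higher-order terms, to avoid overfitting a design with one value per
cell); η²(term) = SS(term)/SS(total), residual takes the remainder, so
each column sums to 1. p-values are deliberately not reported: with cell
means as data they are a function of how many cells one chooses to
simulate. The EH design has 96 cells and residual df 57; the MML design 24
cells and residual df 6. The EMD summary table averages over initial item
parameters and sample size (the summary shows criterion × initial weights
within each true-distribution block; this aggregation is an explicit
choice). The normal-vs-skewed contrast uses Welch's t with Satterthwaite
df and Cohen's d (pooled SD). The difficulty-bias regression is OLS of
per-item difficulty bias on the generating density at the item's
difficulty and the true difficulty.

Non-converged fits are flagged in the records and included in aggregates.

## Problem sizes and numerical choices

The test suite runs the full 4×4×3×2×4 factor grid (both methods) at 25
replications — the scale at which the directional patterns (EMD worsening
with tighter criteria, `est` weights best at 1e-5, MML's indifference to
item starts, sample-size dominance of ICC bias) are stable — and the
acceptance script uses 25 replications of the criterion-1e-2 grid. The
full published design (100 replications) runs with the same code by
setting `n_reps=100`. The EM inner loop has a compiled (numba) and a
reference (numpy) implementation; they agree to ~1e-14 per cycle and give
identical cycle counts on shared fits. Posterior normalization failures
(all-zero rows) are impossible by construction in log space; degenerate
latent distributions (zero spread) raise rather than standardize.

## Known limitations

* The proprietary reference estimator's Bayesian priors and its post-EM
  Gauss–Newton polish are intentionally out of scope; cycle counts and the
  absolute magnitude of tight-criterion degradation therefore differ from
  published values even where directions agree. In particular, latent-
  distribution degradation at tight criteria is milder here (grand-mean
  EMD ≈ 0.11 rather than ≈ 0.5), and the sample-size share of ICC-bias
  variance is correspondingly a few points higher.
* The item bank is a constructed stand-in; single-item numbers are not
  comparable item-for-item with any published table.
* No 1PL/3PL, no missing data, no standard errors.
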