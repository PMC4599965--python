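"""Factorial Monte Carlo experiment driver and its analyses.

Five factors are crossed: initial item parameters (iip), initial latent
distribution (ild; empirical-histogram method only), true latent
distribution (tld), sample size (n), and EM convergence criterion.  Within
one (tld, n, replication) cell every estimation-side condition is fit to
the identical response matrix (shared seeds), so differences between
conditions are purely differences of the estimator, never of the data.

Analyses mirror the study design: eta-squared tables from fixed-effects
ANOVAs on per-cell replication means (main effects plus two-way
interactions only), Earth Mover's Distance summary tables, a Welch test
with Cohen's d for the normal-vs-skewed contrast, and a linear model of
per-item difficulty bias on the true latent density and true difficulty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .estimation import fit_path, make_grid_points, normal_grid
from .initialization import (
    IIP_LEVELS,
    ILD_LEVELS,
    init_items,
    init_weights,
    shortrun_init,
)
from .metrics import emd, icc_bias_items, sample_to_grid
from .simulate import (
    TLD_LEVELS,
    AbilitySpec,
    ItemBank,
    condition_seed,
    default_item_bank,
    generate_responses,
    sample_abilities,
)

__all__ = [
    "StudyConfig",
    "AnovaTable",
    "run_study",
    "aggregate_cells",
    "eta_squared_table",
    "welch_cohen",
    "bias_regression",
    "summarize_tables",
]

FACTORS_EH = ("iip", "ild", "n", "tld")
FACTORS_MML = ("iip", "n", "tld")


@dataclass
class StudyConfig:
    """Factor levels and run settings for the Monte Carlo experiment.

    Defaults are the full study design: all four item-start and weight-start
    strategies, both true latent distributions, sample sizes 250/500/1000,
    convergence criteria 1e-2 .. 1e-5, 100 replications, 10 support points,
    and an EM cycle cap of 10000.
    """

    iip_levels: Sequence[str] = IIP_LEVELS
    ild_levels: Sequence[str] = ILD_LEVELS
    tld_levels: Sequence[str] = TLD_LEVELS
    n_levels: Sequence[int] = (250, 500, 1000)
    criteria: Sequence[float] = (1e-2, 1e-3, 1e-4, 1e-5)
    methods: Sequence[str] = ("eh", "mml")
    n_reps: int = 100
    n_support: int = 10
    grid_span: tuple[float, float] = (-4.0, 4.0)
    max_em_cycles: int = 10_000
    skew_shape: float = 10.0
    shortrun_starts: int = 50
    shortrun_cycles: int = 10
    master_seed: int = 0
    bank: ItemBank | None = None

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("need at least one replication")
        if self.bank is None:
            self.bank = default_item_bank()


def _record(base, res, bank, true_w, points):
    row = dict(base)
    row["n_cycles"] = res.n_cycles
    row["converged"] = bool(res.converged)
    row["loglik"] = float(res.loglik_trace[-1])
    row["icc_bias"] = icc_bias_items(res.a_hat, res.b_hat, bank.a, bank.b).test_level
    if true_w is not None:
        row["emd"] = emd(res.grid.weights, true_w, points)
    else:
        row["emd"] = np.nan
    for i in range(bank.k):
        row[f"a_err_{i:02d}"] = res.a_hat[i] - bank.a[i]
        row[f"b_err_{i:02d}"] = res.b_hat[i] - bank.b[i]
    return row


def run_study(config: StudyConfig, progress: bool = False) -> pd.DataFrame:
    """Run the full factorial experiment; one row per condition-cell x rep.

    Within each (tld, n, rep) cell a single response matrix is generated
    from the cell seed and reused by every (iip, ild, criterion, method)
    condition.  All criteria for one initial-value condition are obtained
    from a single EM pass with snapshots at each criterion crossing, which
    is exactly equivalent to separate runs because the iteration is
    deterministic.
    """
    cfg = config
    bank = cfg.bank
    points = make_grid_points(cfg.n_support, cfg.grid_span)
    norm_w = normal_grid(cfg.n_support, cfg.grid_span).weights
    rows: list[dict] = []
    for tld in cfg.tld_levels:
        spec = AbilitySpec(family=tld, shape=cfg.skew_shape)
        for n in cfg.n_levels:
            for rep in range(1, cfg.n_reps + 1):
                seed = condition_seed(tld, n, rep, cfg.master_seed)
                rng = np.random.default_rng(seed)
                abilities = sample_abilities(n, spec, rng)
                x = generate_responses(bank, abilities, rng).x.astype(float)
                true_w = sample_to_grid(abilities.z, points)

                shortruns: dict[str, object] = {}

                def get_shortrun(method: str):
                    if method not in shortruns:
                        tag = 0 if method == "eh" else 1
                        shortruns[method] = shortrun_init(
                            x,
                            points,
                            np.random.default_rng([seed, tag]),
                            method=method,
                            n_starts=cfg.shortrun_starts,
                            n_cycles=cfg.shortrun_cycles,
                        )
                    return shortruns[method]

                def item_start(iip: str, method: str):
                    if iip == "shortrun":
                        sr = get_shortrun(method)
                        return sr.a0.copy(), sr.b0.copy()
                    return init_items(iip, x, truth=bank)

                def weight_start(ild: str, method: str):
                    if ild == "shortrun":
                        return get_shortrun(method).w0.copy()
                    return init_weights(ild, x, points)

                if "eh" in cfg.methods:
                    for iip in cfg.iip_levels:
                        a0, b0 = item_start(iip, "eh")
                        for ild in cfg.ild_levels:
                            w0 = weight_start(ild, "eh")
                            path = fit_path(
                                x, a0, b0, w0, cfg.criteria,
                                method="eh", points=points,
                                max_em_cycles=cfg.max_em_cycles,
                            )
                            for crit, res in path.items():
                                base = dict(
                                    method="eh", iip=iip, ild=ild, tld=tld,
                                    n=n, criterion=crit, rep=rep,
                                )
                                rows.append(_record(base, res, bank, true_w, points))
                if "mml" in cfg.methods:
                    for iip in cfg.iip_levels:
                        a0, b0 = item_start(iip, "mml")
                        path = fit_path(
                            x, a0, b0, norm_w, cfg.criteria,
                            method="mml", points=points,
                            max_em_cycles=cfg.max_em_cycles,
                        )
                        for crit, res in path.items():
                            base = dict(
                                method="mml", iip=iip, ild="normal(fixed)",
                                tld=tld, n=n, criterion=crit, rep=rep,
                            )
                            rows.append(_record(base, res, bank, None, points))
            if progress:
                done = len(rows)
                print(f"[run_study] tld={tld} n={n}: {done} records", flush=True)
    return pd.DataFrame(rows)


def aggregate_cells(records: pd.DataFrame, method: str = "eh") -> pd.DataFrame:
    """Per-condition replication means of every outcome.

    Test-level bias follows the study definition: per-item signed errors are
    first averaged over replications within the cell, then their absolute
    values are averaged over items.  ICC bias and EMD are plain replication
    means of their per-replication test-level values.
    """
    df = records[records["method"] == method]
    if df.empty:
        raise ValueError(f"no records for method {method!r}")
    keys = ["iip", "ild", "n", "tld", "criterion"] if method == "eh" else [
        "iip", "n", "tld", "criterion"]
    a_cols = sorted(c for c in df.columns if c.startswith("a_err_"))
    b_cols = sorted(c for c in df.columns if c.startswith("b_err_"))
    g = df.groupby(keys, sort=True)
    out = pd.DataFrame(
        {
            "bias_a": g[a_cols].mean().abs().mean(axis=1),
            "bias_b": g[b_cols].mean().abs().mean(axis=1),
            "icc_bias": g["icc_bias"].mean(),
            "emd": g["emd"].mean(),
            "n_reps": g["rep"].count(),
            "n_cycles": g["n_cycles"].mean(),
        }
    ).reset_index()
    return out


@dataclass
class AnovaTable:
    """Fixed-effects eta-squared table: term, df, eta2 (rows sum to 1)."""

    table: pd.DataFrame

    def eta2(self, term: str) -> float:
        return float(self.table.loc[term, "eta2"])

    def df(self, term: str) -> int:
        return int(self.table.loc[term, "df"])


def eta_squared_table(
    cell_means: pd.DataFrame,
    response: str,
    factors: Sequence[str],
) -> AnovaTable:
    """Eta-squared ANOVA on a balanced full factorial of cell means.

    The model has all main effects and all two-way interactions of the
    given factors (no higher-order terms); eta-squared of a term is its sum
    of squares divided by the total (centered) sum of squares, and the
    residual row absorbs the remainder, so the eta2 column sums to 1.
    """
    df = cell_means.copy()
    sizes = [df[f].nunique() for f in factors]
    expected = int(np.prod(sizes))
    if len(df) != expected or df.duplicated(subset=list(factors)).any():
        raise ValueError(
            f"need exactly one mean per cell of the {'x'.join(map(str, sizes))} design"
        )
    terms = [f"C({f})" for f in factors]
    terms += [f"C({f1}):C({f2})" for f1, f2 in combinations(factors, 2)]
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        aov = anova_lm(model, typ=1)
    ss_total = float(aov["sum_sq"].sum())
    rename = {f"C({f})": f for f in factors}
    rename.update({f"C({f1}):C({f2})": f"{f1}:{f2}" for f1, f2 in combinations(factors, 2)})
    aov = aov.rename(index=rename)
    table = pd.DataFrame(
        {
            "df": aov["df"].astype(int),
            "eta2": aov["sum_sq"] / ss_total if ss_total > 0 else 0.0,
        }
    )
    return AnovaTable(table=table)


def welch_cohen(group1, group2):
    """Welch's unequal-variance t test and Cohen's d (pooled SD).

    Returns ``(t, df, p, d)`` with Satterthwaite degrees of freedom.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    m1, m2 = g1.mean(), g2.mean()
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("both groups have zero variance")
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    d = (m1 - m2) / pooled if pooled > 0 else np.inf
    return float(t), float(df), float(p), float(d)


def bias_regression(item_bias, density_at_b, b_true):
    """OLS of per-item difficulty bias on true latent density and difficulty.

    Greater outward bias is expected where the latent density is low (little
    information) and where the true difficulty is extreme (scale expansion).
    Returns ``(params, r_squared)``; flags perfectly collinear predictors.
    """
    y = np.asarray(item_bias, dtype=float)
    x1 = np.asarray(density_at_b, dtype=float)
    x2 = np.asarray(b_true, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 items")
    X = np.column_stack([np.ones_like(y), x1, x2])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("collinear predictors")
    model = sm.OLS(y, X).fit()
    params = pd.Series(model.params, index=["intercept", "density", "difficulty"])
    return params, float(model.rsquared)


def summarize_tables(records: pd.DataFrame) -> dict:
    """Study summary tables from a long-format record set.

    Returns a dict with

    ``emd``
        mean EMD per (true distribution, criterion) x initial-weight
        condition, averaged over initial item parameters, sample sizes and
        replications (empirical-histogram fits only);
    ``eta_eh``
        {(measure, criterion): AnovaTable} for the empirical-histogram
        design (factors iip, ild, n, tld), measures bias_a / bias_b /
        icc_bias;
    ``eta_mml``
        same keyed tables for the fixed-normal design (factors iip, n, tld).
    """
    out: dict = {}
    eh = records[records["method"] == "eh"]
    if not eh.empty:
        cells = aggregate_cells(records, "eh")
        out["emd"] = cells.pivot_table(
            index=["tld", "criterion"], columns="ild", values="emd", aggfunc="mean"
        )
        eta = {}
        for crit in sorted(cells["criterion"].unique(), reverse=True):
            sub = cells[cells["criterion"] == crit]
            for measure in ("bias_a", "bias_b", "icc_bias"):
                eta[(measure, crit)] = eta_squared_table(sub, measure, FACTORS_EH)
        out["eta_eh"] = eta
    mml = records[records["method"] == "mml"]
    if not mml.empty:
        cells = aggregate_cells(records, "mml")
        eta = {}
        for crit in sorted(cells["criterion"].unique(), reverse=True):
            sub = cells[cells["criterion"] == crit]
            for measure in ("bias_a", "bias_b", "icc_bias"):
                eta[(measure, crit)] = eta_squared_table(sub, measure, FACTORS_MML)
        out["eta_mml"] = eta
    return out
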