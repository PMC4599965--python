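"""Marginal-maximum-likelihood EM estimation of the two-parameter logistic model.

The 2PL gives the probability of a correct response to item ``i`` by a
testee with latent ability ``z`` as

    pi_i(z) = exp[a_i (z - b_i)] / (1 + exp[a_i (z - b_i)])

with discrimination ``a_i > 0`` and difficulty ``b_i``.  Item parameters are
estimated by Bock-Aitkin EM over a fixed grid of equally spaced quadrature
(support) points.  Two variants are provided:

``mml``
    standard marginal maximum likelihood: the latent distribution is held
    fixed at its initial weights (normal weights in the usual setup).
``eh``
    empirical histogram: the weights at the support points are re-estimated
    in every maximization step, so the latent distribution is estimated
    jointly with the item parameters.  The latent metric is standardized to
    mean 0 / SD 1 whenever a fit is reported, which identifies the scale
    without perturbing the EM ascent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._kernels import HAVE_NUMBA, em_run

__all__ = [
    "LatentGrid",
    "ConvergenceSettings",
    "ExpectedCounts",
    "FitResult",
    "make_grid_points",
    "normal_grid",
    "response_probability",
    "marginal_log_likelihood",
    "e_step",
    "m_step_items",
    "m_step_weights",
    "standardize_metric",
    "em_cycles",
    "fit",
    "fit_path",
]

# Safeguard clamps for divergent item estimates (near-Heywood items).
A_MIN, A_MAX = 0.05, 10.0
B_MIN, B_MAX = -10.0, 10.0

_WEIGHT_SUM_TOL = 1e-12


def make_grid_points(n_points: int = 10, span: tuple[float, float] = (-4.0, 4.0)) -> np.ndarray:
    """Equally spaced support-point locations on the latent scale."""
    if n_points < 2:
        raise ValueError("need at least 2 support points")
    lo, hi = span
    if not hi > lo:
        raise ValueError("grid span must be increasing")
    return np.linspace(lo, hi, n_points)


@dataclass
class LatentGrid:
    """Discrete latent distribution: weights on equally spaced support points."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.points.ndim != 1 or self.points.shape != self.weights.shape:
            raise ValueError("points and weights must be 1-d arrays of equal length")
        if self.points.size < 1:
            raise ValueError("need at least one support point")
        d = np.diff(self.points)
        if np.any(d <= 0):
            raise ValueError("points must be strictly increasing")
        if d.size and not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
            raise ValueError("points must be equally spaced")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")
        # remove any residual rounding error so invariants hold exactly
        self.weights = self.weights / self.weights.sum()

    @property
    def spacing(self) -> float:
        return float(self.points[1] - self.points[0])

    def mean(self) -> float:
        return float(self.weights @ self.points)

    def sd(self) -> float:
        m = self.mean()
        return float(np.sqrt(self.weights @ (self.points - m) ** 2))


def normal_grid(n_points: int = 10, span: tuple[float, float] = (-4.0, 4.0)) -> LatentGrid:
    """Grid with standard-normal density weights (the usual MML default)."""
    pts = make_grid_points(n_points, span)
    w = np.exp(-0.5 * pts**2)
    return LatentGrid(pts, w / w.sum())


@dataclass
class ConvergenceSettings:
    """EM stopping rule: largest between-cycle item-parameter change."""

    criterion: float = 1e-2
    max_em_cycles: int = 10_000
    method: str = "eh"

    def __post_init__(self) -> None:
        if not self.criterion > 0:
            raise ValueError("criterion must be positive")
        if self.max_em_cycles < 1:
            raise ValueError("max_em_cycles must be >= 1")
        if self.method not in ("mml", "eh"):
            raise ValueError("method must be 'mml' or 'eh'")


@dataclass
class ExpectedCounts:
    """Bock-Aitkin E-step sufficient statistics.

    ``r[i, q]`` is the expected number of correct responses to item ``i``
    attributed to support point ``q``; ``m[q]`` is the expected number of
    testees at support point ``q``.
    """

    r: np.ndarray
    m: np.ndarray


@dataclass
class FitResult:
    a_hat: np.ndarray
    b_hat: np.ndarray
    grid: LatentGrid
    loglik_trace: np.ndarray
    n_cycles: int
    converged: bool
    final_change: float
    clamped: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def response_probability(a, b, z):
    """2PL probability of a correct response, overflow-safe (broadcasts)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b)) and np.all(np.isfinite(z))):
        raise ValueError("parameters and abilities must be finite")
    if np.any(a <= 0):
        raise ValueError("discrimination must be positive")
    out = expit(a * (z - b))
    return float(out) if out.ndim == 0 else out


def _log_item_probs(a: np.ndarray, b: np.ndarray, points: np.ndarray):
    """log pi and log(1-pi) for every item at every support point, (k, Q)."""
    u = a[:, None] * (points[None, :] - b[:, None])
    log_p = -np.logaddexp(0.0, -u)
    log_q = -np.logaddexp(0.0, u)
    return log_p, log_q


def _validate_weights(weights: np.ndarray) -> None:
    if np.any(weights < 0):
        raise ValueError("latent weights must be nonnegative")
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("latent weights must sum to 1")


def _e_step_arrays(a, b, points, weights, x):
    """Posterior weights and expected counts; all heavy math in log space.

    Returns (loglik, posteriors (n, Q), m (Q,), r (k, Q)).
    """
    log_p, log_q = _log_item_probs(a, b, points)
    # log L_jq = sum_i x_ij log p_iq + (1 - x_ij) log q_iq
    loglik_jq = x @ (log_p - log_q) + log_q.sum(axis=0)[None, :]
    with np.errstate(divide="ignore"):
        post_log = loglik_jq + np.log(weights)[None, :]
    top = post_log.max(axis=1, keepdims=True)
    ex = np.exp(post_log - top)
    denom = ex.sum(axis=1, keepdims=True)
    if np.any(denom <= 0) or not np.all(np.isfinite(denom)):
        raise FloatingPointError("zero posterior mass for some testee")
    post = ex / denom
    loglik = float((np.log(denom) + top).sum())
    m = post.sum(axis=0)
    r = x.T @ post
    return loglik, post, m, r


def marginal_log_likelihood(a, b, grid: LatentGrid, x) -> float:
    """Marginal log-likelihood of a binary response matrix over the grid.

    ``sum_j log sum_q W_q prod_i pi_iq^x_ij (1-pi_iq)^(1-x_ij)`` computed in
    log space.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    x = np.asarray(x, dtype=float)
    _validate_weights(grid.weights)
    ll, *_ = _e_step_arrays(a, b, grid.points, grid.weights, x)
    return ll


def e_step(a, b, grid: LatentGrid, x):
    """Expected counts and per-testee posterior distributions over the grid."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    x = np.asarray(x, dtype=float)
    _validate_weights(grid.weights)
    _, post, m, r = _e_step_arrays(a, b, grid.points, grid.weights, x)
    return ExpectedCounts(r=r, m=m), post


def _item_objective(alpha, beta, points, r, m):
    """Expected complete-data Bernoulli log-likelihood per item, (k,)."""
    u = alpha[:, None] * points[None, :] + beta[:, None]
    log_p = -np.logaddexp(0.0, -u)
    log_q = -np.logaddexp(0.0, u)
    return (r * log_p + (m[None, :] - r) * log_q).sum(axis=1)


def m_step_items(counts: ExpectedCounts, points, a, b, max_iter: int = 50, tol: float = 1e-10):
    """Per-item weighted logistic maximization (Bock-Aitkin M-step).

    Works in the slope-intercept parameterization ``logit = alpha z + beta``
    (``alpha = a``, ``beta = -a b``) where the objective is concave, using
    Newton steps with per-item step halving.  Every candidate is projected
    into the box a in [0.05, 10], b in [-10, 10] before it is evaluated, so
    accepted updates are always feasible and never decrease the objective
    (divergent items simply stick to the boundary and are flagged); this
    keeps the EM ascent property intact even for near-Heywood items.

    Returns ``(a_new, b_new, clamped_flags)``.
    """
    points = np.asarray(points, dtype=float)
    r, m = counts.r, counts.m
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    alpha = np.clip(a, A_MIN, A_MAX).copy()
    beta = -alpha * np.clip(b, B_MIN, B_MAX)
    f = _item_objective(alpha, beta, points, r, m)
    for _ in range(max_iter):
        u = alpha[:, None] * points[None, :] + beta[:, None]
        p = expit(u)
        resid = r - m[None, :] * p
        w2 = m[None, :] * p * (1.0 - p)
        g1 = (resid * points[None, :]).sum(axis=1)
        g0 = resid.sum(axis=1)
        h11 = (w2 * points[None, :] ** 2).sum(axis=1)
        h01 = (w2 * points[None, :]).sum(axis=1)
        h00 = w2.sum(axis=1)
        det = h11 * h00 - h01**2
        ok = det > 1e-12
        d_alpha = np.where(ok, (h00 * g1 - h01 * g0) / np.where(ok, det, 1.0), np.sign(g1) * 0.1)
        d_beta = np.where(ok, (h11 * g0 - h01 * g1) / np.where(ok, det, 1.0), np.sign(g0) * 0.1)
        step = np.ones_like(alpha)
        for _ in range(40):
            raw_a = alpha + step * d_alpha
            raw_b = beta + step * d_beta
            # project into the feasible box (in the natural a, b metric)
            cand_a = np.clip(raw_a, A_MIN, A_MAX)
            cand_b = -cand_a * np.clip(-raw_b / cand_a, B_MIN, B_MAX)
            f_new = _item_objective(cand_a, cand_b, points, r, m)
            worse = f_new < f - 1e-12
            if not worse.any():
                break
            step[worse] *= 0.5
        else:
            # no ascent found for some item: keep its current value
            stuck = f_new < f - 1e-12
            cand_a[stuck] = alpha[stuck]
            cand_b[stuck] = beta[stuck]
            f_new[stuck] = f[stuck]
        change = np.maximum(np.abs(cand_a - alpha), np.abs(cand_b - beta))
        alpha, beta, f = cand_a, cand_b, f_new
        if change.max() < tol:
            break
    a_new = alpha
    b_new = -beta / alpha
    clamped = (a_new <= A_MIN) | (a_new >= A_MAX) | (b_new <= B_MIN) | (b_new >= B_MAX)
    return a_new, b_new, clamped


def m_step_weights(posteriors: np.ndarray) -> np.ndarray:
    """Empirical-histogram weight update: average posterior over testees."""
    post = np.asarray(posteriors, dtype=float)
    w = post.mean(axis=0)
    return w / w.sum()


def standardize_metric(a, b, grid: LatentGrid):
    """Rescale the latent metric so the discrete distribution has mean 0, SD 1.

    Item parameters transform exactly (``a <- a s``, ``b <- (b - m)/s``); the
    weight distribution is re-expressed on the FIXED original support points
    by monotone piecewise-linear interpolation of the transformed cumulative
    weights: each transformed support point carries its mass as a uniform
    cell of the transformed spacing, and the resulting CDF is read off at
    the original grid-cell edges.  This is mass-preserving, reduces to the
    identity when the distribution is already standard, and accumulates any
    mass pushed beyond the grid ends at the end points.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mu = grid.mean()
    s = grid.sd()
    if not s > 1e-8:
        raise ValueError("degenerate latent distribution (zero spread)")
    a_new = a * s
    b_new = (b - mu) / s
    zp = (grid.points - mu) / s
    half = 0.5 * grid.spacing / s  # transformed half-cell width
    # ramp CDF: rises linearly across each transformed cell [zp_q-h, zp_q+h]
    cdf = np.cumsum(grid.weights)
    nodes = np.concatenate(([zp[0] - half], zp + half))
    values = np.concatenate(([0.0], cdf))
    edges = grid.points + 0.5 * grid.spacing  # right edge of each target cell
    g = np.interp(edges, nodes, values, left=0.0, right=1.0)
    w_new = np.diff(np.concatenate(([0.0], g)))
    w_new[-1] += 1.0 - g[-1]
    w_new = np.clip(w_new, 0.0, None)
    return a_new, b_new, LatentGrid(grid.points, w_new / w_new.sum())


def em_cycles(x, a0, b0, w0, points, method: str = "eh", n_cycles: int = 10,
              engine: str = "auto"):
    """Run a fixed number of EM cycles with no convergence check.

    Used by the multi-start ("shortrun") initialization.  Returns
    ``(a, b, weights, loglik)`` where ``loglik`` is the marginal
    log-likelihood of the returned parameters.
    """
    x = np.asarray(x, dtype=float)
    points = np.asarray(points, dtype=float)
    a = np.asarray(a0, dtype=float).copy()
    b = np.asarray(b0, dtype=float).copy()
    w = np.asarray(w0, dtype=float).copy()
    w = w / w.sum()
    use_numba = HAVE_NUMBA if engine == "auto" else engine == "numba"
    if use_numba:
        xc = np.ascontiguousarray(x)
        xt = np.ascontiguousarray(x.T)
        trace = np.empty(n_cycles)
        em_run(xc, xt, a, b, w, np.ascontiguousarray(points),
               method == "eh", 0.0, n_cycles, trace)
    else:
        for _ in range(n_cycles):
            _, post, m, r = _e_step_arrays(a, b, points, w, x)
            counts = ExpectedCounts(r=r, m=m)
            a, b, _ = m_step_items(counts, points, a, b)
            if method == "eh":
                w = m_step_weights(post)
    ll, *_ = _e_step_arrays(a, b, points, w, x)
    return a, b, w, ll


def fit_path(
    x,
    a0,
    b0,
    w0,
    criteria,
    method: str = "eh",
    points=None,
    max_em_cycles: int = 10_000,
    engine: str = "auto",
) -> dict[float, FitResult]:
    """Fit the 2PL once, snapshotting at several nested convergence criteria.

    The EM iteration is deterministic given the data and initial values, so
    the fit stopped at a loose criterion is exactly the state of the fit at
    the first cycle where the largest item-parameter change drops below that
    threshold.  Running a single EM pass to the tightest criterion and
    recording the state at each crossing therefore reproduces separate runs
    at every criterion at the cost of one.

    ``engine`` selects the inner loop: ``"numpy"`` is the reference
    implementation, ``"numba"`` the compiled one, ``"auto"`` the compiled
    one when available.  Returns a dict mapping each requested criterion to
    its FitResult.
    """
    if method not in ("mml", "eh"):
        raise ValueError("method must be 'mml' or 'eh'")
    if engine not in ("auto", "numpy", "numba"):
        raise ValueError("engine must be 'auto', 'numpy', or 'numba'")
    if engine == "numba" and not HAVE_NUMBA:
        raise RuntimeError("numba is not available")
    use_numba = HAVE_NUMBA if engine == "auto" else engine == "numba"
    x = np.asarray(x, dtype=float)
    if points is None:
        points = make_grid_points()
    points = np.asarray(points, dtype=float)
    criteria = sorted(set(float(c) for c in criteria), reverse=True)
    if not criteria or criteria[-1] <= 0:
        raise ValueError("criteria must be positive")

    a = np.asarray(a0, dtype=float).copy()
    b = np.asarray(b0, dtype=float).copy()
    w = np.asarray(w0, dtype=float).copy()
    _validate_weights(w)
    w = w / w.sum()

    results: dict[float, FitResult] = {}
    trace: list[float] = []
    pending = list(criteria)
    change = np.inf
    clamped = np.zeros(x.shape[1], dtype=bool)
    def snapshot(cycle: int, converged: bool, change: float) -> FitResult:
        # the EM iterates in an unconstrained latent metric; estimates are
        # reported on the identified mean-0 / SD-1 metric
        if method == "eh":
            a_out, b_out, grid = standardize_metric(a, b, LatentGrid(points, w))
        else:
            a_out, b_out, grid = a.copy(), b.copy(), LatentGrid(points, w.copy())
        return FitResult(
            a_hat=a_out,
            b_hat=b_out,
            grid=grid,
            loglik_trace=np.array(trace),
            n_cycles=cycle,
            converged=converged,
            final_change=change,
            clamped=clamped.copy(),
        )

    if use_numba:
        xc = np.ascontiguousarray(x)
        xt = np.ascontiguousarray(x.T)
        points = np.ascontiguousarray(points)
        trace_buf = np.empty(max_em_cycles)
        total = 0
        while pending:
            remaining = max_em_cycles - total
            if remaining <= 0:
                break
            done, change = em_run(
                xc, xt, a, b, w, points, method == "eh",
                pending[0], remaining, trace_buf[total:],
            )
            total += done
            trace = trace_buf[:total].tolist()
            clamped = (a <= A_MIN) | (a >= A_MAX) | (b <= B_MIN) | (b >= B_MAX)
            if not change < pending[0]:
                break
            while pending and change < pending[0]:
                results[pending.pop(0)] = snapshot(total, True, float(change))
        for crit in pending:
            results[crit] = snapshot(total, False, float(change))
        return results

    cycle = 0
    for cycle in range(1, max_em_cycles + 1):
        ll, post, m, r = _e_step_arrays(a, b, points, w, x)
        trace.append(ll)  # log-likelihood of the iterate entering this cycle
        a_prev, b_prev = a, b
        a, b, clamped = m_step_items(ExpectedCounts(r=r, m=m), points, a, b)
        if method == "eh":
            w = m_step_weights(post)
        change = float(np.max(np.maximum(np.abs(a - a_prev), np.abs(b - b_prev))))
        while pending and change < pending[0]:
            results[pending.pop(0)] = snapshot(cycle, True, change)
        if not pending:
            break
    for crit in pending:
        results[crit] = snapshot(cycle, False, change)
    return results


def fit(x, a0, b0, w0, settings: ConvergenceSettings, points=None) -> FitResult:
    """Fit the 2PL by EM under a single convergence setting."""
    res = fit_path(
        x,
        a0,
        b0,
        w0,
        [settings.criterion],
        method=settings.method,
        points=points,
        max_em_cycles=settings.max_em_cycles,
    )
    return res[settings.criterion]
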