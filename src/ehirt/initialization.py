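"""Initial-value strategies for 2PL EM estimation.

Item-parameter starts
    ``true``      copy the generating parameters (reference condition)
    ``default``   classical-test-theory estimators from the estimation
                  sample: discriminations from the biserial correlation of
                  each item with the total score, difficulties from the
                  item proportion correct
    ``const``     a = 1, b = 0 for every item
    ``shortrun``  best of 50 random starts, each run for 10 EM cycles

Latent-weight starts
    ``uniform``   equal weights at every support point
    ``default``   standard-normal density at the support points, normalized
    ``est``       relative frequencies of CTT-weighted sum scores binned to
                  the support points
    ``shortrun``  the weights belonging to the shortrun winner
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimation import em_cycles

__all__ = [
    "InitialValues",
    "CttStats",
    "ctt_stats",
    "ctt_discrimination",
    "init_items",
    "init_weights",
    "est_weights",
    "shortrun_init",
    "IIP_LEVELS",
    "ILD_LEVELS",
]

IIP_LEVELS = ("true", "default", "const", "shortrun")
ILD_LEVELS = ("uniform", "default", "est", "shortrun")

_RBIS_CAP = 0.999
_A_FLOOR = 0.3


@dataclass
class InitialValues:
    a0: np.ndarray
    b0: np.ndarray
    w0: np.ndarray
    label_items: str = ""
    label_weights: str = ""

    def __post_init__(self) -> None:
        self.a0 = np.asarray(self.a0, dtype=float)
        self.b0 = np.asarray(self.b0, dtype=float)
        self.w0 = np.asarray(self.w0, dtype=float)
        if np.any(self.a0 <= 0):
            raise ValueError("initial discriminations must be positive")
        if np.any(self.w0 < 0) or abs(self.w0.sum() - 1.0) > 1e-8:
            raise ValueError("initial weights must be a probability vector")


@dataclass
class CttStats:
    """Classical test theory item statistics."""

    p: np.ndarray
    r_bis: np.ndarray
    degenerate: np.ndarray  # items with a constant response column


def ctt_stats(x) -> CttStats:
    """Proportion correct and biserial item-total correlation per item.

    The point-biserial correlation of each item with the total number of
    items solved (item included) is converted to a biserial correlation via
    ``r_bis = r_pb sqrt(p q) / phi(Phi^-1(p))`` and capped at +-0.999.
    Constant items get ``r_bis = 0`` and are flagged.
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 testees")
    p = x.mean(axis=0)
    total = x.sum(axis=1)
    degenerate = (p <= 0.0) | (p >= 1.0)
    sx = x.std(axis=0)
    st = total.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (x * total[:, None]).mean(axis=0) - p * total.mean()
        r_pb = cov / (sx * st)
    r_pb = np.where(degenerate | (st == 0), 0.0, r_pb)
    pq = np.clip(p * (1.0 - p), 1e-12, None)
    ordinate = stats.norm.pdf(stats.norm.ppf(np.clip(p, 1e-12, 1 - 1e-12)))
    r_bis = r_pb * np.sqrt(pq) / ordinate
    r_bis = np.clip(np.where(degenerate, 0.0, r_bis), -_RBIS_CAP, _RBIS_CAP)
    return CttStats(p=p, r_bis=r_bis, degenerate=degenerate)


def ctt_discrimination(r_bis):
    """CTT approximation of the 2PL discrimination: 1.7 r / sqrt(1 - r^2)."""
    r = np.asarray(r_bis, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|biserial correlation| must be below 1")
    out = 1.7 * r / np.sqrt(1.0 - r**2)
    return float(out) if out.ndim == 0 else out


def init_items(strategy: str, x, truth=None, rng=None, points=None, method="eh"):
    """Initial (a0, b0) under one of the four item-start strategies."""
    if strategy not in IIP_LEVELS:
        raise ValueError(f"strategy must be one of {IIP_LEVELS}")
    x = np.asarray(x, dtype=float)
    k = x.shape[1]
    if strategy == "true":
        if truth is None:
            raise ValueError("strategy 'true' requires the generating item bank")
        return truth.a.copy(), truth.b.copy()
    if strategy == "const":
        return np.ones(k), np.zeros(k)
    if strategy == "default":
        cs = ctt_stats(x)
        a0 = np.maximum(ctt_discrimination(cs.r_bis), _A_FLOOR)
        n = x.shape[0]
        p = np.clip(cs.p, 0.5 / n, 1.0 - 0.5 / n)
        b0 = -np.log(p / (1.0 - p)) / np.maximum(a0, _A_FLOOR)
        return a0, np.clip(b0, -10.0, 10.0)
    # shortrun
    if points is None or rng is None:
        raise ValueError("strategy 'shortrun' requires grid points and an rng")
    iv = shortrun_init(x, points, rng, method=method)
    return iv.a0, iv.b0


def init_weights(strategy: str, x, points, rng=None, method="eh", shortrun=None):
    """Initial latent weights under one of the four weight-start strategies.

    For ``shortrun`` either pass a precomputed :func:`shortrun_init` result
    via ``shortrun`` (so item and weight starts come from the same winning
    candidate) or an rng to run the procedure here.
    """
    if strategy not in ILD_LEVELS:
        raise ValueError(f"strategy must be one of {ILD_LEVELS}")
    points = np.asarray(points, dtype=float)
    q = points.size
    if q < 2:
        raise ValueError("need at least 2 support points")
    if strategy == "uniform":
        return np.full(q, 1.0 / q)
    if strategy == "default":
        w = stats.norm.pdf(points)
        return w / w.sum()
    if strategy == "est":
        return est_weights(x, points)
    if shortrun is not None:
        return shortrun.w0.copy()
    if rng is None:
        raise ValueError("strategy 'shortrun' requires an rng or a precomputed result")
    return shortrun_init(np.asarray(x, dtype=float), points, rng, method=method).w0


def est_weights(x, points) -> np.ndarray:
    """CTT estimate of the latent weights.

    Each testee's sum score weighted by the CTT discrimination approximation
    is standardized (sample mean 0, SD 1) and assigned to the nearest
    support point; the weights are the relative frequencies at each point.
    If every testee has the same score (zero variance), all mass lands on
    the support point nearest 0 and a warning is issued.
    """
    x = np.asarray(x, dtype=float)
    points = np.asarray(points, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 testees")
    cs = ctt_stats(x)
    a_hat = ctt_discrimination(cs.r_bis)
    score = x @ a_hat
    sd = score.std()
    if sd <= 0:
        warnings.warn("zero score variance: all testees assigned to one support point")
        s = np.zeros(n)
    else:
        s = (score - score.mean()) / sd
    idx = np.abs(s[:, None] - points[None, :]).argmin(axis=1)
    w = np.bincount(idx, minlength=points.size).astype(float)
    return w / n


def shortrun_init(
    x,
    points,
    rng,
    method: str = "eh",
    n_starts: int = 50,
    n_cycles: int = 10,
) -> InitialValues:
    """Multi-start initialization: best of short EM runs from random starts.

    Each start draws a ~ LogNormal(0, 0.5), b ~ N(0, 1) per item and
    weights ~ symmetric Dirichlet(1) over the support points, runs exactly
    ``n_cycles`` EM cycles (no convergence check), and the candidate with
    the highest marginal log-likelihood wins.
    """
    x = np.asarray(x, dtype=float)
    points = np.asarray(points, dtype=float)
    rng = np.random.default_rng(rng)
    k = x.shape[1]
    q = points.size
    best = None
    best_ll = -np.inf
    for _ in range(n_starts):
        a0 = rng.lognormal(mean=0.0, sigma=0.5, size=k)
        b0 = rng.normal(size=k)
        w0 = rng.dirichlet(np.ones(q))
        a, b, w, ll = em_cycles(x, a0, b0, w0, points, method=method, n_cycles=n_cycles)
        if ll > best_ll:
            best_ll = ll
            best = (a, b, w)
    a, b, w = best
    return InitialValues(a0=a, b0=b, w0=w, label_items="shortrun", label_weights="shortrun")
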