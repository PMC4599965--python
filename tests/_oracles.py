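"""Independent brute-force oracles shared across test modules."""

import numpy as np
from scipy import optimize


def brute_force_loglik(a, b, grid, x):
    """Naive double-loop marginal likelihood, no log-space tricks."""
    total = 0.0
    for row in np.atleast_2d(x):
        lik = 0.0
        for wq, zq in zip(grid.weights, grid.points):
            term = wq
            for ai, bi, xij in zip(a, b, row):
                p = 1.0 / (1.0 + np.exp(-ai * (zq - bi)))
                term *= p if xij else (1.0 - p)
            lik += term
        total += np.log(lik)
    return total


def lp_transport_cost(w1, w2, points):
    """Optimal-transport cost by linear programming (independent oracle)."""
    q = points.size
    cost = np.abs(points[:, None] - points[None, :]).ravel()
    a_eq = []
    for i in range(q):  # row sums = w1
        row = np.zeros((q, q))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(q):  # column sums = w2
        col = np.zeros((q, q))
        col[:, j] = 1
        a_eq.append(col.ravel())
    res = optimize.linprog(
        cost, A_eq=np.array(a_eq), b_eq=np.concatenate([w1, w2]),
        bounds=(0, None), method="highs",
    )
    assert res.success
    return res.fun
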