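"""Compiled inner loop for the Bock-Aitkin EM iteration.

The factorial study runs tens of thousands of EM fits, so the per-cycle
work (E-step over an n x Q posterior table, per-item Newton maximization)
is implemented here as a numba kernel.  The pure-numpy implementation in
:mod:`ehirt.estimation` remains the reference; the two paths are checked
against each other in the test suite, and everything falls back to numpy
when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional speedup
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


A_MIN, A_MAX = 0.05, 10.0
B_MIN, B_MAX = -10.0, 10.0


@njit(cache=True)
def _item_obj(alpha, beta, points, ri, m):
    s = 0.0
    for q in range(points.shape[0]):
        u = alpha * points[q] + beta
        if u > 0.0:
            lp = -np.log1p(np.exp(-u))
            lq = lp - u
        else:
            lq = -np.log1p(np.exp(u))
            lp = lq + u
        s += ri[q] * lp + (m[q] - ri[q]) * lq
    return s


@njit(cache=True)
def em_run(x, xt, a, b, w, points, eh, crit, max_cycles, trace):
    """Iterate EM in place until the item-parameter change drops below crit.

    ``trace`` receives the marginal log-likelihood of the iterate entering
    each cycle.  Returns (cycles_done, last_change).
    """
    n, k = x.shape
    q_n = points.shape[0]
    u_mat = np.empty((k, q_n))
    cq = np.empty(q_n)
    m = np.empty(q_n)
    post = np.empty((n, q_n))
    logw = np.empty(q_n)
    change = 1.0e300
    cycles = 0
    for _cycle in range(max_cycles):
        # ---- E-step ----
        for qq in range(q_n):
            cq[qq] = 0.0
        for i in range(k):
            for qq in range(q_n):
                u = a[i] * (points[qq] - b[i])
                u_mat[i, qq] = u
                if u > 0.0:
                    cq[qq] += -(u + np.log1p(np.exp(-u)))
                else:
                    cq[qq] += -np.log1p(np.exp(u))
        lmat = np.dot(x, u_mat)  # (n, Q): sum_i x_ij * u_iq
        for qq in range(q_n):
            logw[qq] = np.log(w[qq]) if w[qq] > 0.0 else -np.inf
        ll = 0.0
        for qq in range(q_n):
            m[qq] = 0.0
        for j in range(n):
            mx = -1.0e308
            for qq in range(q_n):
                v = lmat[j, qq] + cq[qq] + logw[qq]
                post[j, qq] = v
                if v > mx:
                    mx = v
            ssum = 0.0
            for qq in range(q_n):
                e = np.exp(post[j, qq] - mx)
                post[j, qq] = e
                ssum += e
            ll += np.log(ssum) + mx
            inv = 1.0 / ssum
            for qq in range(q_n):
                post[j, qq] *= inv
                m[qq] += post[j, qq]
        r = np.dot(xt, post)  # (k, Q)
        trace[cycles] = ll
        # ---- M-step: per-item concave Newton with step halving ----
        change = 0.0
        for i in range(k):
            alpha = a[i]
            if alpha < A_MIN:
                alpha = A_MIN
            elif alpha > A_MAX:
                alpha = A_MAX
            bb = b[i]
            if bb < B_MIN:
                bb = B_MIN
            elif bb > B_MAX:
                bb = B_MAX
            beta = -alpha * bb
            f = _item_obj(alpha, beta, points, r[i], m)
            for _it in range(50):
                g0 = 0.0
                g1 = 0.0
                h00 = 0.0
                h01 = 0.0
                h11 = 0.0
                for qq in range(q_n):
                    u = alpha * points[qq] + beta
                    p = 1.0 / (1.0 + np.exp(-u))
                    res = r[i, qq] - m[qq] * p
                    wq = m[qq] * p * (1.0 - p)
                    g1 += res * points[qq]
                    g0 += res
                    h11 += wq * points[qq] * points[qq]
                    h01 += wq * points[qq]
                    h00 += wq
                det = h11 * h00 - h01 * h01
                if det > 1e-12:
                    da = (h00 * g1 - h01 * g0) / det
                    db = (h11 * g0 - h01 * g1) / det
                else:
                    da = 0.1 if g1 > 0.0 else (-0.1 if g1 < 0.0 else 0.0)
                    db = 0.1 if g0 > 0.0 else (-0.1 if g0 < 0.0 else 0.0)
                step = 1.0
                ok = False
                na = alpha
                nb = beta
                fn = f
                for _h in range(40):
                    na = alpha + step * da
                    nb = beta + step * db
                    # project into the feasible (a, b) box before evaluating
                    if na < A_MIN:
                        na = A_MIN
                    elif na > A_MAX:
                        na = A_MAX
                    bb_c = -nb / na
                    if bb_c < B_MIN:
                        bb_c = B_MIN
                    elif bb_c > B_MAX:
                        bb_c = B_MAX
                    nb = -na * bb_c
                    fn = _item_obj(na, nb, points, r[i], m)
                    if fn >= f - 1e-12:
                        ok = True
                        break
                    step *= 0.5
                if not ok:
                    na = alpha
                    nb = beta
                    fn = f
                delta = abs(na - alpha)
                d2 = abs(nb - beta)
                if d2 > delta:
                    delta = d2
                alpha = na
                beta = nb
                f = fn
                if delta < 1e-10:
                    break
            a_new = alpha
            b_new = -beta / alpha
            d1 = abs(a_new - a[i])
            d2 = abs(b_new - b[i])
            if d1 > change:
                change = d1
            if d2 > change:
                change = d2
            a[i] = a_new
            b[i] = b_new
        # ---- M-step: empirical-histogram weights ----
        if eh:
            for qq in range(q_n):
                w[qq] = m[qq] / n
        cycles += 1
        if change < crit:
            break
    return cycles, change
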