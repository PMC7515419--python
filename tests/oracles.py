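"""Independent reference implementations used only by the tests.

These deliberately avoid the package's dual-space solution path: the
primal oracle minimizes the reweighting objective directly over the
probability simplex, the grid oracle enumerates the 2-simplex, the
Wasserstein oracle uses the classical sorted-sample identity, and the
runs-test oracle enumerates sign arrangements exhaustively.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


def primal_objective(w, values, y, sig, theta, w0):
    """(m/2) * chi2_red - theta * S_rel, evaluated at explicit weights."""
    m = values.shape[1]
    means = w @ values
    chi2 = np.mean(((means - y) / sig) ** 2)
    wpos = w > 0
    srel = -np.sum(w[wpos] * np.log(w[wpos] / w0[wpos]))
    return (m / 2.0) * chi2 - theta * srel


def primal_minimize_softmax(values, y, sig, theta, w0, n_restarts=3, seed=0):
    """Minimize the primal over the simplex via a softmax parametrization."""
    rng = np.random.default_rng(seed)
    n = values.shape[0]

    def f(u):
        u = u - u.max()
        w = np.exp(u)
        w /= w.sum()
        return primal_objective(w, values, y, sig, theta, w0)

    best = None
    for trial in range(n_restarts):
        u0 = np.zeros(n) if trial == 0 else rng.normal(0, 0.5, n)
        res = minimize(f, u0, method="BFGS", options=dict(gtol=1e-12, maxiter=5000))
        if best is None or res.fun < best.fun:
            best = res
    u = best.x - best.x.max()
    w = np.exp(u)
    return w / w.sum()


def primal_minimize_grid_2simplex(values, y, sig, theta, w0):
    """Brute-force minimization over the 2-simplex (N=3) by hierarchical
    grid refinement down to step 1e-6."""
    assert values.shape[0] == 3

    def eval_grid(c1, c2, step):
        w1 = np.arange(max(c1 - 60 * step, 0.0), min(c1 + 60 * step, 1.0) + step / 2, step)
        w2 = np.arange(max(c2 - 60 * step, 0.0), min(c2 + 60 * step, 1.0) + step / 2, step)
        g1, g2 = np.meshgrid(w1, w2, indexing="ij")
        mask = g1 + g2 <= 1.0
        best_val, best_w = np.inf, None
        for a, b in zip(g1[mask], g2[mask]):
            w = np.array([a, b, 1.0 - a - b])
            val = primal_objective(w, values, y, sig, theta, w0)
            if val < best_val:
                best_val, best_w = val, w
        return best_w

    w = eval_grid(1 / 3, 1 / 3, 1e-2)
    for step in (1e-3, 1e-4, 1e-5, 1e-6):
        w = eval_grid(w[0], w[1], step)
    return w


def wasserstein_sorted_oracle(a, b):
    """W1 between equal-size, equal-weight samples: mean |sorted a - sorted b|."""
    return float(np.mean(np.abs(np.sort(a) - np.sort(b))))


def runs_count(signs):
    return 1 + int(np.sum(np.asarray(signs[1:]) != np.asarray(signs[:-1])))


def runs_distribution_enumeration(n_pos, n_neg):
    """Exact run-count distribution over all distinct arrangements."""
    n = n_pos + n_neg
    counts = {}
    for pos_idx in itertools.combinations(range(n), n_pos):
        signs = np.full(n, -1)
        signs[list(pos_idx)] = 1
        r = runs_count(signs)
        counts[r] = counts.get(r, 0) + 1
    total = sum(counts.values())
    rs = np.array(sorted(counts))
    probs = np.array([counts[r] / total for r in rs])
    mean = float(np.sum(rs * probs))
    var = float(np.sum((rs - mean) ** 2 * probs))
    return rs, probs, mean, var


def cdf_integral_wasserstein(a, wa, b, wb):
    """W1 as the explicit area between the two weighted CDFs."""
    support = np.unique(np.concatenate([a, b]))
    fa = np.array([np.sum(wa[a <= x]) for x in support])
    fb = np.array([np.sum(wb[b <= x]) for x in support])
    return float(np.sum(np.abs(fa[:-1] - fb[:-1]) * np.diff(support)))
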