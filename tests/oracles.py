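"""Independent oracles used by the test suite.

Everything here is written from the defining formulas with plain dense
linear algebra and exhaustive search, sharing no code with the package's
fitter, so agreement between the two is evidence of correctness rather than
of shared bugs.
"""

from __future__ import annotations

import math

import numpy as np


def hedges_g_oracle(mt, mc, st, sc, nt, nc):
    """Hedges' g and variance, step by step from the defining formulas."""
    sp = math.sqrt(((nt - 1) * st * st + (nc - 1) * sc * sc) / (nt + nc - 2))
    j = 1 - 3 / (4 * (nt + nc - 2) - 1)
    g = j * (mt - mc) / sp
    var = (nt + nc) / (nt * nc) + g * g / (2 * (nt + nc))
    return g, var, j


def lor_oracle(a, c, nt, nc):
    """Log odds ratio and variance from the 2x2 table, with 0.5 added to all
    cells of tables containing a zero cell."""
    b, d = nt - a, nc - c
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return math.log((a / b) / (c / d)), 1 / a + 1 / b + 1 / c + 1 / d


def reml_neg2ll_dense(sigma2, y, v, X, groupings):
    """-2 restricted log-likelihood by direct dense evaluation.

    ``groupings`` is a list of per-record label arrays, one per variance
    component (identity level covariance).
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    X = np.asarray(X, float)
    V = np.diag(v).astype(float)
    for s2, labels in zip(sigma2, groupings):
        labels = np.asarray(labels)
        same = labels[:, None] == labels[None, :]
        V = V + s2 * same.astype(float)
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return np.inf
    Vinv = np.linalg.inv(V)
    A = X.T @ Vinv @ X
    signA, logdetA = np.linalg.slogdet(A)
    if signA <= 0:
        return np.inf
    beta = np.linalg.solve(A, X.T @ Vinv @ y)
    r = y - X @ beta
    return float(logdetV + logdetA + r @ Vinv @ r)


def grid_search_reml(y, v, X, groupings, upper=None, rounds=6, points=15):
    """Global grid search of the REML criterion with iterative zooming.

    Returns the variance-component vector minimizing the dense criterion,
    refined to a resolution of roughly ``upper * (2/(points-1))**rounds``.
    """
    q = len(groupings)
    if upper is None:
        upper = max(4.0 * float(np.var(np.asarray(y, float), ddof=1)), 0.5)
    lows = np.zeros(q)
    highs = np.full(q, float(upper))
    best = None
    for _ in range(rounds):
        axes = [np.linspace(lows[i], highs[i], points) for i in range(q)]
        mesh = np.meshgrid(*axes, indexing="ij")
        flat = np.stack([m.ravel() for m in mesh], axis=1)
        vals = np.array(
            [reml_neg2ll_dense(s2, y, v, X, groupings) for s2 in flat]
        )
        best = flat[int(np.argmin(vals))]
        span = (highs - lows) / (points - 1)
        lows = np.maximum(best - span, 0.0)
        highs = best + span
    return best
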