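"""Independent brute-force oracles used to validate the iterative fitters.

These deliberately avoid the package's own update formulas: for a fixed set
of centers the optimal memberships have a closed form, so each objective
reduces to a function of the centers alone, which is minimized numerically
with many restarts. Only usable at tiny problem sizes.
"""

from itertools import permutations

import numpy as np
from scipy.optimize import minimize


def reduced_fcm_objective(x, centers, m=2.0):
    """min over memberships of the weighted squared-distance objective."""
    d2 = (np.asarray(x, float)[:, None] - np.asarray(centers, float)[None, :]) ** 2
    total = 0.0
    for row in d2:
        if np.any(row == 0):
            continue  # mass on the coincident center costs nothing
        total += float(np.sum(row ** (1.0 / (1.0 - m))) ** (1.0 - m))
    return total


def brute_force_fcm_min(x, c=2, m=2.0, n_starts=40, seed=0):
    """Global minimum of the fuzzy c-means objective over center positions."""
    x = np.asarray(x, float)
    rng = np.random.default_rng(seed)
    best = np.inf
    lo, hi = x.min(), x.max()
    for _ in range(n_starts):
        v0 = rng.uniform(lo, hi, size=c)
        res = minimize(lambda v: reduced_fcm_objective(x, v, m), v0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return best


def _kl_rows(y, centers, floor=1e-12):
    y = np.asarray(y, float)
    logy = np.where(y > 0, np.log(np.where(y > 0, y, 1.0)), 0.0)
    return (y * logy).sum(axis=1)[:, None] - y @ np.log(np.maximum(centers, floor)).T


def reduced_consensus_objective(y, centers, m=2.0):
    """min over memberships of the KL consensus objective for fixed centers."""
    d = _kl_rows(y, centers)
    total = 0.0
    for row in d:
        if np.any(row < 1e-12):
            continue
        total += float(np.sum(row ** (1.0 / (1.0 - m))) ** (1.0 - m))
    return total


def brute_force_consensus_min(y, c=2, m=2.0, n_starts=40, seed=0):
    """Global minimum of the KL consensus objective over simplex centers.

    Centers are parametrized by a row-wise softmax so the search is
    unconstrained.
    """
    y = np.asarray(y, float)
    s = y.shape[1]
    rng = np.random.default_rng(seed)

    def unpack(theta):
        z = theta.reshape(c, s)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    best = np.inf
    for _ in range(n_starts):
        theta0 = rng.normal(0, 2.0, size=c * s)
        res = minimize(lambda th: reduced_consensus_objective(y, unpack(th), m), theta0,
                       method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 5000, "maxfev": 10000})
        best = min(best, res.fun)
    return best


def exhaustive_alignment_accuracy(pred, ref):
    """Best pixel agreement over every permutation of predicted labels."""
    pred = np.asarray(pred).ravel()
    ref = np.asarray(ref).ravel()
    k = int(max(pred.max(), ref.max())) + 1
    best = -1.0
    for perm in permutations(range(k)):
        lut = np.asarray(perm)
        best = max(best, float(np.mean(lut[pred] == ref)))
    return best
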