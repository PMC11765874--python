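"""Independent oracles used by the test-suite.

These deliberately avoid the package's recursion-based machinery: the
conditional likelihood is evaluated by explicit enumeration of all 2^k
response patterns, and maximized with a generic quasi-Newton optimizer over
the sum-zero parameter space.  Feasible for k <= ~12 items.
"""

from itertools import product

import numpy as np
from scipy.optimize import minimize


def enumerated_esf(epsilon):
    """gamma_r by summing products over every response pattern."""
    epsilon = np.asarray(epsilon, dtype=float)
    k = epsilon.size
    gamma = np.zeros(k + 1)
    for pat in product([0, 1], repeat=k):
        pat = np.array(pat)
        gamma[pat.sum()] += float(np.prod(epsilon**pat))
    return gamma


def enumerated_cll(delta, x):
    """Conditional log-likelihood of complete dichotomous data, by enumeration."""
    x = np.asarray(x, dtype=float)
    k = x.shape[1]
    eps = np.exp(-np.asarray(delta, dtype=float))
    gamma = enumerated_esf(eps)
    ll = 0.0
    for row in x:
        r = int(row.sum())
        if r in (0, k):
            continue
        ll += float(np.log(eps) @ row) - np.log(gamma[r])
    return ll


def brute_force_delta(x):
    """Sum-zero difficulties maximizing the enumerated conditional likelihood."""
    x = np.asarray(x, dtype=float)
    k = x.shape[1]

    def neg(free):
        return -enumerated_cll(np.append(free, -free.sum()), x)

    res = minimize(neg, np.zeros(k - 1), method="BFGS", options={"gtol": 1e-10})
    return np.append(res.x, -res.x.sum())
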