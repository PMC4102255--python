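"""Independent oracles used by the test suite.

These implementations are deliberately naive (explicit enumeration,
step-by-step arithmetic) and share no code with the package paths they
check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar


def cox_partial_loglik(beta: float, entry, exit_, event, x) -> float:
    """Written-out left-truncated Cox partial log-likelihood, one covariate.

    Risk set at event time t is {i : entry_i < t <= exit_i}. Tied event
    times use the Efron correction. Pure enumeration; O(n^2).
    """
    entry = np.asarray(entry, float)
    exit_ = np.asarray(exit_, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for t in sorted(set(exit_[event == 1])):
        d_idx = np.flatnonzero((exit_ == t) & (event == 1))
        r_idx = np.flatnonzero((entry < t) & (t <= exit_))
        d = len(d_idx)
        sum_d = np.exp(beta * x[d_idx]).sum()
        sum_r = np.exp(beta * x[r_idx]).sum()
        ll += beta * x[d_idx].sum()
        for ell in range(d):
            ll -= math.log(sum_r - (ell / d) * sum_d)
    return ll


def cox_mle_bruteforce(entry, exit_, event, x) -> float:
    """Maximize the enumerated partial likelihood to high precision."""
    res = minimize_scalar(
        lambda b: -cox_partial_loglik(b, entry, exit_, event, x),
        bounds=(-20, 20),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def dl_spreadsheet(theta, se):
    """Step-by-step DerSimonian-Laird arithmetic (k studies).

    Returns (combined, se, tau2, Q) computed with explicit loops, the
    way one would lay it out in a spreadsheet.
    """
    k = len(theta)
    w = [1.0 / s**2 for s in se]
    sw = sum(w)
    fe = sum(wi * ti for wi, ti in zip(w, theta)) / sw
    Q = sum(wi * (ti - fe) ** 2 for wi, ti in zip(w, theta))
    c = sw - sum(wi**2 for wi in w) / sw
    tau2 = max(0.0, (Q - (k - 1)) / c)
    ws = [1.0 / (s**2 + tau2) for s in se]
    comb = sum(wi * ti for wi, ti in zip(ws, theta)) / sum(ws)
    return comb, sum(ws) ** -0.5, tau2, Q


def ols_normal_equations(X, y):
    """(X'X)^{-1} X'y with coefficient covariance; textbook arithmetic."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xtx_inv = np.linalg.inv(X.T @ X)
    b = xtx_inv @ X.T @ y
    resid = y - X @ b
    df = X.shape[0] - X.shape[1]
    s2 = float(resid @ resid) / df
    return b, np.sqrt(s2 * np.diag(xtx_inv)), df
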