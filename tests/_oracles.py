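"""Independent reference implementations used to check the package.

These deliberately avoid the library's own code paths: the curve fit is
checked against brute-force minimization of the same weighted objective
(dense grid over the nonlinear parameter, exact linear solve for the
amplitude), and the rank test against exhaustive enumeration of the U
distribution.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def grid_fit(t, y, w, t_d, alpha_grid):
    """Brute-force weighted least squares over a dense alpha grid.

    For each candidate alpha the optimal Y_eq has a closed form (the
    objective is linear in Y_eq), so the grid needs to cover only the
    nonlinear parameter.  Returns (alpha, y_eq, sse) at the grid minimum.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    dt = np.clip(t - t_d, 0.0, None)
    g = -np.expm1(-np.outer(alpha_grid, dt))  # n_alpha x n_obs
    denom = (g * g * w).sum(axis=1)
    y_eq = np.where(denom > 0, (g * w * y).sum(axis=1) / np.where(denom > 0, denom, 1.0), 0.0)
    y_eq = np.clip(y_eq, 0.0, None)
    r = y[None, :] - y_eq[:, None] * g
    sse = (w * r * r).sum(axis=1)
    i = int(np.argmin(sse))
    return float(alpha_grid[i]), float(y_eq[i]), float(sse[i])


def exact_mannwhitney_p(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney p by exhaustive enumeration (no ties allowed).

    Builds the exact null distribution of U over all C(m+n, m) assignments
    of the pooled ranks to the first group; two-sided p doubles the smaller
    tail (capped at 1).  Returns (U_x, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size != pooled.size:
        raise ValueError("enumeration oracle requires tie-free data")
    m, n = len(x), len(y)
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = float(ranks[:m].sum() - m * (m + 1) / 2)
    total = comb(m + n, m)
    us = np.empty(total)
    for i, picks in enumerate(combinations(range(1, m + n + 1), m)):
        us[i] = sum(picks) - m * (m + 1) / 2
    cdf = np.mean(us <= u_obs)
    sf = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(cdf, sf))
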