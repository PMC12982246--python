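"""Independent oracle implementations used by the test suite.

These deliberately avoid the package's computational paths: the REML
log-likelihood is evaluated through the dense n x n covariance matrix, its
maximiser is located by iterative grid refinement, and GLS fits are done by
explicit matrix inversion.
"""

from __future__ import annotations

import itertools

import numpy as np


def dense_reml_loglik(y, X, Zs, sig2s, sig2e):
    """REML log-likelihood via the dense observation covariance."""
    n, p = X.shape
    V = sig2e * np.eye(n)
    for Z, s in zip(Zs, sig2s):
        V += s * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    yPy = (y - X @ beta) @ Vi @ y
    _, ld_V = np.linalg.slogdet(V)
    _, ld_X = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + ld_V + ld_X + yPy)


def grid_search_reml(y, X, Zs, lo=1e-6, hi=None, n_points=13, final_step=2.5e-4):
    """Maximise the dense REML log-likelihood by iterative grid refinement.

    Returns (components array incl. residual last, loglik).  The final grid
    step is below 1e-3 in every dimension.
    """
    k = len(Zs) + 1
    hi = hi or 3.0 * float(np.var(y, ddof=1))
    centers = np.full(k, (lo + hi) / 2)
    half = np.full(k, (hi - lo) / 2)
    best = None
    while True:
        axes = [np.linspace(max(lo, c - h), c + h, n_points)
                for c, h in zip(centers, half)]
        best = None
        for point in itertools.product(*axes):
            ll = dense_reml_loglik(y, X, Zs, point[:-1], point[-1])
            if best is None or ll > best[1]:
                best = (np.array(point), ll)
        centers = best[0]
        step = np.array([a[1] - a[0] for a in axes])
        if np.all(step <= final_step):
            return best
        half = 1.2 * step  # cover one step either side of the new centre


def bh_adjust_reference(p):
    """Benjamini-Hochberg adjustment via statsmodels (independent route)."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="fdr_bh")[1]
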