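"""Independent brute-force oracle for the mixture likelihood.

Computes the observed-data log-likelihood of point/interval p-value
reports directly from scipy's Beta distribution and maximises it over a
coarse (pi0, a, b) grid.  Deliberately independent of the package's
estimator internals.
"""

import numpy as np
from scipy import stats


def _split(reports):
    pts = np.array([r[1] for r in reports if r[0] == "point"])
    ivs = np.array([[r[1], r[2]] for r in reports if r[0] == "interval"])
    return pts, ivs


def oracle_loglik(reports, pi0, a, b, alpha=0.05):
    """reports: list of ('point', p) or ('interval', lo, hi)."""
    pts, ivs = _split(reports)
    return _loglik_split(pts, ivs, pi0, a, b, alpha)


def _loglik_split(pts, ivs, pi0, a, b, alpha):
    fa = stats.beta.cdf(alpha, a, b)
    ll = 0.0
    if pts.size:
        lik = pi0 / alpha + (1 - pi0) * stats.beta.pdf(pts, a, b) / fa
        ll += np.sum(np.log(np.maximum(lik, 1e-300)))
    if ivs.size:
        mass = (stats.beta.cdf(ivs[:, 1], a, b) - stats.beta.cdf(ivs[:, 0], a, b)) / fa
        lik = pi0 * (ivs[:, 1] - ivs[:, 0]) / alpha + (1 - pi0) * mass
        ll += np.sum(np.log(np.maximum(lik, 1e-300)))
    return float(ll)


PI0_GRID = np.linspace(0.05, 0.95, 10)
A_GRID = (0.3, 0.5, 0.7, 1.0, 2.0)
B_GRID = (5.0, 10.0, 20.0, 30.0, 50.0, 100.0)


def grid_best(reports, alpha=0.05):
    """(best loglik, best params) over the coarse grid."""
    pts, ivs = _split(reports)
    best_ll, best = -np.inf, None
    for a in A_GRID:
        for b in B_GRID:
            for pi0 in PI0_GRID:
                ll = _loglik_split(pts, ivs, pi0, a, b, alpha)
                if ll > best_ll:
                    best_ll, best = ll, (pi0, a, b)
    return best_ll, best
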