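"""Independent oracles shared by the unit and acceptance suites.

These deliberately avoid the code paths they are used to check: the
univariate oracle solves the one-dimensional profile equation by root
finding, and the brute-force oracle explores the chi-square-constrained
region by dense random search.
"""

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2

from medci.engines import SampleMoments, SimpleCovStructure, ml_discrepancy


def univariate_variance_profile_bounds(moments: SampleMoments, level: float = 0.95):
    """Closed-form profile-likelihood CI for a single normal variance.

    The endpoints solve n (s2/v - 1 + ln(v/s2)) = chi2_1(level).
    """
    s2 = moments.cov_ml[0, 0]
    crit = chi2.ppf(level, 1)
    prof = lambda v: moments.n * (s2 / v - 1.0 + np.log(v / s2)) - crit
    lo = brentq(prof, s2 * 1e-3, s2, xtol=1e-12)
    hi = brentq(prof, s2, s2 * 1e3, xtol=1e-12)
    return lo, hi


def brute_force_ab_bounds(
    moments: SampleMoments, seed: int = 7, n_draws: int = 1_000_000, level: float = 0.95
):
    """Random-search extrema of a*b over the ML chi-square-constrained region.

    Samples parameter vectors along curvature-matched directions (Hessian of
    the discrepancy at the optimum, by central differences) with radii
    straddling the constraint boundary, keeps the feasible ones, and returns
    (min ab, max ab, n_feasible).  By construction the result can only lie
    inside the true profile interval.
    """
    struct = SimpleCovStructure()
    D = ml_discrepancy(moments)
    th = struct.start(moments)
    crit = chi2.ppf(level, 1)
    d_max = float(D(struct.implied(th))) + crit

    p = struct.n_params
    h = 1e-5 * np.maximum(np.abs(th), 0.1)
    f = lambda t: float(D(struct.implied(t)))
    H = np.zeros((p, p))
    for i in range(p):
        for j in range(i, p):
            ei, ej = np.zeros(p), np.zeros(p)
            ei[i], ej[j] = h[i], h[j]
            H[i, j] = H[j, i] = (
                f(th + ei + ej) - f(th + ei - ej) - f(th - ei + ej) + f(th - ei - ej)
            ) / (4 * h[i] * h[j])
    L = np.linalg.cholesky(np.linalg.inv(H))

    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n_draws, p))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    radius = np.sqrt(2.0 * crit) * (0.2 + 1.1 * rng.random(n_draws))
    thetas = th + (u * radius[:, None]) @ L.T
    thetas = thetas[(thetas[:, 3] > 0) & (thetas[:, 4] > 0) & (thetas[:, 5] > 0)]
    feasible = D(struct.implied(thetas)) <= d_max
    ab = thetas[feasible, 0] * thetas[feasible, 1]
    return float(ab.min()), float(ab.max()), int(feasible.sum())
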