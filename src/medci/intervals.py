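"""The five interval procedures for indirect effects.

* ``profile_ci`` — likelihood-based confidence interval (LBCI): the set of
  effect values not rejected by a 1-df likelihood-ratio (or ADF chi-square)
  test, found as the constrained extrema of the effect over the region where
  the discrepancy rises by at most the chi-square-1 critical value.  Runs over
  three engines: ML (``lbci``), ADF (``lbci-adf``) and ML with the predictor
  variance fixed (``lbci-fx``).
* ``bootstrap_percentile_ci`` — nonparametric percentile bootstrap over case
  resamples, OLS re-estimation in each resample.
* ``monte_carlo_ci`` — percentiles of products of independent normal draws
  centered at the OLS path estimates with SDs equal to their standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import NonlinearConstraint, minimize
from scipy.stats import chi2

from .effects import MediationDataset, OLSEstimates, ols_fit
from .engines import (
    CovarianceStructure,
    SampleMoments,
    adf_discrepancy,
    get_structure,
    ml_discrepancy,
)

__all__ = [
    "IntervalEstimate",
    "profile_ci",
    "bootstrap_percentile_ci",
    "monte_carlo_ci",
    "bootstrap_effect_distribution",
]

#: engine aliases -> (method tag, discrepancy kind, fixed_x)
_ENGINES = {
    "ml": ("lbci", "ml", False),
    "lbci": ("lbci", "ml", False),
    "adf": ("lbci-adf", "adf", False),
    "lbci-adf": ("lbci-adf", "adf", False),
    "ml-fixed-x": ("lbci-fx", "ml", True),
    "lbci-fx": ("lbci-fx", "ml", True),
}


@dataclass
class IntervalEstimate:
    """A point estimate with a confidence interval and provenance tags."""

    estimate: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = ""
    effect_type: str = "unstd"
    status: str = "converged"
    info: dict = field(default_factory=dict)

    def contains(self, value: float) -> bool:
        """Closed-interval containment test."""
        return self.lower <= value <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def to_dict(self) -> dict:
        return {
            "estimate": float(self.estimate),
            "lower": float(self.lower),
            "upper": float(self.upper),
            "level": float(self.level),
            "method": self.method,
            "effect_type": self.effect_type,
            "status": self.status,
        }


# ---------------------------------------------------------------------------
# profile (likelihood-based) confidence interval
# ---------------------------------------------------------------------------


def profile_ci(
    moments: SampleMoments,
    engine: str = "ml",
    model: str | CovarianceStructure = "simple",
    derived: str = "unstd",
    level: float = 0.95,
    max_restarts: int = 5,
    activity_tol: float = 1e-4,
) -> IntervalEstimate:
    """Likelihood-based CI for a derived parameter by constrained extremization.

    Finds min and max of the derived function g(theta) subject to
    D(theta) - D(theta_hat) <= chi2_1(level), where D is the concentrated
    -2 ln L (ML engines) or the (n-1)-scaled ADF statistic.  This inverts the
    1-df likelihood-ratio test, so values of g outside the interval are
    rejected at 1 - level.  Each failed bound search is restarted from
    perturbed starting values up to ``max_restarts`` times; a bound that
    never converges is flagged in ``status`` and reported at the best
    feasible value found.
    """
    tag, kind, fixed_x = _ENGINES[engine.lower()]
    struct = get_structure(model)
    D_sigma = ml_discrepancy(moments) if kind == "ml" else adf_discrepancy(moments)
    theta_hat = struct.start(moments)
    mask = np.ones(struct.n_params, dtype=bool)
    if fixed_x:
        ix = struct.idx(struct.var_x_name)
        mask[ix] = False
        theta_hat = theta_hat.copy()
        theta_hat[ix] = moments.cov_ml[0, 0]
    g = struct.effect_fn(derived) if isinstance(derived, str) else derived

    fixed_full = theta_hat.copy()

    def expand(tf: np.ndarray) -> np.ndarray:
        th = fixed_full.copy()
        th[mask] = tf
        return th

    def D(tf: np.ndarray) -> float:
        return float(D_sigma(struct.implied(expand(tf))))

    def g_free(tf: np.ndarray) -> float:
        return float(g(expand(tf)))

    d_hat = D(theta_hat[mask])
    crit = float(chi2.ppf(level, 1))
    d_max = d_hat + crit
    estimate = float(g(theta_hat))

    bounds = [
        (1e-10, None) if i in struct.variance_idx else (None, None)
        for i in range(struct.n_params)
        if mask[i]
    ]
    constraint = NonlinearConstraint(D, -np.inf, d_max)
    theta0 = theta_hat[mask]
    scale = np.maximum(np.abs(theta0), 0.1)
    rng = np.random.default_rng(987654321)  # only used to perturb restarts

    results: dict[str, float] = {}
    failed: list[str] = []
    for sign, side in ((1.0, "lower"), (-1.0, "upper")):
        best = estimate
        ok = False
        for attempt in range(max_restarts + 1):
            start = theta0 if attempt == 0 else theta0 + rng.normal(size=theta0.size) * 0.1 * scale
            for i, (lo, _) in enumerate(bounds):
                if lo is not None:
                    start[i] = max(start[i], lo)
            res = minimize(
                lambda tf: sign * g_free(tf),
                start,
                method="SLSQP",
                bounds=bounds,
                constraints=[constraint],
                options={"maxiter": 300, "ftol": 1e-10},
            )
            feasible = D(res.x) <= d_max + activity_tol * max(1.0, abs(d_max))
            if feasible:
                val = g_free(res.x)
                if sign * val < sign * best:
                    best = val
                if res.success:
                    ok = True
                    break
        results[side] = best
        if not ok:
            failed.append(side)
    lower = min(results["lower"], estimate)
    upper = max(results["upper"], estimate)
    if not failed:
        status = "converged"
    elif len(failed) == 2:
        status = "degenerate"
    else:
        status = f"failed-{failed[0]}"
    return IntervalEstimate(
        estimate=estimate,
        lower=lower,
        upper=upper,
        level=level,
        method=tag,
        effect_type=derived if isinstance(derived, str) else "custom",
        status=status,
        info={"d_hat": d_hat, "critical": crit},
    )


# ---------------------------------------------------------------------------
# percentile bootstrap
# ---------------------------------------------------------------------------


def _effects_from_cov(C: np.ndarray, model: str, effect_type: str):
    """Indirect effects from batched (divisor-n) covariance matrices.

    Solving the regression normal equations from the covariance matrix gives
    exactly the OLS slopes, so this is a vectorized equivalent of refitting
    each resample.  Returns (effects, bad) where ``bad`` marks singular
    designs.
    """
    C = np.asarray(C)
    single = C.ndim == 2
    if single:
        C = C[None]
    tiny = np.finfo(float).tiny
    with np.errstate(divide="ignore", invalid="ignore"):
        if model == "simple":
            C00, C01, C02 = C[:, 0, 0], C[:, 0, 1], C[:, 0, 2]
            C11, C12, C22 = C[:, 1, 1], C[:, 1, 2], C[:, 2, 2]
            det = C11 * C00 - C01**2
            bad = (C00 <= 0) | (det <= 1e-12 * np.maximum(C11 * C00, tiny))
            a = C01 / C00
            b = (C12 * C00 - C02 * C01) / det
            eff = a * b
            vx, vy = C00, C22
        else:
            C00 = C[:, 0, 0]
            det2 = C[:, 1, 1] * C00 - C[:, 0, 1] ** 2
            bad = (C00 <= 0) | (det2 <= 1e-12 * np.maximum(C[:, 1, 1] * C00, tiny))
            a = C[:, 0, 1] / C00
            b1 = (C[:, 1, 2] * C00 - C[:, 0, 2] * C[:, 0, 1]) / det2
            idx = [1, 2, 0]
            M = C[:, idx][:, :, idx]
            rhs = C[:, idx, 3]
            det3 = np.linalg.det(M)
            norm3 = np.abs(M).sum(axis=(1, 2)) ** 3 + tiny
            bad |= ~np.isfinite(det3) | (np.abs(det3) <= 1e-12 * norm3)
            Msafe = np.where(bad[:, None, None], np.eye(3), M)
            coef = np.linalg.solve(Msafe, rhs[..., None])[..., 0]
            b2 = coef[:, 1]
            eff = a * b1 * b2
            vx, vy = C00, C[:, 3, 3]
        if effect_type == "std":
            bad |= vy <= 0
            eff = eff * np.sqrt(np.where(vy > 0, vx / vy, np.nan))
        elif effect_type != "unstd":
            raise ValueError(f"unknown effect_type {effect_type!r}")
    bad |= ~np.isfinite(eff)
    if single:
        return float(eff[0]), bool(bad[0])
    return eff, bad


def _resample_cov(Z: np.ndarray, idx: np.ndarray) -> np.ndarray:
    Zb = Z[idx]  # (B, n, k)
    Zc = Zb - Zb.mean(axis=1, keepdims=True)
    return np.einsum("bni,bnj->bij", Zc, Zc) / Z.shape[0]


def bootstrap_effect_distribution(
    dataset: MediationDataset,
    effect_type: str,
    B: int,
    rng: np.random.Generator,
):
    """B bootstrap estimates of the indirect effect; rank-deficient resamples
    are redrawn and counted."""
    Z = dataset.values()
    n = Z.shape[0]
    effects = np.empty(B)
    pending = B
    n_redraws = 0
    guard = 0
    while pending > 0:
        idx = rng.integers(0, n, size=(pending, n))
        eff, bad = _effects_from_cov(_resample_cov(Z, idx), dataset.model, effect_type)
        good = ~bad
        n_good = int(good.sum())
        effects[B - pending : B - pending + n_good] = eff[good]
        n_redraws += pending - n_good
        pending -= n_good
        guard += 1
        if guard > 100:
            raise RuntimeError("bootstrap resampling failed to produce full-rank designs")
    return effects, n_redraws


def bootstrap_percentile_ci(
    dataset: MediationDataset,
    effect_type: str = "unstd",
    B: int = 2000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> IntervalEstimate:
    """Percentile bootstrap CI: resample n cases with replacement B times,
    re-estimate the effect by OLS in each resample, and take the empirical
    (1-level)/2 and 1-(1-level)/2 quantiles (linear interpolation between
    order statistics).  Deterministic given the seed."""
    if B < 2:
        raise ValueError("B must be at least 2")
    if dataset.n < 3:
        raise ValueError("need at least 3 cases to bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    effects, n_redraws = bootstrap_effect_distribution(dataset, effect_type, B, rng)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(effects, [alpha, 1.0 - alpha])
    Zc = dataset.values() - dataset.values().mean(axis=0)
    C = Zc.T @ Zc / dataset.n
    estimate, bad = _effects_from_cov(C, dataset.model, effect_type)
    if bad:
        raise np.linalg.LinAlgError("rank-deficient design in the full sample")
    status = "converged" if n_redraws <= 0.05 * B else "warn-redraws"
    return IntervalEstimate(
        estimate=float(estimate),
        lower=float(lower),
        upper=float(upper),
        level=level,
        method="boot",
        effect_type=effect_type,
        status=status,
        info={"B": B, "n_redraws": n_redraws},
    )


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------


def monte_carlo_ci(
    estimates: OLSEstimates,
    effect_type: str = "unstd",
    n_draws: int = 1000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> IntervalEstimate:
    """Monte Carlo CI from products of independent normal draws.

    Each path along the mediated chain is drawn independently with mean equal
    to its OLS estimate and SD equal to its standard error (zero cross-path
    covariance); the interval is the percentile range of the products.  The
    standardized variant multiplies both limits by sd(x)/sd(y), treating the
    standardizers as fixed — the known weakness of this method.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    paths = ("a", "b") if estimates.model == "simple" else ("a", "b1", "b2")
    for p in paths:
        if estimates.ses[p] < 0:
            raise ValueError(f"negative standard error for path {p}")
    prod = np.ones(n_draws)
    for p in paths:
        prod *= rng.normal(estimates.coefs[p], estimates.ses[p], size=n_draws)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(prod, [alpha, 1.0 - alpha])
    estimate = float(np.prod([estimates.coefs[p] for p in paths]))
    if effect_type == "std":
        ratio = estimates.sds["x"] / estimates.sds["y"]
        lower, upper, estimate = lower * ratio, upper * ratio, estimate * ratio
    elif effect_type != "unstd":
        raise ValueError(f"unknown effect_type {effect_type!r}")
    return IntervalEstimate(
        estimate=estimate,
        lower=float(lower),
        upper=float(upper),
        level=level,
        method="mc",
        effect_type=effect_type,
        status="converged",
        info={"n_draws": n_draws},
    )
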