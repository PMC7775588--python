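"""Saturated path-model estimation engines: normal-theory ML, ADF/WLS and
fixed-predictor-variance ML, plus the discrepancy functions profiled by the
likelihood-based interval search.

Because the fitted models are saturated (just-identified), the optimum is
available in closed form from the sample moments — OLS path estimates and
divisor-n variances reproduce the sample covariance exactly — and the
numerical optimizer only polishes that solution.  What the engines really
contribute is the *discrepancy surface away from the optimum*, which is what
a profile (likelihood-based) confidence interval explores:

* ML: the multivariate-normal -2 log-likelihood, computable from sample
  moments alone;
* ADF: Browne's asymptotically distribution-free quadratic form in the
  half-vectorized covariance residuals, weighted by the inverse fourth-moment
  matrix, scaled by (n - 1) for chi-square calibration;
* ML-fixed-X: the ML surface with the predictor variance pinned to its
  observed (divisor-n) value and removed from the free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .effects import (
    MediationDataset,
    MediationParams,
    SerialMediationParams,
    SimpleMediationParams,
)

__all__ = [
    "SampleMoments",
    "FitResult",
    "compute_moments",
    "minus_two_loglik",
    "implied_covariance",
    "ml_fit",
    "adf_fit",
    "CovarianceStructure",
    "SimpleCovStructure",
    "SerialCovStructure",
    "UnivariateVarianceStructure",
    "ml_discrepancy",
    "adf_discrepancy",
    "get_structure",
]


@dataclass
class SampleMoments:
    """Sample means, covariances (both divisors) and central fourth moments."""

    n: int
    variables: tuple[str, ...]
    means: np.ndarray
    cov_ml: np.ndarray
    cov_unbiased: np.ndarray
    m4: np.ndarray  # shape (p, p, p, p), divisor n

    @property
    def p(self) -> int:
        return len(self.variables)


def compute_moments(dataset: MediationDataset | pd.DataFrame | np.ndarray) -> SampleMoments:
    """Exact sample moments of a rectangular dataset.

    Covariances are reported with both divisor n (``cov_ml``, the ML
    convention used throughout the likelihood) and divisor n-1; fourth
    moments are central with divisor n.
    """
    if isinstance(dataset, MediationDataset):
        Z = dataset.values()
        variables = dataset.variables
    elif isinstance(dataset, pd.DataFrame):
        Z = dataset.to_numpy(dtype=float)
        variables = tuple(dataset.columns)
    else:
        Z = np.asarray(dataset, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        variables = tuple(f"v{i}" for i in range(Z.shape[1]))
    n, p = Z.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    means = Z.mean(axis=0)
    D = Z - means
    cov_ml = D.T @ D / n
    cov_unbiased = cov_ml * n / (n - 1)
    pairs = (D[:, :, None] * D[:, None, :]).reshape(n, p * p)
    m4 = (pairs.T @ pairs / n).reshape(p, p, p, p)
    return SampleMoments(
        n=n, variables=variables, means=means, cov_ml=cov_ml,
        cov_unbiased=cov_unbiased, m4=m4,
    )


def implied_covariance(params: MediationParams) -> np.ndarray:
    """Model-implied covariance of the observed variables (reduced form)."""
    return params.implied_covariance()


def minus_two_loglik(params: MediationParams, moments: SampleMoments) -> float:
    """Full multivariate-normal -2 ln L of the path model against the data.

    n * (p ln 2pi + ln|Sigma| + tr(Sigma^-1 S_ml)
         + (xbar - mu)' Sigma^-1 (xbar - mu)).
    """
    sigma = params.implied_covariance()
    mu = params.implied_means()
    n, p = moments.n, moments.p
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("implied covariance is not positive definite")
    diff = moments.means - mu
    sinv_s = np.linalg.solve(sigma, moments.cov_ml)
    mean_term = float(diff @ np.linalg.solve(sigma, diff))
    return n * (p * np.log(2 * np.pi) + logdet + np.trace(sinv_s) + mean_term)


# ---------------------------------------------------------------------------
# covariance-structure models (the parameter -> implied-covariance maps that
# the engines and the profile search share)
# ---------------------------------------------------------------------------


class CovarianceStructure:
    """Map from a parameter vector to an implied covariance matrix.

    Subclasses define ``param_names``, the observed dimension ``k``, which
    entries are variances (for optimizer bounds), ``implied`` (broadcastable
    over leading axes of theta) and the closed-form just-identified solution
    ``start``.
    """

    param_names: tuple[str, ...] = ()
    variance_names: tuple[str, ...] = ()
    k: int = 0
    var_x_name: str | None = None

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def idx(self, name: str) -> int:
        return self.param_names.index(name)

    @property
    def variance_idx(self) -> tuple[int, ...]:
        return tuple(self.idx(v) for v in self.variance_names)

    def start(self, moments: SampleMoments) -> np.ndarray:
        raise NotImplementedError

    def implied(self, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def to_params(self, theta: np.ndarray, moments: SampleMoments | None = None):
        return None

    def effect_fn(self, effect_type: str) -> Callable[[np.ndarray], np.ndarray]:
        raise NotImplementedError(f"no indirect effect defined for {type(self).__name__}")


def _stack_sym(rows: Sequence[Sequence[np.ndarray]]) -> np.ndarray:
    """Assemble a (..., k, k) array from broadcastable scalar entries."""
    rows = [[np.asarray(e) for e in row] for row in rows]
    shape = np.broadcast_shapes(*(e.shape for row in rows for e in row))
    k = len(rows)
    dtype = np.result_type(*(e.dtype for row in rows for e in row))
    out = np.empty(shape + (k, k), dtype=dtype)
    for i, row in enumerate(rows):
        for j, e in enumerate(row):
            out[..., i, j] = e
    return out


class SimpleCovStructure(CovarianceStructure):
    """Covariance structure of the simple mediation model (x, m, y).

    theta = (a, b, c_prime, var_x, var_em, var_ey); intercepts and the
    predictor mean are saturated and concentrated out, so they never appear
    in the profile search.
    """

    param_names = ("a", "b", "c_prime", "var_x", "var_em", "var_ey")
    variance_names = ("var_x", "var_em", "var_ey")
    k = 3
    var_x_name = "var_x"

    def start(self, moments: SampleMoments) -> np.ndarray:
        S = moments.cov_ml
        a = S[0, 1] / S[0, 0]
        b, cp = np.linalg.solve(
            np.array([[S[1, 1], S[0, 1]], [S[0, 1], S[0, 0]]]), np.array([S[1, 2], S[0, 2]])
        )
        var_em = S[1, 1] - a * S[0, 1]
        var_ey = S[2, 2] - b * S[1, 2] - cp * S[0, 2]
        return np.array([a, b, cp, S[0, 0], var_em, var_ey])

    def implied(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta)
        a, b, cp, vx, vem, vey = np.moveaxis(theta, -1, 0)
        cxm = a * vx
        vm = a * cxm + vem
        cxy = (a * b + cp) * vx
        cmy = b * vm + cp * cxm
        vy = b * b * vm + cp * cp * vx + 2 * b * cp * cxm + vey
        return _stack_sym([[vx, cxm, cxy], [cxm, vm, cmy], [cxy, cmy, vy]])

    def implied_var_y(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta)
        a, b, cp, vx, vem, vey = np.moveaxis(theta, -1, 0)
        vm = a * a * vx + vem
        return b * b * vm + cp * cp * vx + 2 * b * cp * a * vx + vey

    def effect_fn(self, effect_type: str) -> Callable[[np.ndarray], np.ndarray]:
        if effect_type == "unstd":
            return lambda th: np.asarray(th)[..., 0] * np.asarray(th)[..., 1]
        if effect_type == "std":
            def g(th: np.ndarray) -> np.ndarray:
                th = np.asarray(th)
                return th[..., 0] * th[..., 1] * np.sqrt(th[..., 3] / self.implied_var_y(th))
            return g
        raise ValueError(f"unknown effect_type {effect_type!r}")

    def to_params(self, theta: np.ndarray, moments: SampleMoments | None = None):
        a, b, cp, vx, vem, vey = theta
        mean_x, i_m, i_y = 0.0, 0.0, 0.0
        if moments is not None:
            mx, mm, my = moments.means
            mean_x, i_m, i_y = mx, mm - a * mx, my - b * mm - cp * mx
        return SimpleMediationParams(
            a=a, b=b, c_prime=cp, var_x=vx, var_em=max(vem, 0.0), var_ey=max(vey, 0.0),
            i_m=i_m, i_y=i_y, mean_x=mean_x,
        )


class SerialCovStructure(CovarianceStructure):
    """Covariance structure of the serial model (x, m1, m2, y), saturated."""

    param_names = (
        "a", "b1", "b2", "c_prime", "d_xm2", "d_m1y",
        "var_x", "var_em1", "var_em2", "var_ey",
    )
    variance_names = ("var_x", "var_em1", "var_em2", "var_ey")
    k = 4
    var_x_name = "var_x"

    def start(self, moments: SampleMoments) -> np.ndarray:
        S = moments.cov_ml
        a = S[0, 1] / S[0, 0]
        b1, d_xm2 = np.linalg.solve(
            np.array([[S[1, 1], S[0, 1]], [S[0, 1], S[0, 0]]]), np.array([S[1, 2], S[0, 2]])
        )
        d_m1y, b2, cp = np.linalg.solve(
            S[np.ix_([1, 2, 0], [1, 2, 0])], np.array([S[1, 3], S[2, 3], S[0, 3]])
        )
        var_em1 = S[1, 1] - a * S[0, 1]
        var_em2 = S[2, 2] - b1 * S[1, 2] - d_xm2 * S[0, 2]
        var_ey = S[3, 3] - d_m1y * S[1, 3] - b2 * S[2, 3] - cp * S[0, 3]
        return np.array([a, b1, b2, cp, d_xm2, d_m1y, S[0, 0], var_em1, var_em2, var_ey])

    def _pieces(self, theta: np.ndarray):
        theta = np.asarray(theta)
        a, b1, b2, cp, dx2, d1y, vx, ve1, ve2, vey = np.moveaxis(theta, -1, 0)
        c_x_m1 = a * vx
        v_m1 = a * c_x_m1 + ve1
        c_x_m2 = b1 * c_x_m1 + dx2 * vx
        c_m1_m2 = b1 * v_m1 + dx2 * c_x_m1
        v_m2 = b1 * b1 * v_m1 + dx2 * dx2 * vx + 2 * b1 * dx2 * c_x_m1 + ve2
        c_x_y = b2 * c_x_m2 + d1y * c_x_m1 + cp * vx
        c_m1_y = b2 * c_m1_m2 + d1y * v_m1 + cp * c_x_m1
        c_m2_y = b2 * v_m2 + d1y * c_m1_m2 + cp * c_x_m2
        v_y = (
            b2 * b2 * v_m2 + d1y * d1y * v_m1 + cp * cp * vx
            + 2 * (b2 * d1y * c_m1_m2 + b2 * cp * c_x_m2 + d1y * cp * c_x_m1)
            + vey
        )
        return (vx, c_x_m1, v_m1, c_x_m2, c_m1_m2, v_m2, c_x_y, c_m1_y, c_m2_y, v_y)

    def implied(self, theta: np.ndarray) -> np.ndarray:
        (vx, c_x_m1, v_m1, c_x_m2, c_m1_m2, v_m2, c_x_y, c_m1_y, c_m2_y, v_y) = self._pieces(theta)
        return _stack_sym(
            [
                [vx, c_x_m1, c_x_m2, c_x_y],
                [c_x_m1, v_m1, c_m1_m2, c_m1_y],
                [c_x_m2, c_m1_m2, v_m2, c_m2_y],
                [c_x_y, c_m1_y, c_m2_y, v_y],
            ]
        )

    def implied_var_y(self, theta: np.ndarray) -> np.ndarray:
        return self._pieces(theta)[-1]

    def effect_fn(self, effect_type: str) -> Callable[[np.ndarray], np.ndarray]:
        if effect_type == "unstd":
            return lambda th: (
                np.asarray(th)[..., 0] * np.asarray(th)[..., 1] * np.asarray(th)[..., 2]
            )
        if effect_type == "std":
            def g(th: np.ndarray) -> np.ndarray:
                th = np.asarray(th)
                prod = th[..., 0] * th[..., 1] * th[..., 2]
                return prod * np.sqrt(th[..., 6] / self.implied_var_y(th))
            return g
        raise ValueError(f"unknown effect_type {effect_type!r}")

    def to_params(self, theta: np.ndarray, moments: SampleMoments | None = None):
        a, b1, b2, cp, dx2, d1y, vx, ve1, ve2, vey = theta
        i = {"mean_x": 0.0, "i_m1": 0.0, "i_m2": 0.0, "i_y": 0.0}
        if moments is not None:
            mx, m1, m2, my = moments.means
            i = {
                "mean_x": mx,
                "i_m1": m1 - a * mx,
                "i_m2": m2 - b1 * m1 - dx2 * mx,
                "i_y": my - b2 * m2 - d1y * m1 - cp * mx,
            }
        return SerialMediationParams(
            a=a, b1=b1, b2=b2, c_prime=cp, d_xm2=dx2, d_m1y=d1y,
            var_x=vx, var_em1=max(ve1, 0.0), var_em2=max(ve2, 0.0), var_ey=max(vey, 0.0),
            **i,
        )


class UnivariateVarianceStructure(CovarianceStructure):
    """Single normal variable with free variance (closed-form profile oracle)."""

    param_names = ("var",)
    variance_names = ("var",)
    k = 1

    def start(self, moments: SampleMoments) -> np.ndarray:
        return np.array([moments.cov_ml[0, 0]])

    def implied(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta)
        return theta[..., None]


_STRUCTURES = {"simple": SimpleCovStructure, "serial": SerialCovStructure}


def get_structure(model: str | CovarianceStructure) -> CovarianceStructure:
    if isinstance(model, CovarianceStructure):
        return model
    try:
        return _STRUCTURES[model]()
    except KeyError:
        raise ValueError(f"unknown model {model!r}") from None


# ---------------------------------------------------------------------------
# discrepancy functions
# ---------------------------------------------------------------------------


def ml_discrepancy(moments: SampleMoments) -> Callable[[np.ndarray], np.ndarray]:
    """Concentrated ML discrepancy D(Sigma) = n (ln|Sigma| + tr(Sigma^-1 S)).

    Saturated means are profiled out exactly (the mean term vanishes at its
    optimum), and the n p ln 2pi constant is dropped: only differences in D
    matter for profiling.  Broadcasts over leading axes of ``sigma``.
    """
    S = moments.cov_ml
    n = moments.n
    k = S.shape[0]
    penalty = 1e12  # large finite value keeps constrained optimizers stable

    def D(sigma: np.ndarray) -> np.ndarray:
        sigma = np.asarray(sigma)
        sign, logdet = np.linalg.slogdet(sigma)
        ok = sign > 0
        safe = np.where(np.asarray(ok)[..., None, None], sigma, np.eye(k))
        tr = np.trace(np.linalg.solve(safe, np.broadcast_to(S, sigma.shape)),
                      axis1=-2, axis2=-1)
        out = np.where(ok, n * (logdet + tr), penalty)
        return out if out.ndim else float(out)

    return D


def _vech(mat: np.ndarray, k: int) -> np.ndarray:
    i, j = np.tril_indices(k)
    return mat[..., i, j]


def adf_weight_matrix(moments: SampleMoments) -> np.ndarray:
    """Browne's ADF weight matrix W[ij,kl] = m4[ijkl] - s_ij s_kl over vech pairs."""
    kdim = moments.p
    i, j = np.tril_indices(kdim)
    s = moments.cov_ml[i, j]
    W = moments.m4[i[:, None], j[:, None], i[None, :], j[None, :]] - np.outer(s, s)
    return W


def adf_discrepancy(
    moments: SampleMoments, scale: str = "n-1"
) -> Callable[[np.ndarray], np.ndarray]:
    """ADF statistic T(Sigma) = (n-1) (s - sigma)' W^-1 (s - sigma).

    W is built from divisor-n central fourth moments; means are fitted
    saturated and excluded (the indirect effects involve the covariance
    structure only).  The (n-1) scale makes T asymptotically chi-square;
    ``scale="n"`` selects the alternative n-scaled convention.
    """
    kdim = moments.p
    s = _vech(moments.cov_ml, kdim)
    W = adf_weight_matrix(moments)
    try:
        cho = cho_factor(W)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by n
        raise np.linalg.LinAlgError("singular ADF weight matrix; n too small") from exc
    if scale == "n-1":
        factor = moments.n - 1
    elif scale == "n":
        factor = moments.n
    else:
        raise ValueError(f"unknown ADF scale {scale!r}")

    def T(sigma: np.ndarray) -> np.ndarray:
        resid = _vech(np.asarray(sigma), kdim) - s
        solved = cho_solve(cho, np.moveaxis(resid, -1, 0)) if resid.ndim > 1 else cho_solve(cho, resid)
        if resid.ndim > 1:
            out = factor * np.einsum("...i,i...->...", resid, solved)
        else:
            out = factor * float(resid @ solved)
        return out

    return T


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of fitting the saturated path model by one engine."""

    estimator: str  # "ML" | "ADF" | "ML-fixed-X"
    model: str
    theta: np.ndarray
    params: MediationParams | None
    statistic: float  # full -2 ln L (ML engines) or (n-1) F_ADF
    converged: bool

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "model": self.model,
            "theta": [float(t) for t in self.theta],
            "statistic": float(self.statistic),
            "converged": bool(self.converged),
        }


def _free_mask(struct: CovarianceStructure, fixed_x: bool, moments: SampleMoments):
    theta0 = struct.start(moments)
    mask = np.ones(struct.n_params, dtype=bool)
    if fixed_x:
        if struct.var_x_name is None:
            raise ValueError("this structure has no predictor variance to fix")
        ix = struct.idx(struct.var_x_name)
        mask[ix] = False
        theta0[ix] = moments.cov_ml[0, 0]
    return theta0, mask


def _optimize_discrepancy(struct, D, theta0, mask, tol=1e-8):
    """Polish the closed-form start with a gradient-based local optimizer."""
    fixed = theta0.copy()

    def expand(tf: np.ndarray) -> np.ndarray:
        th = fixed.copy()
        th[mask] = tf
        return th

    bounds = [
        (1e-10, None) if i in struct.variance_idx else (None, None)
        for i in range(struct.n_params)
        if mask[i]
    ]
    obj = lambda tf: float(D(struct.implied(expand(tf))))
    f0 = obj(theta0[mask])
    res = minimize(obj, theta0[mask], method="L-BFGS-B", bounds=bounds, tol=tol)
    if res.fun <= f0:
        # a line-search stall at the closed-form start (the exact optimum for
        # a saturated model) is convergence, not failure
        return expand(res.x), bool(res.success or res.fun >= f0 - 1e-6 * max(1.0, abs(f0)))
    return expand(theta0[mask]), True


def ml_fit(
    moments: SampleMoments, model: str | CovarianceStructure = "simple", fixed_x: bool = False
) -> FitResult:
    """Fit the saturated path model by normal-theory maximum likelihood.

    With ``fixed_x`` the predictor variance is held at the divisor-n sample
    variance and removed from the free set; for the saturated model this
    changes neither the other estimates nor the optimum -2 ln L.
    """
    struct = get_structure(model)
    theta0, mask = _free_mask(struct, fixed_x, moments)
    D = ml_discrepancy(moments)
    theta, ok = _optimize_discrepancy(struct, D, theta0, mask)
    params = struct.to_params(theta, moments)
    stat = minus_two_loglik(params, moments) if params is not None else float(
        D(struct.implied(theta)) + moments.n * moments.p * np.log(2 * np.pi)
    )
    return FitResult(
        estimator="ML-fixed-X" if fixed_x else "ML",
        model=getattr(struct, "model_tag", model if isinstance(model, str) else "custom"),
        theta=theta,
        params=params,
        statistic=float(stat),
        converged=ok,
    )


def adf_fit(
    moments: SampleMoments, model: str | CovarianceStructure = "simple", fixed_x: bool = False
) -> FitResult:
    """Fit the covariance structure by ADF/WLS.

    Minimizes F = (s - sigma(theta))' W^-1 (s - sigma(theta)) with W built
    from central fourth moments; for the saturated model the minimum is 0 and
    the estimates coincide with ML/OLS.  Reports T = (n-1) F.
    """
    struct = get_structure(model)
    theta0, mask = _free_mask(struct, fixed_x, moments)
    T = adf_discrepancy(moments)
    theta, ok = _optimize_discrepancy(struct, T, theta0, mask)
    params = struct.to_params(theta, moments)
    return FitResult(
        estimator="ADF",
        model=model if isinstance(model, str) else "custom",
        theta=theta,
        params=params,
        statistic=float(T(struct.implied(theta))),
        converged=ok,
    )
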