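"""Structural parameters, indirect-effect formulas and OLS estimation.

The simple mediation model is the pair of regressions

    m = i_m + a*x + e_m
    y = i_y + b*m + c'*x + e_y

and the serial model adds a second mediator,

    m1 = i_m1 + a*x + e_m1
    m2 = i_m2 + b1*m1 + d_xm2*x + e_m2
    y  = i_y  + b2*m2 + d_m1y*m1 + c'*x + e_y,

where the d-paths are zero in the populations studied but are always
estimated, so the fitted model is saturated.  The unstandardized indirect
effect is the product of the paths along the mediated chain (a*b, or
a*b1*b2); the completely standardized indirect effect multiplies it by
sd(x)/sd(y), with sd(y) taken from the model-implied covariance when working
on the parameter scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SimpleMediationParams",
    "SerialMediationParams",
    "MediationParams",
    "MediationDataset",
    "OLSEstimates",
    "indirect_unstandardized",
    "indirect_standardized",
    "standardize_by_sds",
    "ols_fit",
]

SIMPLE_COLUMNS = ("x", "m", "y")
SERIAL_COLUMNS = ("x", "m1", "m2", "y")


@dataclass(frozen=True)
class SimpleMediationParams:
    """Parameters of the simple (one-mediator) path model.

    Variances are on whatever scale the variables live on; the standardized
    indirect effect is invariant to that scale.
    """

    a: float
    b: float
    c_prime: float = 0.0
    var_x: float = 1.0
    var_em: float = 1.0
    var_ey: float = 1.0
    i_m: float = 0.0
    i_y: float = 0.0
    mean_x: float = 0.0

    def __post_init__(self) -> None:
        for name in ("var_x", "var_em", "var_ey"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")

    variables = SIMPLE_COLUMNS
    model = "simple"

    def path_matrix(self) -> np.ndarray:
        """Coefficient matrix A with A[i, j] = path from variable j to i."""
        a, b, cp = self.a, self.b, self.c_prime
        return np.array([[0.0, 0.0, 0.0], [a, 0.0, 0.0], [cp, b, 0.0]])

    def error_variances(self) -> np.ndarray:
        return np.array([self.var_x, self.var_em, self.var_ey])

    def exogenous_terms(self) -> np.ndarray:
        return np.array([self.mean_x, self.i_m, self.i_y])

    def implied_covariance(self) -> np.ndarray:
        return _reduced_form_cov(self.path_matrix(), self.error_variances())

    def implied_means(self) -> np.ndarray:
        return _reduced_form_means(self.path_matrix(), self.exogenous_terms())

    def implied_var_y(self) -> float:
        return float(self.implied_covariance()[-1, -1])


@dataclass(frozen=True)
class SerialMediationParams:
    """Parameters of the serial two-mediator path model.

    ``d_xm2`` (x -> m2) and ``d_m1y`` (m1 -> y) are zero in the generating
    populations but free in the fitted (saturated) model, so they enter the
    implied covariance here.
    """

    a: float
    b1: float
    b2: float
    c_prime: float = 0.0
    d_xm2: float = 0.0
    d_m1y: float = 0.0
    var_x: float = 1.0
    var_em1: float = 1.0
    var_em2: float = 1.0
    var_ey: float = 1.0
    i_m1: float = 0.0
    i_m2: float = 0.0
    i_y: float = 0.0
    mean_x: float = 0.0

    def __post_init__(self) -> None:
        for name in ("var_x", "var_em1", "var_em2", "var_ey"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")

    variables = SERIAL_COLUMNS
    model = "serial"

    def path_matrix(self) -> np.ndarray:
        return np.array(
            [
                [0.0, 0.0, 0.0, 0.0],
                [self.a, 0.0, 0.0, 0.0],
                [self.d_xm2, self.b1, 0.0, 0.0],
                [self.c_prime, self.d_m1y, self.b2, 0.0],
            ]
        )

    def error_variances(self) -> np.ndarray:
        return np.array([self.var_x, self.var_em1, self.var_em2, self.var_ey])

    def exogenous_terms(self) -> np.ndarray:
        return np.array([self.mean_x, self.i_m1, self.i_m2, self.i_y])

    def implied_covariance(self) -> np.ndarray:
        return _reduced_form_cov(self.path_matrix(), self.error_variances())

    def implied_means(self) -> np.ndarray:
        return _reduced_form_means(self.path_matrix(), self.exogenous_terms())

    def implied_var_y(self) -> float:
        return float(self.implied_covariance()[-1, -1])


MediationParams = Union[SimpleMediationParams, SerialMediationParams]


def _reduced_form_cov(A: np.ndarray, psi_diag: np.ndarray) -> np.ndarray:
    """Covariance of a recursive linear system v = A v + u, Var(u) = diag(psi)."""
    total = np.linalg.inv(np.eye(A.shape[0]) - A)
    return total @ np.diag(psi_diag) @ total.T


def _reduced_form_means(A: np.ndarray, nu: np.ndarray) -> np.ndarray:
    return np.linalg.solve(np.eye(A.shape[0]) - A, nu)


def indirect_unstandardized(params: MediationParams) -> float:
    """Product of the paths along the mediated chain: a*b or a*b1*b2."""
    if isinstance(params, SimpleMediationParams):
        return params.a * params.b
    return params.a * params.b1 * params.b2


def indirect_standardized(params: MediationParams) -> float:
    """Completely standardized indirect effect.

    Equals the unstandardized product times sqrt(var_x / Var(y)) with Var(y)
    implied by the full parameter set (for the serial model this includes the
    estimated d-paths, so the formula stays consistent with the saturated fit
    away from the optimum).
    """
    var_y = params.implied_var_y()
    if var_y <= 0:
        raise ValueError(f"implied outcome variance must be positive, got {var_y}")
    return indirect_unstandardized(params) * np.sqrt(params.var_x / var_y)


def standardize_by_sds(ab: float, sd_x: float, sd_y: float) -> float:
    """Convert an unstandardized product to the standardized scale: ab*sd_x/sd_y."""
    if sd_y <= 0:
        raise ValueError(f"sd_y must be positive, got {sd_y}")
    return ab * sd_x / sd_y


@dataclass
class MediationDataset:
    """Case-level data for a mediation model, columns x,m,y or x,m1,m2,y."""

    data: pd.DataFrame
    model: str
    condition: object | None = None
    true_effects: dict[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        expected = SIMPLE_COLUMNS if self.model == "simple" else SERIAL_COLUMNS
        if self.model not in ("simple", "serial"):
            raise ValueError(f"unknown model {self.model!r}")
        missing = set(expected) - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset is missing columns {sorted(missing)}")
        self.data = self.data.loc[:, list(expected)].astype(float)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def variables(self) -> tuple[str, ...]:
        return SIMPLE_COLUMNS if self.model == "simple" else SERIAL_COLUMNS

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @classmethod
    def from_csv(cls, path: str | Path) -> "MediationDataset":
        df = pd.read_csv(path)
        model = "serial" if {"m1", "m2"} <= set(df.columns) else "simple"
        return cls(data=df, model=model)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class OLSEstimates:
    """OLS results for every regression in a mediation model.

    ``coefs``/``ses`` hold the unstandardized slopes and their conventional
    standard errors keyed by path name; ``std_coefs`` the standardized slopes
    (unstandardized times sd(predictor)/sd(outcome), sample SDs with divisor
    n-1); ``sds`` the sample SDs of all observed variables.
    """

    model: str
    coefs: dict[str, float]
    ses: dict[str, float]
    std_coefs: dict[str, float]
    intercepts: dict[str, float]
    sds: dict[str, float]
    resid_var_ml: dict[str, float]
    means: dict[str, float]
    n: int

    def indirect(self, effect_type: str = "unstd") -> float:
        """Sample indirect effect, unstandardized or completely standardized."""
        if self.model == "simple":
            ab = self.coefs["a"] * self.coefs["b"]
        else:
            ab = self.coefs["a"] * self.coefs["b1"] * self.coefs["b2"]
        if effect_type == "unstd":
            return ab
        if effect_type == "std":
            return standardize_by_sds(ab, self.sds["x"], self.sds["y"])
        raise ValueError(f"unknown effect_type {effect_type!r}")

    def to_params(self) -> MediationParams:
        """Fitted parameters as a params object (ML-convention, divisor-n, variances)."""
        n = self.n
        var_x = self.sds["x"] ** 2 * (n - 1) / n
        if self.model == "simple":
            return SimpleMediationParams(
                a=self.coefs["a"],
                b=self.coefs["b"],
                c_prime=self.coefs["c_prime"],
                var_x=var_x,
                var_em=self.resid_var_ml["m"],
                var_ey=self.resid_var_ml["y"],
                i_m=self.intercepts["m"],
                i_y=self.intercepts["y"],
                mean_x=self.means["x"],
            )
        return SerialMediationParams(
            a=self.coefs["a"],
            b1=self.coefs["b1"],
            b2=self.coefs["b2"],
            c_prime=self.coefs["c_prime"],
            d_xm2=self.coefs["d_xm2"],
            d_m1y=self.coefs["d_m1y"],
            var_x=var_x,
            var_em1=self.resid_var_ml["m1"],
            var_em2=self.resid_var_ml["m2"],
            var_ey=self.resid_var_ml["y"],
            i_m1=self.intercepts["m1"],
            i_m2=self.intercepts["m2"],
            i_y=self.intercepts["y"],
            mean_x=self.means["x"],
        )


# regression layout: outcome -> ordered predictors -> path names
_REGRESSIONS = {
    "simple": [("m", ("x",), ("a",)), ("y", ("m", "x"), ("b", "c_prime"))],
    "serial": [
        ("m1", ("x",), ("a",)),
        ("m2", ("m1", "x"), ("b1", "d_xm2")),
        ("y", ("m1", "m2", "x"), ("d_m1y", "b2", "c_prime")),
    ],
}


def ols_fit(dataset: MediationDataset) -> OLSEstimates:
    """Fit every regression of the mediation model by OLS.

    Simple model: m ~ x and y ~ m + x.  Serial model: m1 ~ x, m2 ~ m1 + x and
    y ~ m1 + m2 + x.  Standardized slopes are obtained by rescaling the
    unstandardized ones with sample SDs rather than refitting z-scored data;
    the two are identical in exact arithmetic.
    """
    df = dataset.data
    n = len(df)
    max_k = max(len(preds) for _, preds, _ in _REGRESSIONS[dataset.model])
    if n <= max_k + 1:
        raise ValueError(f"n={n} too small for the {dataset.model} model regressions")
    sds = {v: float(df[v].std(ddof=1)) for v in dataset.variables}
    means = {v: float(df[v].mean()) for v in dataset.variables}
    coefs: dict[str, float] = {}
    ses: dict[str, float] = {}
    std_coefs: dict[str, float] = {}
    intercepts: dict[str, float] = {}
    resid_var_ml: dict[str, float] = {}
    for outcome, predictors, names in _REGRESSIONS[dataset.model]:
        X = sm.add_constant(df[list(predictors)].to_numpy())
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError(
                f"rank-deficient design in regression of {outcome} on {predictors}"
            )
        res = sm.OLS(df[outcome].to_numpy(), X).fit()
        intercepts[outcome] = float(res.params[0])
        resid_var_ml[outcome] = float(np.mean(res.resid**2))
        for j, (pred, name) in enumerate(zip(predictors, names), start=1):
            coefs[name] = float(res.params[j])
            ses[name] = float(res.bse[j])
            std_coefs[name] = coefs[name] * sds[pred] / sds[outcome]
    return OLSEstimates(
        model=dataset.model,
        coefs=coefs,
        ses=ses,
        std_coefs=std_coefs,
        intercepts=intercepts,
        sds=sds,
        resid_var_ml=resid_var_ml,
        means=means,
        n=n,
    )
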