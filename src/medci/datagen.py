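"""Simulation-study populations: nonnormal predictors, unit-variance algebra,
rescaling and the condition grid.

Populations are built on a standardized scale where every observed variable
has mean 0 and variance 1: the predictor is drawn from one of five families
and shifted/scaled by its *population* constants; each downstream variable is
a linear combination of its parents plus a normal error whose variance is
chosen to restore unit variance.  The finished variables are then affinely
rescaled to non-trivial means and SDs so that unstandardized and standardized
effects genuinely differ.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import (
    MediationDataset,
    SerialMediationParams,
    SimpleMediationParams,
    standardize_by_sds,
)

__all__ = [
    "PredictorDistributionSpec",
    "Condition",
    "InfeasibleConditionError",
    "DISTRIBUTIONS",
    "AB_PAIRS",
    "SAMPLE_SIZES",
    "R2_INCREASES",
    "draw_standardized_predictor",
    "cprime_from_r2_increase",
    "population_params",
    "generate_dataset",
    "build_condition_grid",
    "default_grid_config",
]


@dataclass(frozen=True)
class PredictorDistributionSpec:
    """A predictor family together with its population standardizers.

    ``mean``/``sd`` are the population mean and SD of the *raw* family; draws
    are returned as (raw - mean)/sd, so the standardized predictor has
    population mean 0 and SD 1 for every family.
    """

    family: str
    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float

    def draw_raw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "normal":
            return rng.standard_normal(n)
        if self.family == "exponential":
            return rng.exponential(scale=1.0, size=n)
        if self.family == "beta":
            return rng.beta(1.5, 1.5, size=n)
        if self.family == "t5":
            return rng.standard_t(5, size=n)
        if self.family == "t6":
            return rng.standard_t(6, size=n)
        raise ValueError(f"unknown predictor family {self.family!r}")


DISTRIBUTIONS: dict[str, PredictorDistributionSpec] = {
    "normal": PredictorDistributionSpec("normal", 0.0, 1.0, 0.0, 0.0),
    "exponential": PredictorDistributionSpec("exponential", 1.0, 1.0, 2.0, 6.0),
    # Beta(1.5, 1.5): SD = sqrt(a*b/((a+b)^2 (a+b+1))) = sqrt(2.25/36) = 0.25
    "beta": PredictorDistributionSpec("beta", 0.5, 0.25, 0.0, -1.0),
    "t5": PredictorDistributionSpec("t5", 0.0, float(np.sqrt(5 / 3)), 0.0, 6.0),
    "t6": PredictorDistributionSpec("t6", 0.0, float(np.sqrt(6 / 4)), 0.0, 3.0),
}

#: standardized (a, b) path pairs of the study design; serial uses b1=b2=sqrt(b)
AB_PAIRS: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (0.376, 0.376),
    (0.600, 0.600),
    (0.714, 0.714),
    (0.1975, 0.714),
    (0.714, 0.1975),
    (0.5056, 0.714),
    (0.714, 0.5056),
)
SAMPLE_SIZES: tuple[int, ...] = (50, 100, 150, 200, 500)
R2_INCREASES: tuple[float, ...] = (0.0, 0.02, 0.13, 0.26)
MAX_TOTAL_R2 = 0.80

#: rescaling targets (mean, SD) per variable
RESCALE_SIMPLE: dict[str, tuple[float, float]] = {"x": (3.0, 4.0), "m": (5.0, 5.0), "y": (4.0, 3.0)}
RESCALE_SERIAL: dict[str, tuple[float, float]] = {
    "x": (3.0, 4.0),
    "m1": (5.0, 5.0),
    "m2": (2.0, 2.0),
    "y": (4.0, 3.0),
}


class InfeasibleConditionError(ValueError):
    """The requested paths imply a negative error variance."""


def _as_spec(distribution: str | PredictorDistributionSpec) -> PredictorDistributionSpec:
    if isinstance(distribution, PredictorDistributionSpec):
        return distribution
    try:
        return DISTRIBUTIONS[distribution]
    except KeyError:
        raise ValueError(f"unknown predictor family {distribution!r}") from None


def draw_standardized_predictor(
    spec: str | PredictorDistributionSpec,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> np.ndarray:
    """Draw n i.i.d. predictor values standardized by population constants."""
    if n < 1:
        raise ValueError("n must be at least 1")
    spec = _as_spec(spec)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return (spec.draw_raw(rng, n) - spec.mean) / spec.sd


def cprime_from_r2_increase(d: float, a: float) -> float:
    """Direct effect c' giving an R-squared increase of d when x enters y's model.

    On the standardized scale the squared semipartial correlation of x in the
    regression of y on (m, x) is c'^2 (1 - a^2), so c' = sqrt(d / (1 - a^2)).
    """
    if not 0 <= d < 1:
        raise ValueError(f"d must be in [0, 1), got {d}")
    if not abs(a) < 1:
        raise ValueError(f"|a| must be < 1, got {a}")
    return float(np.sqrt(d / (1.0 - a * a)))


@dataclass(frozen=True)
class Condition:
    """One cell of the simulation grid.

    ``a`` and ``b`` are the standardized population paths; the serial model
    splits b into b1 = b2 = sqrt(b) so both models share the same indirect
    effect a*b.  ``r2_increase`` is the population R-squared gain from adding
    the direct path, from which c' is derived.
    """

    model: str
    n: int
    a: float
    b: float
    r2_increase: float
    distribution: str = "normal"
    rescale: dict[str, tuple[float, float]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.model not in ("simple", "serial"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.rescale is None:
            default = RESCALE_SIMPLE if self.model == "simple" else RESCALE_SERIAL
            object.__setattr__(self, "rescale", dict(default))

    @property
    def c_prime(self) -> float:
        return cprime_from_r2_increase(self.r2_increase, self.a)

    @property
    def spec(self) -> PredictorDistributionSpec:
        return _as_spec(self.distribution)

    def total_r2(self) -> float:
        """Population R-squared of the outcome on the standardized scale."""
        params = population_params(self, check=False)
        return 1.0 - params.var_ey

    def is_feasible(self) -> bool:
        try:
            population_params(self)
        except InfeasibleConditionError:
            return False
        return True

    def true_effects(self) -> dict[str, float]:
        """Population indirect effects on the rescaled (data) scale."""
        ab = self.a * self.b
        sd_x = self.rescale["x"][1]
        sd_y = self.rescale["y"][1]
        return {"unstd": ab * sd_y / sd_x, "std": ab}

    def label(self) -> dict[str, object]:
        return {
            "model": self.model,
            "distribution": self.spec.family,
            "n": self.n,
            "a": self.a,
            "b": self.b,
            "d": self.r2_increase,
        }


def population_params(
    condition: Condition, check: bool = True
) -> SimpleMediationParams | SerialMediationParams:
    """Population parameters on the pre-rescale, unit-variance scale.

    Error variances are chosen so every observed variable has population
    variance 1: for the simple model var_em = 1 - a^2 and
    var_ey = 1 - b^2 - c'^2 - 2abc'; the serial model (b1 = b2 = sqrt(b))
    gives var_em1 = 1 - a^2, var_em2 = 1 - b, var_ey = 1 - b - c'^2 - 2abc'.
    """
    a, b, cp = condition.a, condition.b, condition.c_prime
    if condition.model == "simple":
        var_em = 1.0 - a * a
        var_ey = 1.0 - b * b - cp * cp - 2.0 * a * b * cp
        if check and (var_em < 0 or var_ey < 0):
            raise InfeasibleConditionError(
                f"negative error variance for a={a}, b={b}, c'={cp:.4f}"
            )
        return SimpleMediationParams(
            a=a, b=b, c_prime=cp, var_x=1.0, var_em=max(var_em, 0.0), var_ey=max(var_ey, 0.0)
        )
    broot = float(np.sqrt(b))
    var_em1 = 1.0 - a * a
    var_em2 = 1.0 - b
    var_ey = 1.0 - b - cp * cp - 2.0 * a * b * cp
    if check and (var_em1 < 0 or var_em2 < 0 or var_ey < 0):
        raise InfeasibleConditionError(
            f"negative error variance for a={a}, b1=b2={broot:.4f}, c'={cp:.4f}"
        )
    return SerialMediationParams(
        a=a,
        b1=broot,
        b2=broot,
        c_prime=cp,
        var_x=1.0,
        var_em1=max(var_em1, 0.0),
        var_em2=max(var_em2, 0.0),
        var_ey=max(var_ey, 0.0),
    )


def rescaled_population_params(
    condition: Condition,
) -> SimpleMediationParams | SerialMediationParams:
    """Population parameters on the rescaled (data) scale.

    An affine map v -> mean_v + sd_v * v multiplies each path by
    sd(outcome)/sd(predictor) and each error variance by sd(outcome)^2; the
    standardized indirect effect is unchanged.
    """
    p = population_params(condition)
    s = {v: condition.rescale[v][1] for v in condition.rescale}
    mn = {v: condition.rescale[v][0] for v in condition.rescale}
    if condition.model == "simple":
        return SimpleMediationParams(
            a=p.a * s["m"] / s["x"],
            b=p.b * s["y"] / s["m"],
            c_prime=p.c_prime * s["y"] / s["x"],
            var_x=s["x"] ** 2,
            var_em=p.var_em * s["m"] ** 2,
            var_ey=p.var_ey * s["y"] ** 2,
            i_m=mn["m"] - p.a * s["m"] / s["x"] * mn["x"],
            i_y=mn["y"] - p.b * s["y"] / s["m"] * mn["m"] - p.c_prime * s["y"] / s["x"] * mn["x"],
            mean_x=mn["x"],
        )
    a_r = p.a * s["m1"] / s["x"]
    b1_r = p.b1 * s["m2"] / s["m1"]
    b2_r = p.b2 * s["y"] / s["m2"]
    cp_r = p.c_prime * s["y"] / s["x"]
    return SerialMediationParams(
        a=a_r,
        b1=b1_r,
        b2=b2_r,
        c_prime=cp_r,
        var_x=s["x"] ** 2,
        var_em1=p.var_em1 * s["m1"] ** 2,
        var_em2=p.var_em2 * s["m2"] ** 2,
        var_ey=p.var_ey * s["y"] ** 2,
        i_m1=mn["m1"] - a_r * mn["x"],
        i_m2=mn["m2"] - b1_r * mn["m1"],
        i_y=mn["y"] - b2_r * mn["m2"] - cp_r * mn["x"],
        mean_x=mn["x"],
    )


def generate_dataset(
    condition: Condition, seed: int | np.random.SeedSequence
) -> MediationDataset:
    """Generate one sample under a condition, deterministic given the seed.

    The predictor and each error vector come from independent substreams of
    the seed, so reproducibility does not depend on draw order, and resampling
    methods applied later never share a stream with data generation.
    """
    params = population_params(condition)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_err = 2 if condition.model == "simple" else 3
    streams = [np.random.default_rng(child) for child in ss.spawn(1 + n_err)]
    n = condition.n
    x = draw_standardized_predictor(condition.spec, n, streams[0])
    if condition.model == "simple":
        m = params.a * x + streams[1].normal(0.0, np.sqrt(params.var_em), n)
        y = params.b * m + params.c_prime * x + streams[2].normal(0.0, np.sqrt(params.var_ey), n)
        std = {"x": x, "m": m, "y": y}
    else:
        m1 = params.a * x + streams[1].normal(0.0, np.sqrt(params.var_em1), n)
        m2 = params.b1 * m1 + streams[2].normal(0.0, np.sqrt(params.var_em2), n)
        y = (
            params.b2 * m2
            + params.c_prime * x
            + streams[3].normal(0.0, np.sqrt(params.var_ey), n)
        )
        std = {"x": x, "m1": m1, "m2": m2, "y": y}
    rescaled = {
        v: condition.rescale[v][0] + condition.rescale[v][1] * vals for v, vals in std.items()
    }
    return MediationDataset(
        data=pd.DataFrame(rescaled),
        model=condition.model,
        condition=condition,
        true_effects=condition.true_effects(),
    )


def default_grid_config() -> dict:
    """The full study grid as a plain config mapping."""
    return {
        "models": ["simple", "serial"],
        "sample_sizes": list(SAMPLE_SIZES),
        "ab_pairs": [list(p) for p in AB_PAIRS],
        "r2_increases": list(R2_INCREASES),
        "distributions": list(DISTRIBUTIONS),
        "max_total_r2": MAX_TOTAL_R2,
    }


def build_condition_grid(config: dict | None = None) -> list[Condition]:
    """Cartesian product of the design factors, minus excluded conditions.

    A condition is dropped when any population error variance would be
    negative or when the implied population R-squared of the outcome exceeds
    the cap (0.80 by default).
    """
    cfg = default_grid_config()
    if config:
        cfg.update(config)
    max_r2 = cfg.get("max_total_r2", MAX_TOTAL_R2)
    rescale_cfg = cfg.get("rescale")  # optional {model: {var: [mean, sd]}}
    grid: list[Condition] = []
    for model, n, (a, b), d, dist in itertools.product(
        cfg["models"], cfg["sample_sizes"], cfg["ab_pairs"], cfg["r2_increases"], cfg["distributions"]
    ):
        rescale = None
        if rescale_cfg and model in rescale_cfg:
            rescale = {v: tuple(t) for v, t in rescale_cfg[model].items()}
        cond = Condition(
            model=model, n=int(n), a=float(a), b=float(b), r2_increase=float(d),
            distribution=dist, rescale=rescale,
        )
        if not cond.is_feasible():
            continue
        if cond.total_r2() > max_r2:
            continue
        grid.append(cond)
    return grid
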