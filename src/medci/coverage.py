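"""Coverage-probability simulation: replicate conditions, apply the interval
methods, and classify empirical coverage against the tolerable range.

Coverage is the proportion of replications whose 95% interval contains the
true population effect; 0.935-0.965 is treated as the tolerable range around
the nominal 0.95.  Replications are independently seeded work units, so
results are identical regardless of parallel scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .datagen import Condition, generate_dataset
from .effects import ols_fit
from .engines import compute_moments
from .intervals import IntervalEstimate, bootstrap_percentile_ci, monte_carlo_ci, profile_ci

__all__ = [
    "CoverageResult",
    "ALL_METHODS",
    "TOLERABLE_LOW",
    "TOLERABLE_HIGH",
    "classify_coverage",
    "run_condition",
    "summarize",
]

ALL_METHODS = ("boot", "lbci", "lbci-adf", "lbci-fx", "mc")
TOLERABLE_LOW = 0.935
TOLERABLE_HIGH = 0.965

_PROFILE_ENGINE = {"lbci": "ml", "lbci-adf": "adf", "lbci-fx": "ml-fixed-x"}


def classify_coverage(coverage: float) -> str:
    """Classify an empirical coverage against the tolerable range (inclusive)."""
    if not 0.0 <= coverage <= 1.0:
        raise ValueError(f"coverage must be in [0, 1], got {coverage}")
    if coverage < TOLERABLE_LOW:
        return "below"
    if coverage > TOLERABLE_HIGH:
        return "above"
    return "within"


@dataclass
class CoverageResult:
    """Empirical coverage of one method/effect-type in one condition."""

    condition: Condition
    method: str
    effect_type: str
    n_reps: int
    n_converged: int
    coverage: float
    mean_width: float

    @property
    def classification(self) -> str:
        return classify_coverage(self.coverage)


def _replicate(
    condition: Condition,
    seed: np.random.SeedSequence,
    methods: tuple[str, ...],
    effect_types: tuple[str, ...],
    level: float,
    B: int,
    mc_draws: int,
):
    """One replication: generate data, form every requested interval, test
    containment of the true effects.  Returns {(method, effect): (hit|None, width)}."""
    data_seed, boot_seed, mc_seed = seed.spawn(3)
    dataset = generate_dataset(condition, data_seed)
    true = dataset.true_effects
    moments = None
    estimates = None
    out: dict[tuple[str, str], tuple[bool | None, float]] = {}
    for method in methods:
        for effect_type in effect_types:
            if method == "boot":
                ci: IntervalEstimate = bootstrap_percentile_ci(
                    dataset, effect_type, B=B, level=level,
                    seed=np.random.default_rng(boot_seed),
                )
            elif method == "mc":
                if estimates is None:
                    estimates = ols_fit(dataset)
                ci = monte_carlo_ci(
                    estimates, effect_type, n_draws=mc_draws, level=level,
                    seed=np.random.default_rng(mc_seed),
                )
            elif method in _PROFILE_ENGINE:
                if moments is None:
                    moments = compute_moments(dataset)
                ci = profile_ci(
                    moments, engine=_PROFILE_ENGINE[method], model=condition.model,
                    derived=effect_type, level=level,
                )
            else:
                raise ValueError(f"unknown method {method!r}")
            if ci.status.startswith("failed") or ci.status == "degenerate":
                out[(method, effect_type)] = (None, np.nan)
            else:
                out[(method, effect_type)] = (ci.contains(true[effect_type]), ci.width)
    return out


def run_condition(
    condition: Condition,
    methods: tuple[str, ...] = ALL_METHODS,
    n_reps: int = 1000,
    master_seed: int | np.random.SeedSequence = 0,
    effect_types: tuple[str, ...] = ("unstd", "std"),
    level: float = 0.95,
    B: int = 2000,
    mc_draws: int = 1000,
    n_jobs: int = 1,
) -> list[CoverageResult]:
    """Replicate one condition and aggregate coverage per method/effect type.

    Replications whose interval search failed are excluded from that
    method's denominator; their count shows up as n_reps - n_converged.
    Reproducible given ``master_seed``; the per-replication seeds are spawned
    up front, so ``n_jobs`` changes scheduling but never the results.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    ss = (
        master_seed
        if isinstance(master_seed, np.random.SeedSequence)
        else np.random.SeedSequence(master_seed)
    )
    rep_seeds = ss.spawn(n_reps)
    args = (condition, methods, effect_types, level, B, mc_draws)
    if n_jobs == 1:
        rep_results = [
            _replicate(condition, seed, methods, effect_types, level, B, mc_draws)
            for seed in rep_seeds
        ]
    else:
        rep_results = Parallel(n_jobs=n_jobs)(
            delayed(_replicate)(condition, seed, methods, effect_types, level, B, mc_draws)
            for seed in rep_seeds
        )
    results = []
    for method in methods:
        for effect_type in effect_types:
            hits = [r[(method, effect_type)] for r in rep_results]
            converged = [(h, w) for h, w in hits if h is not None]
            n_conv = len(converged)
            coverage = (
                float(np.mean([h for h, _ in converged])) if n_conv else float("nan")
            )
            mean_width = (
                float(np.mean([w for _, w in converged])) if n_conv else float("nan")
            )
            results.append(
                CoverageResult(
                    condition=condition,
                    method=method,
                    effect_type=effect_type,
                    n_reps=n_reps,
                    n_converged=n_conv,
                    coverage=coverage,
                    mean_width=mean_width,
                )
            )
    return results


_SUMMARY_COLUMNS = [
    "model", "distribution", "n", "a", "b", "d", "method", "effect_type",
    "n_reps", "n_converged", "coverage", "classification", "mean_width",
]


def summarize(results: list[CoverageResult]) -> pd.DataFrame:
    """Long-format coverage table, one row per condition x method x effect."""
    rows = []
    for r in results:
        row = dict(r.condition.label())
        row.update(
            method=r.method,
            effect_type=r.effect_type,
            n_reps=r.n_reps,
            n_converged=r.n_converged,
            coverage=r.coverage,
            classification=r.classification if np.isfinite(r.coverage) else "n/a",
            mean_width=r.mean_width,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
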