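"""The five interval procedures, checked against closed-form, brute-force and
large-simulation oracles."""

import numpy as np
import pandas as pd
import pytest

from medci import (
    Condition,
    MediationDataset,
    bootstrap_percentile_ci,
    compute_moments,
    generate_dataset,
    monte_carlo_ci,
    ols_fit,
    profile_ci,
)
from medci.engines import UnivariateVarianceStructure
from medci.intervals import bootstrap_effect_distribution

from oracles import brute_force_ab_bounds, univariate_variance_profile_bounds


# ---------------------------------------------------------------------------
# profile (likelihood-based) CIs
# ---------------------------------------------------------------------------


def test_profile_ci_constant_derived_function(simple_moments):
    ci = profile_ci(simple_moments, engine="ml", model="simple", derived=lambda th: 2.5)
    assert (ci.lower, ci.upper) == (2.5, 2.5)


def test_profile_ci_matches_univariate_closed_form():
    """Profile CI for a normal variance solves n(s2/v - 1 + ln(v/s2)) = 3.8415."""
    rng = np.random.default_rng(3)
    mo = compute_moments(rng.normal(0.0, 2.0, size=80))
    lo, hi = univariate_variance_profile_bounds(mo)
    ci = profile_ci(
        mo, engine="ml", model=UnivariateVarianceStructure(), derived=lambda th: th[..., 0]
    )
    assert ci.status == "converged"
    assert ci.lower == pytest.approx(lo, abs=1e-4)
    assert ci.upper == pytest.approx(hi, abs=1e-4)


def test_profile_ci_matches_brute_force_constrained_extrema():
    """Generic search vs a dense random search over the feasible region.

    The oracle samples ~1e6 parameter vectors around the chi-square boundary
    ellipsoid and takes the extreme a*b among those with D - D_hat <= 3.8415.
    The random search can only underestimate the true extrema, and with this
    sampling density the gap is a few 1e-3, so the profile bounds must
    bracket the oracle bounds from outside within that resolution.
    """
    ds = generate_dataset(Condition("simple", 50, 0.6, 0.6, 0.0, "normal"), 123)
    mo = compute_moments(ds)
    ab_min, ab_max, n_feasible = brute_force_ab_bounds(mo, seed=7)
    assert n_feasible > 100_000  # oracle actually explored the region

    ci = profile_ci(mo, engine="ml", model="simple", derived="unstd")
    assert ci.status == "converged"
    assert ci.lower <= ab_min + 1e-4
    assert ci.upper >= ab_max - 1e-4
    assert ab_min - ci.lower < 0.015
    assert ci.upper - ab_max < 0.015


def test_profile_ci_contains_estimate_and_widens_with_level(simple_moments):
    narrow = profile_ci(simple_moments, engine="ml", derived="unstd", level=0.90)
    wide = profile_ci(simple_moments, engine="ml", derived="unstd", level=0.99)
    assert narrow.lower <= narrow.estimate <= narrow.upper
    assert wide.lower < narrow.lower and wide.upper > narrow.upper


def test_profile_ci_standardized_invariant_to_rescaling(simple_dataset):
    """ML profile CI of the standardized effect ignores affine variable scale."""
    base = profile_ci(compute_moments(simple_dataset), engine="ml", derived="std")
    df = simple_dataset.data.copy()
    df["x"] = df["x"] * 3.0 - 1.0
    df["y"] = df["y"] / 2.0 + 4.0
    moved = profile_ci(
        compute_moments(MediationDataset(df, "simple")), engine="ml", derived="std"
    )
    assert moved.lower == pytest.approx(base.lower, abs=2e-4)
    assert moved.upper == pytest.approx(base.upper, abs=2e-4)


def test_fixed_x_differs_only_for_standardized_effect():
    """The fixed parameter does not enter a*b, so lbci and lbci-fx agree on the
    unstandardized effect; for the standardized effect the missing sampling
    variability of var_x shows up as a systematic difference."""
    cond = Condition("simple", 50, 0.6, 0.6, 0.0, "normal")
    d_unstd, d_std = [], []
    ss = np.random.SeedSequence(2025)
    for child in ss.spawn(100):
        mo = compute_moments(generate_dataset(cond, child))
        for derived, acc in (("unstd", d_unstd), ("std", d_std)):
            free = profile_ci(mo, engine="ml", derived=derived)
            fixed = profile_ci(mo, engine="ml-fixed-x", derived=derived)
            acc.append(abs(free.lower - fixed.lower) + abs(free.upper - fixed.upper))
    assert np.mean(d_unstd) < np.mean(d_std)


def test_profile_ci_serial_adf_runs(serial_moments):
    ci = profile_ci(serial_moments, engine="adf", model="serial", derived="std")
    assert ci.status == "converged"
    assert ci.lower < ci.estimate < ci.upper
    assert ci.method == "lbci-adf"


# ---------------------------------------------------------------------------
# percentile bootstrap
# ---------------------------------------------------------------------------


def test_bootstrap_deterministic_given_seed(simple_dataset):
    a = bootstrap_percentile_ci(simple_dataset, "std", B=400, seed=99)
    b = bootstrap_percentile_ci(simple_dataset, "std", B=400, seed=99)
    assert (a.lower, a.upper) == (b.lower, b.upper)
    c = bootstrap_percentile_ci(simple_dataset, "std", B=400, seed=100)
    assert (a.lower, a.upper) != (c.lower, c.upper)


def test_bootstrap_degenerate_estimator_collapses_to_point(simple_dataset, monkeypatch):
    """An estimator returning the same value on every resample yields a
    zero-width interval at that value."""
    import medci.intervals as iv

    def constant_estimator(C, model, effect_type):
        if np.asarray(C).ndim == 2:
            return 2.5, False
        B = C.shape[0]
        return np.full(B, 2.5), np.zeros(B, dtype=bool)

    monkeypatch.setattr(iv, "_effects_from_cov", constant_estimator)
    ci = bootstrap_percentile_ci(simple_dataset, "unstd", B=200, seed=1)
    assert (ci.lower, ci.upper, ci.estimate) == (2.5, 2.5, 2.5)


def test_bootstrap_default_resample_count(simple_dataset):
    ci = bootstrap_percentile_ci(simple_dataset, seed=1)
    assert ci.info["B"] == 2000


def test_bootstrap_monotone_equivariance(simple_dataset):
    """With quantiles landing on order statistics, the percentile interval of a
    monotone transform of the estimator is the transform of the interval."""
    B = 81  # 0.025 * (B - 1) = 2, an exact order statistic
    rng = np.random.default_rng(5)
    effects, _ = bootstrap_effect_distribution(simple_dataset, "unstd", B, rng)
    lo, hi = np.quantile(effects, [0.025, 0.975])
    tlo, thi = np.quantile(np.exp(effects), [0.025, 0.975])
    assert tlo == pytest.approx(np.exp(lo), rel=1e-12)
    assert thi == pytest.approx(np.exp(hi), rel=1e-12)


def test_bootstrap_matches_per_resample_ols(simple_dataset):
    """The vectorized resample effects equal statsmodels OLS refits."""
    rng = np.random.default_rng(17)
    n = simple_dataset.n
    idx = rng.integers(0, n, size=(5, n))
    rng2 = np.random.default_rng(17)
    effects, _ = bootstrap_effect_distribution(simple_dataset, "std", 5, rng2)
    for row, eff in zip(idx, effects):
        sub = MediationDataset(simple_dataset.data.iloc[row].reset_index(drop=True), "simple")
        assert eff == pytest.approx(ols_fit(sub).indirect("std"), rel=1e-9)


def test_bootstrap_input_validation(simple_dataset):
    with pytest.raises(ValueError):
        bootstrap_percentile_ci(simple_dataset, B=1)
    tiny = MediationDataset(simple_dataset.data.iloc[:2], "simple")
    with pytest.raises(ValueError):
        bootstrap_percentile_ci(tiny, B=10)


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------


def _fake_estimates(a, b, se_a, se_b, sd_x=1.0, sd_y=1.0):
    from medci.effects import OLSEstimates

    return OLSEstimates(
        model="simple",
        coefs={"a": a, "b": b, "c_prime": 0.0},
        ses={"a": se_a, "b": se_b, "c_prime": 0.0},
        std_coefs={},
        intercepts={"m": 0.0, "y": 0.0},
        sds={"x": sd_x, "m": 1.0, "y": sd_y},
        resid_var_ml={"m": 1.0, "y": 1.0},
        means={"x": 0.0, "m": 0.0, "y": 0.0},
        n=100,
    )


def test_monte_carlo_zero_ses_gives_point_interval():
    est = _fake_estimates(0.5, 0.4, 0.0, 0.0)
    ci = monte_carlo_ci(est, "unstd", seed=0)
    assert (ci.lower, ci.upper) == (pytest.approx(0.2), pytest.approx(0.2))
    assert ci.info["n_draws"] == 1000


def test_monte_carlo_product_normal_quantile_oracle():
    """Null paths, unit SEs: limits approach the +/- 97.5th percentile of the
    product of two independent standard normals (independent large-draw oracle)."""
    oracle_rng = np.random.default_rng(1234)
    q = np.quantile(
        oracle_rng.standard_normal(4_000_000) * oracle_rng.standard_normal(4_000_000), 0.975
    )
    est = _fake_estimates(0.0, 0.0, 1.0, 1.0)
    ci = monte_carlo_ci(est, "unstd", n_draws=400_000, seed=5)
    assert ci.upper == pytest.approx(q, abs=0.02)
    assert ci.lower == pytest.approx(-q, abs=0.02)


def test_monte_carlo_standardized_is_exact_sd_ratio_of_unstandardized():
    est = _fake_estimates(0.6, 0.5, 0.1, 0.08, sd_x=4.0, sd_y=3.0)
    unstd = monte_carlo_ci(est, "unstd", seed=11)
    std = monte_carlo_ci(est, "std", seed=11)
    ratio = 4.0 / 3.0
    assert std.lower == pytest.approx(unstd.lower * ratio, rel=1e-12)
    assert std.upper == pytest.approx(unstd.upper * ratio, rel=1e-12)


def test_monte_carlo_width_shrinks_with_ses():
    wide = monte_carlo_ci(_fake_estimates(0.5, 0.4, 0.2, 0.2), seed=3)
    narrow = monte_carlo_ci(_fake_estimates(0.5, 0.4, 0.01, 0.01), seed=3)
    assert narrow.width < wide.width / 5


def test_monte_carlo_rejects_negative_se():
    with pytest.raises(ValueError):
        monte_carlo_ci(_fake_estimates(0.5, 0.4, -0.1, 0.1))
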