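"""Scaling fits, normalization, residuals, interaction test."""

import numpy as np
import pytest

from boxtess.allometry import (fit_loglog, fit_scute_count, normalize_by_sa,
                               residuals_by_geometry,
                               region_interaction_test)


SA13 = np.geomspace(2000, 32000, 13)


def test_noiseless_power_law_recovered_exactly():
    y = 3.1 * SA13 ** 0.56
    fit = fit_loglog(SA13, y, variable="width")
    assert fit.slope == pytest.approx(0.56, abs=1e-12)
    assert fit.ci95[1] - fit.ci95[0] < 1e-10
    assert fit.n == 13


def test_scale_equivariance_only_moves_intercept():
    rng = np.random.default_rng(0)
    y = SA13 ** 0.5 * np.exp(rng.normal(0, 0.1, 13))
    f1 = fit_loglog(SA13, y)
    f2 = fit_loglog(SA13, 7.5 * y)
    assert f2.slope == pytest.approx(f1.slope, abs=1e-12)
    assert f2.intercept == pytest.approx(f1.intercept + np.log(7.5))
    assert np.allclose(f1.residuals, f2.residuals)


def test_ci_coverage_of_true_exponent():
    # Monte-Carlo oracle: 95% CI covers the generating exponent ~95% of
    # the time at n = 13, lognormal noise sigma = 0.1
    rng = np.random.default_rng(42)
    covered = 0
    reps = 500
    for _ in range(reps):
        y = SA13 ** 0.5 * np.exp(rng.normal(0, 0.1, 13))
        lo, hi = fit_loglog(SA13, y).ci95
        covered += lo <= 0.5 <= hi
    assert covered / reps == pytest.approx(0.95, abs=0.03)


def test_nonpositive_values_identify_specimen():
    y = SA13 ** 0.5
    y[4] = -1.0
    with pytest.raises(ValueError, match="sp04"):
        fit_loglog(SA13, y, specimen_ids=[f"sp{i:02d}" for i in range(13)])


def test_constant_counts_give_unit_backtransformed_slope():
    counts = np.full(13, 450)
    fit = fit_scute_count(SA13, counts)
    assert fit.slope == pytest.approx(1.0, abs=1e-12)
    assert fit.model == "poisson_loglink"


def test_poisson_simulation_recovers_backtransformed_slope():
    rng = np.random.default_rng(1)
    b = 3e-5  # log-rate slope per mm^2
    reps = 300
    est = np.empty(reps)
    for i in range(reps):
        counts = rng.poisson(np.exp(5.5 + b * SA13))
        est[i] = fit_scute_count(SA13, counts, ci_method="wald").slope
    mc_se = est.std(ddof=1) / np.sqrt(reps)
    assert abs(est.mean() - np.exp(b)) < 2 * mc_se + 1e-9


def test_profile_ci_brackets_wald_plausibly():
    rng = np.random.default_rng(3)
    counts = rng.poisson(np.exp(5.5 + 2e-5 * SA13))
    prof = fit_scute_count(SA13, counts, ci_method="profile")
    wald = fit_scute_count(SA13, counts, ci_method="wald")
    assert prof.ci95[0] <= prof.slope <= prof.ci95[1]
    # both methods should agree closely in this regular problem
    assert prof.ci95[0] == pytest.approx(wald.ci95[0], abs=1e-4)
    assert prof.ci95[1] == pytest.approx(wald.ci95[1], abs=1e-4)


def test_non_integer_counts_rejected():
    with pytest.raises(ValueError):
        fit_scute_count(SA13, np.full(13, 450.5))


def test_normalization_identities():
    vals = np.array([1.0, 2.0, 3.0])
    assert np.allclose(normalize_by_sa(vals, np.full(3, 10.0), 0.0), vals)
    assert np.allclose(normalize_by_sa([5.0], [10.0], -1.0), [50.0])


def test_normalized_values_have_zero_slope():
    rng = np.random.default_rng(5)
    y = 0.2 * SA13 ** 1.17 * np.exp(rng.normal(0, 0.1, 13))
    fit = fit_loglog(SA13, y)
    z = normalize_by_sa(y, SA13, fit.slope)
    refit = fit_loglog(SA13, z)
    assert abs(refit.slope) < (fit.ci95[1] - fit.ci95[0])


def test_residuals_by_geometry_recovers_planted_effect():
    rng = np.random.default_rng(7)
    classes = (["elliptic"] * 4 + ["triangular"] * 4 + ["tetragonal"] * 5)
    height = SA13 ** 0.5 * np.exp(rng.normal(0, 0.03, 13))
    height[:4] *= 1.25  # elliptic carapaces planted relatively taller
    fit = fit_loglog(SA13, height, specimen_ids=list(range(13)))
    table = residuals_by_geometry(fit, classes)
    assert abs(fit.residuals.sum()) < 1e-9
    med = table.groupby("geometry_class")["residual"].median()
    assert med["elliptic"] > 0
    assert table.groupby("geometry_class")["residual"].count().sum() == 13
    with pytest.raises(ValueError):
        residuals_by_geometry(fit, classes[:-1])


def test_interaction_test_detects_different_exponents():
    rng = np.random.default_rng(11)
    noise = lambda: np.exp(rng.normal(0, 0.05, 13))
    y_flat = SA13 ** 0.5 * noise()
    y_edge = SA13 ** 1.0 * noise()
    assert region_interaction_test(SA13, y_flat, y_edge) < 0.05


def test_interaction_test_degenerate_case_warns_nan():
    y = SA13 ** 0.5
    with pytest.warns(UserWarning, match="degenerate"):
        p = region_interaction_test(SA13, y, y)
    assert np.isnan(p)


def test_interaction_test_requires_complete_regions():
    y = SA13 ** 0.5
    bad = y.copy()
    bad[0] = np.nan
    with pytest.raises(ValueError):
        region_interaction_test(SA13, y, bad)
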