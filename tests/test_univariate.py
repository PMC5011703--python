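import numpy as np
import pytest
from scipy import stats

from twinsem.errors import ConvergenceError, DegenerateDataError
from twinsem.likelihood import TwinData
from twinsem.structures import model_covariance, UnivariateStructure
from twinsem.univariate import (fit_ml, fit_model_ladder, icc,
                                implied_twin_correlations, lrt, profile_ci,
                                variance_decomposition)

from conftest import make_pairs, pairs_from_arrays


def _moment_matched_pairs(va, vc, ve, n_per_group=80, seed=0):
    """Pairs whose per-zygosity sample mean is exactly 0 and sample
    covariance (MLE convention, denominator n) exactly matches the
    model-implied pair covariance.  The structured MLE then attains the
    unstructured optimum, so the fit must recover (va, vc, ve) exactly."""
    rng = np.random.default_rng(seed)
    s = UnivariateStructure.from_variances(va, vc, ve)
    pairs = []
    for zyg in ("MZ", "DZ"):
        Z = rng.normal(size=(n_per_group, 2))
        Z = Z - Z.mean(axis=0)
        # whiten empirically, then colour by the target covariance
        C = np.linalg.cholesky(Z.T @ Z / n_per_group)
        W = Z @ np.linalg.inv(C).T @ np.linalg.cholesky(model_covariance(s, zyg)).T
        pairs += pairs_from_arrays(W[:, 0], W[:, 1], [zyg] * n_per_group)
    for i, pr in enumerate(pairs):
        pr.family_id = f"fam{i}"
    return pairs


def test_moment_matched_data_recovers_components_exactly():
    """Data constructed to match ACE moments exactly is recovered to 1e-4."""
    pairs = _moment_matched_pairs(0.5, 0.3, 0.2)
    fit = fit_ml(pairs, "ACE", seed=0)
    dec = variance_decomposition(fit)
    assert dec.h2 == pytest.approx(0.5, abs=1e-4)
    assert dec.c2 == pytest.approx(0.3, abs=1e-4)
    assert dec.e2 == pytest.approx(0.2, abs=1e-4)
    assert dec.total == pytest.approx(1.0, abs=1e-4)


def test_pure_environment_data_estimates_no_heritability():
    pairs = make_pairs(0.0, 0.0, 1.0, 3000, 3000, seed=11)
    fit = fit_ml(pairs, "ACE", seed=0)
    assert variance_decomposition(fit).h2 < 0.05


def test_aic_identity_and_nesting_across_ladder(standard_cohort):
    """AIC = -2 loglik + 2 k for every fit, and the ACE optimum dominates
    each nested submodel's optimum."""
    ladder = fit_model_ladder(standard_cohort, seed=0)
    for kind, fit in ladder.items():
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
        assert fit.converged
    for kind in ("AE", "CE", "E"):
        assert ladder["ACE"].loglik >= ladder[kind].loglik - 1e-6
    res = lrt(ladder["ACE"], ladder["E"])
    assert res.df == 2 and res.statistic > 0


def test_lrt_chi_square_identities(standard_cohort):
    """Identical models give statistic 0 / p 1; the 3.841 cutoff maps to p=0.05."""
    fit = fit_ml(standard_cohort, "ACE", seed=0)
    same = lrt(fit, fit_ml(standard_cohort, "ACE", seed=1))
    assert same.statistic == pytest.approx(0.0, abs=1e-6)
    assert same.p_value == pytest.approx(1.0, abs=1e-4)
    assert stats.chi2.sf(3.841, 1) == pytest.approx(0.05, abs=1e-3)
    assert stats.chi2.ppf(0.95, 1) == pytest.approx(3.841, abs=5e-4)


def test_lrt_rejects_inconsistent_optima(standard_cohort):
    full = fit_ml(standard_cohort, "ACE", seed=0)
    nested = fit_ml(standard_cohort, "AE", seed=0)
    nested.loglik = full.loglik + 1.0  # simulated optimiser failure
    with pytest.raises(ConvergenceError):
        lrt(full, nested)


@pytest.mark.parametrize("shares, expected", [
    ((0.78, 0.01, 0.21), (0.79, 0.40)),   # frontal lobe row
    ((0.79, 0.09, 0.12), (0.88, 0.485)),  # intracranial volume row
    ((0.0, 0.0, 1.0), (0.0, 0.0)),
])
def test_implied_twin_correlations(shares, expected):
    r_mz, r_dz = implied_twin_correlations(shares)
    assert r_mz == pytest.approx(expected[0], abs=1e-12)
    assert r_dz == pytest.approx(expected[1], abs=1e-12)
    with pytest.raises(ValueError):
        implied_twin_correlations((0.5, 0.1, 0.1))


def test_profile_ci_boundary_pins_lower_bound_at_zero():
    """An h2 estimate of ~0 yields a one-sided interval starting at 0."""
    pairs = make_pairs(0.0, 0.3, 0.7, 200, 150, seed=21)
    fit = fit_ml(pairs, "ACE", seed=0)
    dec = variance_decomposition(fit)
    if dec.h2 < 1e-4:  # estimate on the boundary for this draw
        lo, hi = profile_ci(fit, "h2")
        assert lo == 0.0
        assert hi > 0.0
    lo_c, hi_c = profile_ci(fit, "c2")
    assert 0.0 <= lo_c <= dec.c2 <= hi_c <= 1.0


def test_profile_ci_brackets_estimate(standard_cohort):
    fit = fit_ml(standard_cohort, "ACE", seed=0)
    dec = variance_decomposition(fit)
    lo, hi = profile_ci(fit, "h2")
    assert lo <= dec.h2 <= hi
    assert (hi - lo) < 1.0


def test_icc_perfectly_correlated_pairs():
    y = np.linspace(-2, 2, 12)
    pairs = pairs_from_arrays(y, y.copy(), ["MZ"] * 12)
    r = icc(pairs)
    assert r.estimate > 0.999


def test_icc_matches_double_entry_pearson_oracle():
    """Small fixed set: ML ICC tracks the double-entry Pearson correlation."""
    rng = np.random.default_rng(5)
    y1 = rng.normal(size=6)
    y2 = 0.7 * y1 + 0.5 * rng.normal(size=6)
    pairs = pairs_from_arrays(y1, y2, ["MZ"] * 6)
    r = icc(pairs)
    xs = np.concatenate([y1, y2])
    ys = np.concatenate([y2, y1])
    double_entry = np.corrcoef(xs, ys)[0, 1]
    assert r.estimate == pytest.approx(double_entry, abs=0.02)
    assert r.ci[0] <= r.estimate <= r.ci[1]


def test_icc_near_zero_for_independent_twins():
    rng = np.random.default_rng(6)
    n = 5000
    pairs = pairs_from_arrays(rng.normal(size=n), rng.normal(size=n), ["DZ"] * n)
    assert abs(icc(pairs).estimate) < 0.04


def test_icc_refuses_degenerate_input():
    pairs = pairs_from_arrays(np.ones(5), np.ones(5), ["MZ"] * 5)
    with pytest.raises(DegenerateDataError):
        icc(pairs)


def test_missing_pairs_excluded_by_default():
    pairs = make_pairs(0.5, 0.2, 0.3, 30, 30, seed=31)
    pairs[0].y1[0] = np.nan
    pairs[0].mask1[:] = False
    data = TwinData(pairs)
    assert data.n_pairs_used["MZ"] == 29
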