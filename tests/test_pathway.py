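import numpy as np
import pytest

from twinsem.cholesky import fit_cholesky
from twinsem.io import assemble_pairs
from twinsem.pathway import (bilateral_rg, fit_bilateral_ipm, fit_kfactor_ipm,
                             variance_proportions)
from twinsem.pathway import test_bilateral_symmetry as bilateral_symmetry
from twinsem.simulate import GenerativeSpec, simulate_cohort
from twinsem.structures import PathwayStructure
from twinsem.univariate import fit_ml, lrt, variance_decomposition

from conftest import make_pairs

def _pairs_from_structure(s, n_mz, n_dz, seed):
    spec = GenerativeSpec(n_mz=n_mz, n_dz=n_dz, structure=s,
                          include_covariates=False)
    pairs, _ = assemble_pairs(simulate_cohort(spec, seed=seed))
    return pairs


def test_bilateral_rg_closed_forms_and_oracle():
    """a_c=1, a_s=0 gives r_G=1; a_c=1, a_s=1 gives 1/sqrt(4)=0.5; a random
    structure matches normalisation of its implied A matrix to 1e-12."""
    s1 = PathwayStructure.from_paths(2, lambda_a=[1.0, 1.0], lambda_e=[0.3, 0.3],
                                     d_e=[0.4, 0.4])
    assert bilateral_rg(s1).value == pytest.approx(1.0, abs=1e-12)
    s2 = PathwayStructure.from_paths(2, lambda_a=[1.0, 1.0], d_a=[1.0, 1.0],
                                     lambda_e=[0.3, 0.3], d_e=[0.4, 0.4])
    assert bilateral_rg(s2).value == pytest.approx(0.5, abs=1e-12)
    rng = np.random.default_rng(0)
    s3 = PathwayStructure.from_paths(
        2, lambda_a=rng.normal(size=(2, 1)), d_a=rng.normal(size=2),
        lambda_e=[0.5, 0.5], d_e=[0.5, 0.5])
    expect = s3.A[0, 1] / np.sqrt(s3.A[0, 0] * s3.A[1, 1])
    assert bilateral_rg(s3).value == pytest.approx(expect, abs=1e-12)


def test_no_specific_genetics_estimates_rg_near_one():
    s = PathwayStructure.from_paths(2, lambda_a=[0.8, 0.8], lambda_c=[0.2, 0.2],
                                    lambda_e=[0.2, 0.2], d_e=[0.5, 0.5])
    pairs = _pairs_from_structure(s, 300, 200, seed=1)
    fit = fit_bilateral_ipm(pairs, "ACE", seed=0)
    assert fit.converged
    assert bilateral_rg(fit.structure).value > 0.95


def test_duplicated_hemisphere_absorbed_by_common_factors():
    """Right column a noisy copy of the left: specifics stay small."""
    s = PathwayStructure.from_paths(2, lambda_a=[0.7, 0.7], lambda_e=[0.55, 0.55],
                                    d_e=[0.08, 0.08])
    pairs = _pairs_from_structure(s, 500, 400, seed=2)
    fit = fit_bilateral_ipm(pairs, "AE", seed=0)
    assert np.all(np.abs(fit.structure.d_a) < 0.15)
    assert abs(fit.structure.lambda_a[0, 0]) > 0.5


def test_symmetric_generator_retains_symmetry_and_asymmetric_rejects():
    """With hemisphere-specific paths absent the r_G=1 test retains; with
    clearly distinct specifics at large n it rejects."""
    sym = PathwayStructure.from_paths(2, lambda_a=[0.8, 0.8], lambda_e=[0.3, 0.3],
                                      d_e=[0.5, 0.5])
    res = bilateral_symmetry(_pairs_from_structure(sym, 93, 68, seed=3), "AE")
    assert res.rg.value > 0.9
    assert res.lrt_rg_zero.p_value < 1e-6

    asym = PathwayStructure.from_paths(2, lambda_a=[0.6, 0.6], d_a=[0.8, 0.2],
                                       lambda_e=[0.3, 0.3], d_e=[0.5, 0.5])
    res2 = bilateral_symmetry(_pairs_from_structure(asym, 2500, 2500, seed=4), "AE")
    assert res2.lrt_rg_one.p_value < 1e-4
    assert res2.lrt_equal_paths.p_value < 1e-4
    assert res2.rg.value < 0.9


def test_ae_data_prefers_ae_by_aic():
    """On AE-generated bilateral data the AE model matches the ACE model's
    AIC or better in most replicates."""
    s = PathwayStructure.from_paths(2, lambda_a=[0.7, 0.7], d_a=[0.3, 0.3],
                                    lambda_e=[0.4, 0.4], d_e=[0.4, 0.4])
    wins = 0
    reps = 20
    for sd in range(reps):
        pairs = _pairs_from_structure(s, 93, 68, seed=100 + sd)
        ace = fit_bilateral_ipm(pairs, "ACE", seed=0, n_starts=3)
        ae = fit_bilateral_ipm(pairs, "AE", seed=0, n_starts=3)
        wins += (ae.aic <= ace.aic + 1e-9)
    assert wins >= 0.8 * reps


def test_variance_proportions_closed_forms_and_oracle():
    """Single factor, no specifics -> 1.0; two disjoint columns with unit
    loadings -> 3/5 and 2/5; random structure matches the sum-of-squares
    oracle to 1e-12 and proportions always total 1."""
    one = PathwayStructure.from_paths(3, lambda_a=[1.0, 1.0, 1.0],
                                      lambda_e=[0.1] * 3, d_e=[0.5] * 3)
    vp = variance_proportions(one)
    assert vp.factor_proportions[0] == pytest.approx(1.0, abs=1e-12)
    assert vp.specific_proportion == pytest.approx(0.0, abs=1e-12)

    lam = np.zeros((5, 2))
    lam[:3, 0] = 1.0
    lam[3:, 1] = 1.0
    two = PathwayStructure.from_paths(5, lambda_a=lam, lambda_e=[0.1] * 5,
                                      d_e=[0.5] * 5)
    np.testing.assert_allclose(variance_proportions(two).factor_proportions,
                               [3 / 5, 2 / 5], atol=1e-12)

    rng = np.random.default_rng(1)
    lam = rng.normal(size=(4, 2))
    lam[0, 1] = 0.0
    d = rng.normal(size=4)
    s = PathwayStructure.from_paths(4, lambda_a=lam, d_a=d,
                                    lambda_e=[0.3] * 4, d_e=[0.4] * 4)
    vp = variance_proportions(s)
    total_ss = np.sum(lam ** 2) + np.sum(d ** 2)
    np.testing.assert_allclose(vp.factor_proportions,
                               np.sum(lam ** 2, axis=0) / total_ss, atol=1e-12)
    assert vp.total == pytest.approx(1.0, abs=1e-12)


def test_zero_genetic_variance_proportions_flagged_undefined():
    s = PathwayStructure.from_paths(2, lambda_e=[0.5, 0.5], d_e=[0.5, 0.5])
    assert variance_proportions(s).undefined


def test_single_trait_ipm_collapses_to_univariate_fit():
    """p=1, one common factor per component, no specifics: same maximum as
    the univariate ACE model."""
    pairs = make_pairs(0.5, 0.2, 0.3, 93, 68, seed=6)
    uni = fit_ml(pairs, "ACE", seed=0)
    from twinsem.likelihood import TwinData, maximize_loglik
    from twinsem.structures import PathwayParam
    param = PathwayParam(p=1, model_kind="ACE", k_a=1, k_c=1, k_e=1,
                         specific_a=False, specific_c=False, specific_e=False,
                         tie_common=True)
    ipm = maximize_loglik(TwinData(pairs), param, "ACE", seed=0)
    assert ipm.loglik == pytest.approx(uni.loglik, abs=1e-5)
    assert ipm.n_params == uni.n_params


def test_kfactor_recovers_disjoint_factor_supports():
    """Two genetic factors with disjoint supports are recovered up to
    column permutation and sign, max |deviation| < 0.15."""
    lam = np.array([[0.8, 0], [0.7, 0], [0.75, 0],
                    [0, 0.8], [0, 0.7], [0, 0.75]])
    lam_e = np.where(lam > 0, 0.35, 0.0)
    s = PathwayStructure.from_paths(6, lambda_a=lam, lambda_c=[[0.2]] * 6,
                                    lambda_e=lam_e, d_a=[0.25] * 6, d_e=[0.5] * 6)
    pairs = _pairs_from_structure(s, 1500, 1000, seed=7)
    fit = fit_kfactor_ipm(pairs, k_a=2, k_e=2, seed=0, n_starts=2)
    assert fit.converged
    got = fit.structure.lambda_a
    best = np.inf
    for perm in ([0, 1], [1, 0]):
        for s1 in (1, -1):
            for s2 in (1, -1):
                cand = got[:, perm] * np.array([s1, s2])
                best = min(best, np.abs(cand - lam).max())
    assert best < 0.15


def test_ipm_never_beats_saturated_cholesky_loglik():
    lam = np.array([[0.7, 0], [0.6, 0.2], [0, 0.7], [0.1, 0.6]])
    s = PathwayStructure.from_paths(4, lambda_a=lam, lambda_c=[[0.2]] * 4,
                                    lambda_e=np.abs(lam) * 0.5,
                                    d_a=[0.3] * 4, d_e=[0.5] * 4)
    pairs = _pairs_from_structure(s, 93, 68, seed=8)
    ipm = fit_kfactor_ipm(pairs, k_a=2, k_e=2, seed=0, n_starts=2)
    sat = fit_cholesky(pairs, "ACE", seed=0, n_starts=2)
    assert sat.loglik >= ipm.loglik - 1e-4
    assert sat.n_params > ipm.n_params


def test_too_many_factors_is_a_configuration_error():
    pairs = make_pairs(0.5, 0.2, 0.3, 20, 20, seed=9)
    with pytest.raises(ValueError, match="not identified"):
        fit_kfactor_ipm(pairs, k_a=1, k_e=1)
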