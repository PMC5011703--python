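import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from twinsem.errors import NumericError
from twinsem.io import TwinPair
from twinsem.likelihood import TwinData, concentrated_loglik, loglik
from twinsem.structures import (ACEStructure, CholeskyStructure,
                                UnivariateStructure, model_covariance)

from conftest import pairs_from_arrays


def _random_structure(rng, p=2):
    return CholeskyStructure.from_loadings(
        np.tril(rng.normal(size=(p, p))),
        0.5 * np.tril(rng.normal(size=(p, p))),
        np.tril(rng.normal(size=(p, p))) + 2 * np.eye(p))


def _random_pairs(rng, n=8, p=2, q=2):
    pairs = []
    for i in range(n):
        pairs.append(TwinPair(f"f{i}", "MZ" if i % 2 else "DZ",
                              y1=rng.normal(size=p), y2=rng.normal(size=p),
                              x1=np.r_[1.0, rng.normal(size=q - 1)],
                              x2=np.r_[1.0, rng.normal(size=q - 1)]))
    return pairs


def test_model_covariance_identity_when_only_e():
    s = UnivariateStructure.from_paths(0, 0, 1)
    for zyg in ("MZ", "DZ"):
        np.testing.assert_array_equal(model_covariance(s, zyg), np.eye(2))


def test_model_covariance_reproduces_published_frontal_row():
    """(a2, c2, e2) = (0.78, 0.01, 0.21) implies MZ off-diagonal 0.79, DZ 0.40."""
    s = UnivariateStructure.from_variances(0.78, 0.01, 0.21)
    assert model_covariance(s, "MZ")[0, 1] == pytest.approx(0.79)
    assert model_covariance(s, "DZ")[0, 1] == pytest.approx(0.40)


def test_model_covariance_matches_block_assembly_oracle():
    rng = np.random.default_rng(1)
    s = _random_structure(rng)
    for zyg, ga in (("MZ", 1.0), ("DZ", 0.5)):
        within = s.L_A @ s.L_A.T + s.L_C @ s.L_C.T + s.L_E @ s.L_E.T
        cross = ga * (s.L_A @ s.L_A.T) + s.L_C @ s.L_C.T
        expect = np.block([[within, cross], [cross, within]])
        np.testing.assert_allclose(model_covariance(s, zyg), expect, atol=1e-12)
        w = np.linalg.eigvalsh(model_covariance(s, zyg))
        assert w.min() > -1e-10


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_model_covariance_symmetric_psd_property(seed):
    """Any path-parameterised structure implies a symmetric PSD pair covariance."""
    rng = np.random.default_rng(seed)
    s = _random_structure(rng, p=3)
    for zyg in ("MZ", "DZ"):
        om = model_covariance(s, zyg)
        np.testing.assert_allclose(om, om.T, atol=1e-12)
        assert np.linalg.eigvalsh(om).min() > -1e-9


def test_single_standard_pair_density_and_additivity():
    """One MZ pair at the origin under pure E gives -ln(2*pi); duplicating
    the pair list doubles the log-likelihood."""
    pr = TwinPair("f", "MZ", y1=[0.0], y2=[0.0], x1=[1.0], x2=[1.0])
    s = UnivariateStructure.from_variances(0.0, 0.0, 1.0)
    one = loglik([pr], s, beta=[[0.0]])
    assert one == pytest.approx(-np.log(2 * np.pi), abs=1e-12)
    assert loglik([pr, pr], s, beta=[[0.0]]) == pytest.approx(2 * one, abs=1e-12)


def test_loglik_matches_multivariate_normal_oracle():
    """Concentrated and fixed-mean likelihoods agree with an independent
    multivariate-normal density evaluation to 1e-10."""
    rng = np.random.default_rng(2)
    pairs = _random_pairs(rng)
    s = _random_structure(rng)
    data = TwinData(pairs)
    ll, beta = concentrated_loglik(data, s.A, s.C, s.E, return_beta=True)

    def oracle(B):
        tot = 0.0
        for pr in pairs:
            om = model_covariance(s, pr.zygosity)
            mu = np.concatenate([B @ pr.x1, B @ pr.x2])
            tot += multivariate_normal.logpdf(
                np.concatenate([pr.y1, pr.y2]), mean=mu, cov=om)
        return tot

    assert ll == pytest.approx(oracle(beta), abs=1e-10)
    assert loglik(pairs, s, beta=beta) == pytest.approx(ll, abs=1e-10)
    # the concentrated value dominates any other mean coefficients
    for _ in range(5):
        assert oracle(beta + 0.05 * rng.normal(size=beta.shape)) < ll


def test_singular_covariance_reports_condition():
    pr = TwinPair("f", "MZ", y1=[0.0], y2=[0.0], x1=[1.0], x2=[1.0])
    s = UnivariateStructure.from_variances(1.0, 0.0, 0.0)  # MZ block singular
    with pytest.raises(NumericError, match="condition"):
        loglik([pr], s, beta=[[0.0]])


def test_full_information_path_uses_incomplete_pairs():
    """With one phenotype missing, the FIML likelihood equals the complete
    pairs' joint density plus the observed twin's marginal density."""
    rng = np.random.default_rng(3)
    s = UnivariateStructure.from_variances(0.5, 0.2, 0.3)
    complete = pairs_from_arrays(rng.normal(size=4), rng.normal(size=4),
                                 ["MZ", "DZ", "MZ", "DZ"])
    partial = TwinPair("fx", "MZ", y1=[0.7], y2=[np.nan], x1=[1.0], x2=[1.0])
    with_partial = TwinData(complete + [partial], include_incomplete=True)
    from twinsem.likelihood import _loglik_given_omegas
    from twinsem.structures import model_covariance as mc
    omegas = {z: mc(s, z) for z in ("MZ", "DZ")}
    ll_fiml, beta_hat = _loglik_given_omegas(with_partial, omegas, return_beta=True)
    # oracle: concentrated likelihood must exceed any fixed-mean evaluation,
    # and equal complete-pair density + marginal normal density at beta_hat
    marg = multivariate_normal.logpdf(0.7, mean=beta_hat[0, 0], cov=s.total[0, 0])
    assert ll_fiml == pytest.approx(loglik(complete, s, beta=beta_hat) + marg,
                                    abs=1e-10)
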