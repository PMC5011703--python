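"""Independent-pathway models (IPM).

Two flavours are provided:

* the bilateral model for the (left, right) volumes of one structure —
  one common factor per component with equal loadings on both
  hemispheres (the identification constraint) plus hemisphere-specific
  paths; it supports the likelihood-ratio tests of r_G = 0, of perfect
  bilateral genetic symmetry (r_G = 1, i.e. no hemisphere-specific
  genetic variance) and of equal left/right specific paths;

* the k-factor model for a set of regional volumes — k common additive
  genetic factors (echelon zeros identify the rotation), k common
  unique-environment factors, a single common shared-environment factor
  by default, and region-specific genetic and unique-environment paths.

The share of total genetic variance carried by each common factor is
the sum of squares of its path coefficients divided by the sum of
squares of all genetic path coefficients (common and specific).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConvergenceError
from .likelihood import FitResult, TwinData, maximize_loglik
from .structures import PathwayParam, PathwayStructure
from .univariate import LRTResult, lrt


def fit_bilateral_ipm(pairs, model_kind: str = "ACE", *, n_starts: int = 5,
                      seed: int = 0, specific_a: bool = True,
                      tie_specifics: bool = False,
                      common_a: bool = True) -> FitResult:
    """Fit the bilateral independent-pathway model to (left, right) pairs.

    The common loadings are tied equal across hemispheres (Fig-style
    identification constraint a_c1 = a_c2, etc.).  ``specific_a=False``
    removes hemisphere-specific genetic paths (the r_G = 1 constraint);
    ``common_a=False`` removes the common genetic factor (r_G = 0);
    ``tie_specifics`` equates left and right specific paths of every
    component (the lateral-symmetry constraint).
    """
    data = pairs if isinstance(pairs, TwinData) else TwinData(pairs)
    if data.p != 2:
        raise ValueError("bilateral IPM expects exactly two phenotypes (left, right)")
    param = PathwayParam(p=2, model_kind=model_kind,
                         k_a=1 if common_a else 0, k_c=1, k_e=1,
                         specific_a=specific_a, specific_c=True, specific_e=True,
                         tie_common=True, tie_specifics=tie_specifics)
    return maximize_loglik(data, param, model_kind, n_starts=n_starts, seed=seed)


def bilateral_rg(structure: PathwayStructure):
    """Genetic correlation implied by a bilateral IPM structure.

    With common loading a_c and specific paths a_s1, a_s2 this is
    a_c^2 / sqrt((a_c^2 + a_s1^2)(a_c^2 + a_s2^2)); equivalently the
    normalised off-diagonal of the implied A matrix.
    """
    from .cholesky import genetic_correlation
    return genetic_correlation(structure, 0, 1, source_model="bilateral-IPM")


@dataclass
class BilateralSymmetryResult:
    """r_G between hemispheres and the likelihood-ratio tests around it."""

    rg: object                       # CorrelationEstimate
    lrt_rg_one: LRTResult            # no hemisphere-specific genetic variance (df=2)
    lrt_rg_zero: LRTResult           # no common genetic factor (df=1)
    lrt_equal_paths: LRTResult       # left/right specific paths equal (df=3 for ACE)
    fit: FitResult


def test_bilateral_symmetry(pairs, model_kind: str = "AE", *, seed: int = 0,
                            n_starts: int = 5) -> BilateralSymmetryResult:
    """Estimate the bilateral r_G and test r_G = 1, r_G = 0 and path equality.

    The r_G = 1 test drops both hemisphere-specific genetic paths
    (df = 2); the r_G = 0 test drops the common genetic factor (df = 1);
    the equality test ties every component's specific paths across
    hemispheres.
    """
    data = pairs if isinstance(pairs, TwinData) else TwinData(pairs)
    full = fit_bilateral_ipm(data, model_kind, seed=seed, n_starts=n_starts)
    no_spec = fit_bilateral_ipm(data, model_kind, seed=seed, n_starts=n_starts,
                                specific_a=False)
    no_common = fit_bilateral_ipm(data, model_kind, seed=seed, n_starts=n_starts,
                                  common_a=False)
    tied = fit_bilateral_ipm(data, model_kind, seed=seed, n_starts=n_starts,
                             tie_specifics=True)
    for f in (full, no_spec, no_common, tied):
        if not f.converged:
            raise ConvergenceError("a bilateral IPM fit did not converge")
    est = bilateral_rg(full.structure)
    est.test_one = lrt(full, no_spec)
    est.test_zero = lrt(full, no_common)
    return BilateralSymmetryResult(rg=est, lrt_rg_one=est.test_one,
                                   lrt_rg_zero=est.test_zero,
                                   lrt_equal_paths=lrt(full, tied), fit=full)


def fit_kfactor_ipm(pairs, k_a: int = 3, k_e: Optional[int] = None, *,
                    model_kind: str = "ACE", shared_c: str = "single",
                    specific_c: bool = False, n_starts: int = 3,
                    seed: int = 0, maxiter: int = 4000) -> FitResult:
    """Fit the k-factor IPM over p regional volumes.

    ``shared_c="single"`` uses one common shared-environment factor (the
    default, with no region-specific C paths unless ``specific_c``);
    region-specific genetic and unique-environment paths are always
    included.  Echelon zeros (loading[i, j] = 0 for j > i) pin down the
    factor rotation, and the first nonzero loading of each factor is
    reported positive.
    """
    data = pairs if isinstance(pairs, TwinData) else TwinData(pairs)
    k_e = k_a if k_e is None else k_e
    if shared_c == "single":
        k_c = 1 if "C" in model_kind else 0
    elif shared_c == "matched":
        k_c = k_a if "C" in model_kind else 0
    else:
        raise ValueError("shared_c must be 'single' or 'matched'")
    if max(k_a, k_e) >= data.p:
        raise ValueError(
            f"{max(k_a, k_e)} common factors are not identified with p={data.p}")
    param = PathwayParam(p=data.p, model_kind=model_kind, k_a=k_a, k_c=k_c, k_e=k_e,
                         specific_a=True, specific_c=specific_c, specific_e=True)
    return maximize_loglik(data, param, model_kind, n_starts=n_starts, seed=seed,
                           maxiter=maxiter)


@dataclass
class VarianceProportions:
    """Decomposition of total genetic variance over common factors and specifics."""

    factor_proportions: np.ndarray    # one share per common genetic factor
    specific_proportion: float        # all region-specific genetic paths pooled
    within_factor_shares: list        # per factor: squared loading / factor sum of squares
    undefined: bool = False

    @property
    def total(self) -> float:
        return float(np.sum(self.factor_proportions) + self.specific_proportion)


def variance_proportions(structure: PathwayStructure) -> VarianceProportions:
    """Shares of total genetic variance explained by each common factor.

    prop(factor j) = ||Lambda_A[:, j]||^2 / (sum_j ||Lambda_A[:, j]||^2
    + sum_i d_A[i]^2); within a factor, each region's share is its
    squared loading over the factor's sum of squares.
    """
    lam, d = structure.lambda_a, structure.d_a
    factor_ss = np.sum(lam ** 2, axis=0)
    spec_ss = float(np.sum(d ** 2))
    total = float(np.sum(factor_ss) + spec_ss)
    if total <= 0:
        return VarianceProportions(
            factor_proportions=np.full(lam.shape[1], np.nan),
            specific_proportion=float("nan"), within_factor_shares=[],
            undefined=True)
    shares = [lam[:, j] ** 2 / factor_ss[j] if factor_ss[j] > 0
              else np.full(lam.shape[0], np.nan)
              for j in range(lam.shape[1])]
    return VarianceProportions(factor_proportions=factor_ss / total,
                               specific_proportion=spec_ss / total,
                               within_factor_shares=shares)
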