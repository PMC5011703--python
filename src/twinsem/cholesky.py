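"""Multivariate Cholesky ACE models and derived component correlations.

The Cholesky (triangular-decomposition) model is the saturated member of
the ACE class: each of A, C and E is parameterised by a full lower
triangle, so every positive-semidefinite component covariance is
reachable.  Genetic correlations between traits i and j are
``r_G = A_ij / sqrt(A_ii A_jj)``, with shared- and unique-environment
and phenotypic correlations defined analogously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConvergenceError
from .likelihood import FitResult, TwinData, maximize_loglik
from .structures import CholeskyParam
from .univariate import LRTResult, lrt

#: a trait's component variance below this fraction of its total variance
#: makes correlations with that trait undefined rather than +/-1
UNDEFINED_VARIANCE_FRACTION = 1e-10


def fit_cholesky(pairs, model_kind: str = "ACE", *, n_starts: int = 5, seed: int = 0,
                 zero_paths: Optional[dict] = None, include_incomplete: bool = False,
                 covariate_names=None) -> FitResult:
    """ML fit of a p-variate Cholesky ACE/AE/CE/E model, covariates in means.

    ``zero_paths`` pins individual loading entries at zero, e.g.
    ``{"A": [(1, 0)]}`` removes the genetic cross-path of a bivariate
    model (the constrained model of the r_G = 0 test).
    """
    data = pairs if isinstance(pairs, TwinData) else TwinData(
        pairs, include_incomplete=include_incomplete)
    param = CholeskyParam(p=data.p, model_kind=model_kind,
                          zero_paths=zero_paths or {})
    return maximize_loglik(data, param, model_kind, n_starts=n_starts, seed=seed,
                           covariate_names=covariate_names)


@dataclass
class CorrelationMatrixResult:
    """A component correlation matrix with an undefined-entry mask."""

    kind: str
    values: np.ndarray
    undefined: np.ndarray
    labels: Optional[list] = None

    def as_frame(self) -> pd.DataFrame:
        lab = self.labels or [f"trait_{i + 1}" for i in range(self.values.shape[0])]
        df = pd.DataFrame(self.values, index=lab, columns=lab)
        return df.mask(pd.DataFrame(self.undefined, index=lab, columns=lab))


_KIND_TO_MATRIX = {
    "genetic": "A",
    "shared_env": "C",
    "unique_env": "E",
}


def component_correlations(structure, kind: str = "genetic",
                           labels=None) -> CorrelationMatrixResult:
    """Correlation matrix of one variance component (or phenotypic from the total).

    Traits whose component variance is numerically zero (below
    ``UNDEFINED_VARIANCE_FRACTION`` of their total variance) yield
    *undefined* correlations, flagged in the mask instead of being
    propagated as NaN or clipped to +/-1.
    """
    if kind == "phenotypic":
        M = structure.total
        diag_ok = np.diag(M) > 0
    else:
        try:
            M = getattr(structure, _KIND_TO_MATRIX[kind])
        except KeyError:
            raise ValueError(
                "kind must be genetic, shared_env, unique_env or phenotypic")
        diag_ok = np.diag(M) > UNDEFINED_VARIANCE_FRACTION * np.diag(structure.total)
    p = M.shape[0]
    d = np.where(diag_ok, np.sqrt(np.where(diag_ok, np.diag(M), 1.0)), 1.0)
    vals = M / np.outer(d, d)
    np.fill_diagonal(vals, 1.0)
    undef = ~(np.outer(diag_ok, diag_ok))
    vals = np.where(undef, np.nan, np.clip(vals, -1.0, 1.0))
    return CorrelationMatrixResult(kind=kind, values=vals, undefined=undef,
                                   labels=list(labels) if labels else None)


@dataclass
class CorrelationEstimate:
    """One genetic (or environmental) correlation and its likelihood tests."""

    kind: str
    value: float
    undefined: bool
    source_model: str
    test_zero: Optional[LRTResult] = None
    test_one: Optional[LRTResult] = None


def genetic_correlation(structure, i: int = 0, j: int = 1,
                        source_model: str = "ACE") -> CorrelationEstimate:
    """The genetic correlation r_G between traits i and j of a fitted structure."""
    res = component_correlations(structure, "genetic")
    undef = bool(res.undefined[i, j])
    return CorrelationEstimate(kind="genetic",
                               value=float("nan") if undef else float(res.values[i, j]),
                               undefined=undef, source_model=source_model)


def test_rg_zero(pairs, i: int = 0, j: int = 1, *, model_kind: str = "ACE",
                 seed: int = 0, n_starts: int = 5) -> CorrelationEstimate:
    """LRT of r_G = 0 between two traits via the bivariate Cholesky model.

    The constrained model forces the genetic cross-loading to zero
    (A_ij = 0), a one-degree-of-freedom restriction.
    """
    data = pairs if isinstance(pairs, TwinData) else TwinData(pairs)
    if data.p != 2:
        raise ValueError("test_rg_zero expects pairs over exactly two traits")
    if (i, j) != (0, 1) and (i, j) != (1, 0):
        raise ValueError("for a bivariate fit the trait indices are 0 and 1")
    full = fit_cholesky(data, model_kind, seed=seed, n_starts=n_starts)
    constrained = fit_cholesky(data, model_kind, seed=seed, n_starts=n_starts,
                               zero_paths={"A": [(1, 0)]})
    if not (full.converged and constrained.converged):
        raise ConvergenceError("bivariate fit did not converge")
    est = genetic_correlation(full.structure, 0, 1, source_model=model_kind)
    est.test_zero = lrt(full, constrained)
    return est
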