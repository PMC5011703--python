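"""Maximum-likelihood machinery for twin-pair models.

A twin pair contributes a 2p-variate normal log-density with mean
(B x1, B x2) and the zygosity-specific model covariance.  For a fixed
covariance structure the mean coefficients B have a closed-form GLS
solution, so the likelihood is concentrated over B and the numerical
optimisation runs only over the covariance path parameters.  All
per-pair sums reduce to sufficient statistics (cross-moment matrices per
zygosity group), making each likelihood evaluation independent of the
number of pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg, optimize

from .errors import ConvergenceError, NumericError
from .structures import GAMMA_A, GAMMA_C, rescale_structure

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class GroupStats:
    """Sufficient statistics of one zygosity group (complete pairs only)."""

    n: int                      # number of pairs
    Z: np.ndarray               # (n, 2, p) phenotype values, twin-major
    X: np.ndarray               # (n, 2, q) covariate design rows
    G: np.ndarray = None        # (2, 2, q, q): G[j,k] = X_j' X_k
    CZ: np.ndarray = None       # (2, 2, p, p): CZ[j,k] = Z_j' Z_k
    H: np.ndarray = None        # (2, 2, p, q): H[j,k] = Z_j' X_k

    def __post_init__(self):
        p, q = self.Z.shape[2], self.X.shape[2]
        self.G = np.empty((2, 2, q, q))
        self.CZ = np.empty((2, 2, p, p))
        self.H = np.empty((2, 2, p, q))
        for j in range(2):
            for k in range(2):
                self.G[j, k] = self.X[:, j, :].T @ self.X[:, k, :]
                self.CZ[j, k] = self.Z[:, j, :].T @ self.Z[:, k, :]
                self.H[j, k] = self.Z[:, j, :].T @ self.X[:, k, :]


class TwinData:
    """Pairs grouped by zygosity, reduced to cross-moment statistics.

    Pairs with missing values in the selected phenotypes are dropped
    (complete-pair analysis); pass ``include_incomplete=True`` to keep
    them and evaluate a full-information likelihood over the observed
    entries of each pair.
    """

    def __init__(self, pairs, include_incomplete: bool = False):
        pairs = list(pairs)
        if not pairs:
            raise ValueError("no twin pairs supplied")
        self.p = len(pairs[0].y1)
        self.q = len(pairs[0].x1)
        self.groups: dict[str, GroupStats] = {}
        self.incomplete: list = []
        by_zyg = {"MZ": [], "DZ": []}
        for pr in pairs:
            if pr.complete:
                by_zyg[pr.zygosity].append(pr)
            elif include_incomplete:
                self.incomplete.append(pr)
        for zyg, prs in by_zyg.items():
            if not prs:
                continue
            Z = np.stack([np.stack([pr.y1, pr.y2]) for pr in prs])
            X = np.stack([np.stack([pr.x1, pr.x2]) for pr in prs])
            self.groups[zyg] = GroupStats(n=len(prs), Z=Z, X=X)
        self.n_pairs_used = {z: g.n for z, g in self.groups.items()}

    def standardized(self) -> tuple["TwinData", np.ndarray]:
        """Copy with each phenotype scaled to unit pooled variance.

        Returns the scaled data and the per-trait standard deviations
        used, so fitted structures can be mapped back to raw units.
        """
        Zs = [g.Z.reshape(-1, self.p) for g in self.groups.values()]
        sd = np.std(np.vstack(Zs), axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        clone = object.__new__(TwinData)
        clone.p, clone.q = self.p, self.q
        clone.groups = {z: GroupStats(n=g.n, Z=g.Z / sd, X=g.X)
                        for z, g in self.groups.items()}
        clone.incomplete = [
            _ScaledPair(pr, sd) for pr in self.incomplete]
        clone.n_pairs_used = dict(self.n_pairs_used)
        return clone, sd

    # -- moment estimates used for optimiser start values ------------------

    def moment_components(self) -> dict[str, np.ndarray]:
        """Crude A/C/E estimates from OLS-residual twin covariances."""
        Zs, Xs = [], []
        for g in self.groups.values():
            Zs.append(g.Z.reshape(-1, self.p))
            Xs.append(g.X.reshape(-1, self.q))
        Zall, Xall = np.vstack(Zs), np.vstack(Xs)
        beta, *_ = np.linalg.lstsq(Xall, Zall, rcond=None)
        within, cross = {}, {}
        for zyg, g in self.groups.items():
            R = g.Z - np.einsum("ntq,qp->ntp", g.X, beta)
            R = R - R.reshape(-1, self.p).mean(axis=0)
            within[zyg] = (R[:, 0].T @ R[:, 0] + R[:, 1].T @ R[:, 1]) / (2 * g.n)
            cr = R[:, 0].T @ R[:, 1] / g.n
            cross[zyg] = 0.5 * (cr + cr.T)
        sig = np.mean(list(within.values()), axis=0)
        c_mz = cross.get("MZ", 0.5 * sig)
        c_dz = cross.get("DZ", 0.25 * sig)
        A = 2.0 * (c_mz - c_dz)
        C = 2.0 * c_dz - c_mz
        E = sig - c_mz
        return {"A": A, "C": C, "E": E, "Sigma": sig, "beta": beta}


class _ScaledPair:
    """View of a (possibly incomplete) pair with phenotypes rescaled."""

    def __init__(self, pair, sd):
        self.zygosity = pair.zygosity
        self.mask1, self.mask2 = pair.mask1, pair.mask2
        self.y1 = np.where(pair.mask1, pair.y1 / sd, 0.0)
        self.y2 = np.where(pair.mask2, pair.y2 / sd, 0.0)
        self.x1, self.x2 = pair.x1, pair.x2


def _omega_blocks(A, C, E, zyg):
    within = A + C + E
    cross = GAMMA_A[zyg] * A + GAMMA_C[zyg] * C
    return within, cross


def concentrated_loglik(data: TwinData, A, C, E, return_beta: bool = False):
    """Log-likelihood maximised over the mean coefficients B (p x q).

    Returns ``-inf`` when the implied pair covariance is not positive
    definite, which lets unconstrained optimisers back away from
    infeasible path values.
    """
    omegas = {}
    for zyg in data.groups:
        within, cross = _omega_blocks(A, C, E, zyg)
        omegas[zyg] = np.block([[within, cross], [cross, within]])
    return _loglik_given_omegas(data, omegas, return_beta=return_beta)


def _loglik_given_omegas(data: TwinData, omegas: dict, return_beta: bool = False):
    p, q = data.p, data.q
    pq = p * q
    M = np.zeros((pq, pq))
    v = np.zeros((p, q))
    S0 = 0.0
    const = 0.0
    for zyg, g in data.groups.items():
        omega = omegas[zyg]
        try:
            cf = linalg.cho_factor(omega, check_finite=False)
        except linalg.LinAlgError:
            return (-np.inf, None) if return_beta else -np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        W = linalg.cho_solve(cf, np.eye(2 * p), check_finite=False)
        Wb = W.reshape(2, p, 2, p).transpose(0, 2, 1, 3)  # Wb[j,k] p x p
        const += -g.n * p * _LOG2PI - 0.5 * g.n * logdet
        for j in range(2):
            for k in range(2):
                M += np.kron(g.G[j, k], Wb[j, k])
                v += Wb[j, k] @ g.H[k, j]
                S0 += float(np.sum(Wb[j, k] * g.CZ[k, j].T))
    # incomplete pairs: per-pair observed-data terms (full-information path)
    for pr in data.incomplete:
        obs = np.concatenate([pr.mask1, pr.mask2])
        if not obs.any():
            continue
        omega = _pair_omega(omegas, pr.zygosity)[np.ix_(obs, obs)]
        try:
            cf = linalg.cho_factor(omega, check_finite=False)
        except linalg.LinAlgError:
            return (-np.inf, None) if return_beta else -np.inf
        z = np.concatenate([pr.y1, pr.y2])[obs]
        D = np.vstack([_design_block(pr.x1, p), _design_block(pr.x2, p)])[obs]
        Wi = linalg.cho_solve(cf, np.eye(obs.sum()), check_finite=False)
        const += -0.5 * obs.sum() * _LOG2PI - np.sum(np.log(np.diag(cf[0])))
        M += D.T @ Wi @ D
        v += (D.T @ Wi @ z).reshape(p, q, order="F")
        S0 += float(z @ Wi @ z)
    if not (np.isfinite(M).all() and np.isfinite(v).all() and np.isfinite(S0)):
        return (-np.inf, None) if return_beta else -np.inf
    vflat = v.reshape(-1, order="F")
    try:
        beta = np.linalg.solve(M, vflat)
    except np.linalg.LinAlgError:
        raise NumericError("mean-model design is singular; check covariate collinearity")
    quad = S0 - float(vflat @ beta)
    ll = const - 0.5 * quad
    if return_beta:
        return ll, beta.reshape(p, q, order="F")
    return ll


def loglik(pairs, structure, beta=None, include_incomplete: bool = False) -> float:
    """Log-likelihood of twin pairs under an ACE structure.

    With ``beta`` (p x q mean coefficients, applied to each twin's
    covariate row) the density is evaluated at those means; without it
    the mean model is profiled out at its GLS optimum.
    """
    data = pairs if isinstance(pairs, TwinData) else TwinData(
        pairs, include_incomplete=include_incomplete)
    if beta is None:
        return concentrated_loglik(data, structure.A, structure.C, structure.E)
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    total = 0.0
    for zyg, g in data.groups.items():
        within, cross = _omega_blocks(structure.A, structure.C, structure.E, zyg)
        omega = np.block([[within, cross], [cross, within]])
        try:
            cf = linalg.cho_factor(omega, check_finite=False)
        except linalg.LinAlgError:
            raise NumericError(
                f"model covariance for {zyg} pairs is singular "
                f"(condition number {np.linalg.cond(omega):.3g})")
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        mu = np.concatenate([
            np.einsum("pq,ntq->ntp", beta, g.X)[:, 0, :],
            np.einsum("pq,ntq->ntp", beta, g.X)[:, 1, :]], axis=1)
        R = g.Z.transpose(0, 1, 2).reshape(g.n, -1) - mu
        sol = linalg.cho_solve(cf, R.T, check_finite=False)
        total += (-g.n * data.p * _LOG2PI - 0.5 * g.n * logdet
                  - 0.5 * float(np.sum(R.T * sol)))
    return total


def _design_block(x, p):
    # rows of (x' kron I_p) for F-order vec(B), B is p x q
    q = len(x)
    D = np.zeros((p, p * q))
    for c in range(q):
        D[:, c * p:(c + 1) * p] = x[c] * np.eye(p)
    return D


def _pair_omega(omegas, zyg):
    return omegas[zyg]


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood twin-model fit.

    ``n_params`` counts free covariance path parameters plus mean
    coefficients; ``aic = -2 loglik + 2 n_params``.
    """

    structure: object
    mean_coefficients: np.ndarray       # p x q
    loglik: float
    n_params: int
    aic: float
    converged: bool
    n_pairs_used: dict
    model_kind: str
    parameterization: object = field(repr=False, default=None)
    theta: np.ndarray = field(repr=False, default=None)
    data: TwinData = field(repr=False, default=None)
    covariate_names: Optional[list] = None

    def variance_decomposition(self, level: float = 0.95):
        from .univariate import variance_decomposition
        return variance_decomposition(self, level=level)


def maximize_loglik(data: TwinData, param, model_kind: str, *, n_starts: int = 5,
                    seed: int = 0, maxiter: int = 2000,
                    covariate_names=None) -> FitResult:
    """Multi-start quasi-Newton maximisation of the concentrated likelihood."""
    rng = np.random.default_rng(seed)
    # optimise on unit-variance traits: scale-free numerics, identical
    # problems for rescaled inputs; estimates are mapped back afterwards
    sdata, scale = data.standardized()
    moments = sdata.moment_components()
    starts = param.start_points(moments, rng, n_starts=n_starts)

    def negll(theta):
        A, C, E = param.build(theta)
        ll = concentrated_loglik(sdata, A, C, E)
        return 1e12 if not np.isfinite(ll) else -ll

    best = None
    any_success = False
    for s in starts:
        res = optimize.minimize(negll, s, method="L-BFGS-B",
                                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
        any_success = any_success or (res.success and res.fun < 1e11)
    theta = best.x
    structure = rescale_structure(param.to_structure(theta), scale)
    ll, beta = concentrated_loglik(data, structure.A, structure.C, structure.E,
                                   return_beta=True)
    n_params = param.n_theta + data.p * data.q
    converged = bool(any_success and np.isfinite(ll))
    return FitResult(
        structure=structure, mean_coefficients=beta, loglik=float(ll),
        n_params=n_params, aic=float(-2.0 * ll + 2.0 * n_params),
        converged=converged, n_pairs_used=dict(data.n_pairs_used),
        model_kind=model_kind, parameterization=param, theta=theta,
        data=data, covariate_names=list(covariate_names) if covariate_names else None,
    )


def refit_loglik(fit: FitResult, data: Optional[TwinData] = None) -> float:
    """Evaluate a fit's concentrated log-likelihood on (possibly new) data."""
    data = data or fit.data
    s = fit.structure
    return concentrated_loglik(data, s.A, s.C, s.E)


def check_nesting(fit_full: FitResult, fit_nested: FitResult, tol: float = 1e-4) -> None:
    if fit_nested.loglik > fit_full.loglik + tol:
        raise ConvergenceError(
            "nested model log-likelihood exceeds the full model's "
            f"({fit_nested.loglik:.6f} > {fit_full.loglik:.6f}); optimiser failure")
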