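"""Univariate ACE-family fitting, profile confidence intervals, likelihood
ratio tests and intraclass correlations.

The variance decomposition reported is h2 = a^2 / (a^2 + c^2 + e^2) and
analogously c2, e2; profile-likelihood 95% intervals invert the chi^2(1)
likelihood-ratio cutoff (3.841 at 0.95) on the proportion scale and are
truncated to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ConvergenceError, DegenerateDataError, NumericError
from .likelihood import (FitResult, TwinData, check_nesting,
                         concentrated_loglik, maximize_loglik)
from .structures import CholeskyParam

MODEL_KINDS = ("ACE", "AE", "CE", "E")


def fit_ml(pairs, model_kind: str = "ACE", *, n_starts: int = 5, seed: int = 0,
           include_incomplete: bool = False, covariate_names=None) -> FitResult:
    """Maximum-likelihood fit of a univariate ACE/AE/CE/E model.

    ``pairs`` carry both the phenotype (p = 1) and the mean-model design;
    covariates are adjusted in the means, never pre-residualised.
    """
    data = pairs if isinstance(pairs, TwinData) else TwinData(
        pairs, include_incomplete=include_incomplete)
    if data.p != 1:
        raise ValueError(f"fit_ml is univariate; got p={data.p} (use fit_cholesky)")
    param = CholeskyParam(p=1, model_kind=model_kind)
    return maximize_loglik(data, param, model_kind, n_starts=n_starts, seed=seed,
                           covariate_names=covariate_names)


def fit_model_ladder(pairs, *, seed: int = 0, n_starts: int = 5) -> dict[str, FitResult]:
    """Fit ACE, AE, CE and E to the same pairs (the model-selection ladder)."""
    data = pairs if isinstance(pairs, TwinData) else TwinData(pairs)
    return {kind: fit_ml(data, kind, seed=seed, n_starts=n_starts)
            for kind in MODEL_KINDS}


@dataclass
class VarianceDecomposition:
    """Standardised variance shares with profile 95% intervals."""

    h2: float
    c2: float
    e2: float
    total: float
    ci_h2: tuple = None
    ci_c2: tuple = None
    ci_e2: tuple = None

    def as_dict(self):
        return {"h2": self.h2, "c2": self.c2, "e2": self.e2, "total_variance": self.total,
                "ci_h2": self.ci_h2, "ci_c2": self.ci_c2, "ci_e2": self.ci_e2}


def variance_decomposition(fit: FitResult, level: float = 0.95,
                           with_ci: bool = False) -> VarianceDecomposition:
    s = fit.structure
    va, vc, ve = float(s.A[0, 0]), float(s.C[0, 0]), float(s.E[0, 0])
    tot = va + vc + ve
    dec = VarianceDecomposition(h2=va / tot, c2=vc / tot, e2=ve / tot, total=tot)
    if with_ci:
        dec.ci_h2 = profile_ci(fit, "h2", level=level)
        dec.ci_c2 = profile_ci(fit, "c2", level=level)
        dec.ci_e2 = profile_ci(fit, "e2", level=level)
    return dec


def _constrained_ll(data: TwinData, component: str, t: float, x0=None):
    """Profile log-likelihood at a fixed variance share ``t`` of ``component``.

    Free parameters: log total variance and a bounded mixing weight that
    splits the remaining share 1 - t between the other two components.
    """
    order = {"h2": ("A", "C", "E"), "c2": ("C", "A", "E"), "e2": ("E", "A", "C")}[component]

    def neg(z):
        logv, w = z
        v = np.exp(logv)
        rest = 1.0 - t
        shares = {order[0]: t, order[1]: rest * w, order[2]: rest * (1.0 - w)}
        try:
            ll = concentrated_loglik(data, np.array([[v * shares["A"]]]),
                                     np.array([[v * shares["C"]]]),
                                     np.array([[v * shares["E"]]]))
        except NumericError:
            return 1e12
        return 1e12 if not np.isfinite(ll) else -ll

    if x0 is not None:
        starts = [np.asarray(x0, dtype=float)]
    else:
        moments = data.moment_components()
        v0 = max(float(moments["Sigma"][0, 0]), 1e-12)
        starts = [np.array([np.log(v0), 0.25]), np.array([np.log(v0), 0.75])]
    best = None
    for s in starts:
        res = optimize.minimize(neg, s, method="L-BFGS-B",
                                bounds=[(None, None), (0.0, 1.0)],
                                options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun, best.x


def profile_ci(fit: FitResult, component: str = "h2", level: float = 0.95
               ) -> tuple[float, float]:
    """Profile-likelihood interval for h2, c2 or e2, truncated to [0, 1].

    Bounds solve 2 (loglik_max - loglik_profile(t)) = chi^2_1 quantile
    (3.841 at the 0.95 level); a boundary estimate yields a one-sided
    interval with the bound pinned at 0 or 1.
    """
    if not fit.converged:
        raise ConvergenceError("profile_ci requires a converged fit")
    if component not in ("h2", "c2", "e2"):
        raise ValueError("component must be one of h2, c2, e2")
    data = fit.data
    dec = variance_decomposition(fit)
    t_hat = {"h2": dec.h2, "c2": dec.c2, "e2": dec.e2}[component]
    cut = stats.chi2.ppf(level, df=1) / 2.0
    target = fit.loglik - cut

    cache = {}

    def pll(t):
        t = min(max(t, 0.0), 1.0 - 1e-9)
        if t not in cache:
            near = min(cache, key=lambda s: abs(s - t)) if cache else None
            x0 = cache[near][1] if near is not None else None
            cache[t] = _constrained_ll(data, component, t, x0=x0)
        return cache[t][0]

    def f(t):
        return pll(t) - target

    lo = 0.0 if f(0.0) >= 0 else optimize.brentq(f, 0.0, t_hat, xtol=2e-4)
    hi_edge = 1.0 - 1e-6
    if t_hat >= hi_edge:
        hi = 1.0
    elif f(hi_edge) >= 0:
        hi = 1.0
    else:
        hi = optimize.brentq(f, t_hat, hi_edge, xtol=2e-4)
    return (float(max(lo, 0.0)), float(min(hi, 1.0)))


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


def lrt(fit_full: FitResult, fit_nested: FitResult) -> LRTResult:
    """Likelihood-ratio test of a nested against a full model.

    The statistic is clamped at zero; the p-value uses the plain
    chi-square reference with df equal to the parameter-count drop
    (conservative when a variance sits on the boundary).
    """
    check_nesting(fit_full, fit_nested)
    df = fit_full.n_params - fit_nested.n_params
    if df < 0:
        raise ValueError("models are not nested: the full model has fewer parameters")
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_nested.loglik))
    if df == 0:  # identical parameterizations: no test, trivially retained
        return LRTResult(statistic=stat, df=0, p_value=1.0)
    return LRTResult(statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)))


def implied_twin_correlations(decomp) -> tuple[float, float]:
    """Model-implied twin correlations (r_MZ, r_DZ) = (h2 + c2, h2/2 + c2)."""
    if isinstance(decomp, VarianceDecomposition):
        h2, c2, e2 = decomp.h2, decomp.c2, decomp.e2
    else:
        h2, c2, e2 = decomp
    if abs(h2 + c2 + e2 - 1.0) > 1e-6:
        raise ValueError("variance shares must sum to 1")
    return (h2 + c2, 0.5 * h2 + c2)


@dataclass
class ICCResult:
    estimate: float
    ci: tuple
    loglik: float
    n_pairs: int


def icc(pairs, level: float = 0.95) -> ICCResult:
    """Within-pair intraclass correlation by maximum likelihood.

    Fits a bivariate normal with a common (covariate-adjusted) mean and
    variance for both members of each pair and correlation r; the
    confidence interval is by profile likelihood.  All supplied pairs
    must share one zygosity.
    """
    data = pairs if isinstance(pairs, TwinData) else TwinData(pairs)
    if data.p != 1:
        raise ValueError("icc expects a single phenotype")
    if len(data.groups) != 1:
        raise ValueError("icc expects pairs of a single zygosity")
    zyg = next(iter(data.groups))
    n = data.groups[zyg].n
    if n < 3:
        raise DegenerateDataError("at least 3 pairs are needed for an ICC")

    from .likelihood import _loglik_given_omegas

    def ll_at(z):
        logv, u = z
        r = np.clip(np.tanh(u), -1 + 1e-10, 1 - 1e-10)
        omega = np.exp(logv) * np.array([[1.0, r], [r, 1.0]])
        try:
            return _loglik_given_omegas(data, {zyg: omega})
        except NumericError:
            return -np.inf

    def neg(z):
        ll = ll_at(z)
        return 1e12 if not np.isfinite(ll) else -ll

    v0 = float(data.moment_components()["Sigma"][0, 0])
    if v0 <= 0 or not np.isfinite(v0):
        raise DegenerateDataError("phenotype variance is degenerate")
    res = optimize.minimize(neg, np.array([np.log(v0), 0.2]), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-11, "maxiter": 800})
    ll_max = -res.fun
    r_hat = float(np.tanh(res.x[1]))
    cut = stats.chi2.ppf(level, df=1) / 2.0
    target = ll_max - cut

    def pll(r):
        r = float(np.clip(r, -1 + 1e-9, 1 - 1e-9))

        def negv(lv):
            omega = np.exp(lv[0]) * np.array([[1.0, r], [r, 1.0]])
            try:
                ll = _loglik_given_omegas(data, {zyg: omega})
            except NumericError:
                return 1e12
            return 1e12 if not np.isfinite(ll) else -ll

        out = optimize.minimize_scalar(lambda lv: negv([lv]), method="bounded",
                                       bounds=(res.x[0] - 6, res.x[0] + 6))
        return -out.fun

    def f(r):
        return pll(r) - target

    edge = 1 - 1e-6
    rb = float(np.clip(r_hat, -edge, edge))
    if f(-edge) >= 0:
        lo = -1.0
    else:
        lo = optimize.brentq(f, -edge, rb, xtol=1e-6) if f(rb) > 0 else rb
    if f(edge) >= 0:
        hi = 1.0
    else:
        hi = optimize.brentq(f, rb, edge, xtol=1e-6) if f(rb) > 0 else rb
    return ICCResult(estimate=r_hat, ci=(float(lo), float(hi)),
                     loglik=float(ll_max), n_pairs=n)
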