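"""Variance-component structures for the classical twin design.

The phenotypic covariance of a twin pair is decomposed into additive
genetic (A), shared environmental (C) and unique environmental (E)
components.  Across the two members of a pair the genetic component is
correlated gamma_A (1 for monozygotic, 0.5 for dizygotic twins) and the
shared environment is fully correlated in both zygosity groups
(equal-environments assumption).

Everything here is parameterised through path coefficients, i.e. through
loading matrices whose outer products form A, C and E, so the components
are positive semidefinite by construction and unconstrained optimisation
can be used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidityError

# kinship constants of the twin design
GAMMA_A = {"MZ": 1.0, "DZ": 0.5}
GAMMA_C = {"MZ": 1.0, "DZ": 1.0}

_COMPONENTS = {"ACE": ("A", "C", "E"), "AE": ("A", "E"), "CE": ("C", "E"), "E": ("E",)}


def components_for(model_kind: str) -> tuple[str, ...]:
    try:
        return _COMPONENTS[model_kind]
    except KeyError:
        raise ValueError(f"unknown model kind {model_kind!r}; expected one of {sorted(_COMPONENTS)}")


@dataclass
class ACEStructure:
    """Component covariance matrices of an ACE-family model (each p x p)."""

    A: np.ndarray
    C: np.ndarray
    E: np.ndarray

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.E = np.atleast_2d(np.asarray(self.E, dtype=float))
        if not (self.A.shape == self.C.shape == self.E.shape) or self.A.shape[0] != self.A.shape[1]:
            raise ValidityError("A, C and E must be square matrices of equal dimension")

    @property
    def p(self) -> int:
        return self.A.shape[0]

    @property
    def total(self) -> np.ndarray:
        """Phenotypic covariance Sigma = A + C + E."""
        return self.A + self.C + self.E

    def validate_psd(self, atol: float = 1e-8) -> None:
        for name in ("A", "C", "E"):
            m = getattr(self, name)
            if not np.allclose(m, m.T, atol=1e-8):
                raise ValidityError(f"component {name} is not symmetric")
            if np.linalg.eigvalsh(m).min() < -atol * max(1.0, np.trace(m)):
                raise ValidityError(f"component {name} is not positive semidefinite")


@dataclass
class UnivariateStructure(ACEStructure):
    """Univariate ACE structure with scalar path coefficients a, c, e."""

    a: float = 0.0
    c: float = 0.0
    e: float = 0.0

    @classmethod
    def from_paths(cls, a: float, c: float, e: float) -> "UnivariateStructure":
        return cls(A=[[a * a]], C=[[c * c]], E=[[e * e]], a=abs(a), c=abs(c), e=abs(e))

    @classmethod
    def from_variances(cls, va: float, vc: float, ve: float) -> "UnivariateStructure":
        if min(va, vc, ve) < 0:
            raise ValidityError("variance components must be nonnegative")
        return cls.from_paths(np.sqrt(va), np.sqrt(vc), np.sqrt(ve))


@dataclass
class CholeskyStructure(ACEStructure):
    """Saturated (triangular-decomposition) multivariate ACE structure.

    A = L_A L_A', C = L_C L_C', E = L_E L_E' with lower-triangular loading
    matrices; diagonals are nonnegative by sign convention.
    """

    L_A: np.ndarray = None
    L_C: np.ndarray = None
    L_E: np.ndarray = None

    @classmethod
    def from_loadings(cls, L_A, L_C, L_E) -> "CholeskyStructure":
        mats = []
        for L in (L_A, L_C, L_E):
            L = np.atleast_2d(np.asarray(L, dtype=float))
            mats.append(_fix_column_signs(L))
        L_A, L_C, L_E = mats
        return cls(A=L_A @ L_A.T, C=L_C @ L_C.T, E=L_E @ L_E.T, L_A=L_A, L_C=L_C, L_E=L_E)


@dataclass
class PathwayStructure(ACEStructure):
    """Independent-pathway structure: common factors plus trait-specific paths.

    A = Lambda_A Lambda_A' + diag(d_A^2), and analogously for C and E.
    """

    lambda_a: np.ndarray = None  # p x k_A
    lambda_c: np.ndarray = None
    lambda_e: np.ndarray = None
    d_a: np.ndarray = None  # length-p specific paths
    d_c: np.ndarray = None
    d_e: np.ndarray = None

    @classmethod
    def from_paths(cls, p, lambda_a=None, lambda_c=None, lambda_e=None,
                   d_a=None, d_c=None, d_e=None) -> "PathwayStructure":
        def lam(x):
            if x is None:
                return np.zeros((p, 0))
            x = np.asarray(x, dtype=float)
            if x.ndim == 1:
                x = x[:, None]
            return _fix_leading_signs(x)

        def spec(x):
            return np.zeros(p) if x is None else np.abs(np.asarray(x, dtype=float))

        la, lc, le = lam(lambda_a), lam(lambda_c), lam(lambda_e)
        da, dc, de = spec(d_a), spec(d_c), spec(d_e)
        return cls(
            A=la @ la.T + np.diag(da ** 2),
            C=lc @ lc.T + np.diag(dc ** 2),
            E=le @ le.T + np.diag(de ** 2),
            lambda_a=la, lambda_c=lc, lambda_e=le, d_a=da, d_c=dc, d_e=de,
        )


def _fix_column_signs(L: np.ndarray) -> np.ndarray:
    """Flip column signs so diagonal entries are nonnegative (L L' unchanged)."""
    L = L.copy()
    for j in range(min(L.shape)):
        if L[j, j] < 0:
            L[:, j] = -L[:, j]
    return L


def _fix_leading_signs(L: np.ndarray) -> np.ndarray:
    """Flip factor signs so the first nonzero loading of each column is positive."""
    L = L.copy()
    for j in range(L.shape[1]):
        col = L[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            L[:, j] = -col
    return L


def rescale_structure(structure: ACEStructure, scale: np.ndarray) -> ACEStructure:
    """Map a structure fitted on standardized traits back to raw units.

    ``scale`` holds each trait's standard deviation; loadings scale
    linearly, component covariances quadratically.
    """
    d = np.asarray(scale, dtype=float)
    D = np.diag(d)
    if isinstance(structure, UnivariateStructure):
        return UnivariateStructure.from_paths(
            structure.a * d[0], structure.c * d[0], structure.e * d[0])
    if isinstance(structure, CholeskyStructure):
        return CholeskyStructure.from_loadings(
            D @ structure.L_A, D @ structure.L_C, D @ structure.L_E)
    if isinstance(structure, PathwayStructure):
        return PathwayStructure.from_paths(
            structure.p,
            lambda_a=D @ structure.lambda_a, lambda_c=D @ structure.lambda_c,
            lambda_e=D @ structure.lambda_e,
            d_a=d * structure.d_a, d_c=d * structure.d_c, d_e=d * structure.d_e)
    return ACEStructure(D @ structure.A @ D, D @ structure.C @ D,
                        D @ structure.E @ D)


def model_covariance(structure: ACEStructure, zygosity: str) -> np.ndarray:
    """Model-implied 2p x 2p covariance of a twin pair's stacked phenotypes.

    The diagonal blocks are A + C + E; the cross-twin block is
    gamma_A * A + gamma_C * C with gamma_A = 1 (MZ) or 0.5 (DZ) and
    gamma_C = 1 for both zygosities.
    """
    ga, gc = GAMMA_A[zygosity], GAMMA_C[zygosity]
    within = structure.total
    cross = ga * structure.A + gc * structure.C
    return np.block([[within, cross], [cross, within]])


# ---------------------------------------------------------------------------
# Parameterizations: map a free real vector theta to (A, C, E)
# ---------------------------------------------------------------------------

def _tril_indices_masked(p: int, zeros: frozenset) -> list[tuple[int, int]]:
    return [(i, j) for i in range(p) for j in range(i + 1) if (i, j) not in zeros]


@dataclass
class CholeskyParam:
    """Free lower-triangular loadings per included component.

    ``zero_paths`` forces individual loading entries to zero, e.g.
    ``{"A": [(1, 0)]}`` removes the genetic cross path in a bivariate
    model (the constraint behind the r_G = 0 test).
    """

    p: int
    model_kind: str = "ACE"
    zero_paths: dict = field(default_factory=dict)

    def __post_init__(self):
        self.components = components_for(self.model_kind)
        self._idx = {}
        for comp in self.components:
            zeros = frozenset(tuple(z) for z in self.zero_paths.get(comp, ()))
            self._idx[comp] = _tril_indices_masked(self.p, zeros)
        self.n_theta = sum(len(v) for v in self._idx.values())

    def _loadings(self, theta):
        out = {}
        pos = 0
        for comp in self.components:
            idx = self._idx[comp]
            L = np.zeros((self.p, self.p))
            for (i, j), v in zip(idx, theta[pos:pos + len(idx)]):
                L[i, j] = v
            out[comp] = L
            pos += len(idx)
        return out

    def build(self, theta):
        Ls = self._loadings(theta)
        zero = np.zeros((self.p, self.p))
        mats = {c: (L @ L.T) for c, L in Ls.items()}
        return mats.get("A", zero), mats.get("C", zero), mats.get("E", zero)

    def to_structure(self, theta):
        Ls = self._loadings(theta)
        zero = np.zeros((self.p, self.p))
        if self.p == 1:
            a = abs(Ls.get("A", zero)[0, 0])
            c = abs(Ls.get("C", zero)[0, 0])
            e = abs(Ls.get("E", zero)[0, 0])
            return UnivariateStructure.from_paths(a, c, e)
        return CholeskyStructure.from_loadings(
            Ls.get("A", zero), Ls.get("C", zero), Ls.get("E", zero))

    def start_points(self, moments, rng, n_starts=5):
        """Moment-based start plus seeded perturbations of it."""
        base = []
        for comp in self.components:
            L = _psd_cholesky(moments[comp], self.p)
            base.extend(L[i, j] for (i, j) in self._idx[comp])
        base = np.asarray(base)
        scale = max(np.abs(base).max(), 1e-3)
        starts = [base]
        for _ in range(n_starts - 1):
            starts.append(base * (1 + 0.3 * rng.standard_normal(base.size))
                          + 0.1 * scale * rng.standard_normal(base.size))
        return starts


def _psd_cholesky(M: np.ndarray, p: int) -> np.ndarray:
    """Cholesky factor of the PSD projection of M, jittered to full rank."""
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    floor = 1e-4 * max(w.max(), 1e-8)
    w = np.clip(w, floor, None)
    return np.linalg.cholesky((V * w) @ V.T + 1e-10 * np.eye(p))


@dataclass
class PathwayParam:
    """Independent-pathway parameterization with optional constraint tying.

    * ``k_a`` / ``k_c`` / ``k_e``: numbers of common factors per component
      (echelon zeros Lambda[i, j] = 0 for j > i identify the rotation).
    * ``specific_*``: include trait-specific paths for that component.
    * ``tie_common``: all loadings within each common factor share one
      parameter (the bilateral identification constraint for p = 2).
    * ``tie_specifics``: left/right specific paths share one parameter per
      component (the lateral-symmetry equality constraint).
    """

    p: int
    model_kind: str = "ACE"
    k_a: int = 1
    k_c: int = 1
    k_e: int = 1
    specific_a: bool = True
    specific_c: bool = True
    specific_e: bool = True
    tie_common: bool = False
    tie_specifics: bool = False

    def __post_init__(self):
        self.components = components_for(self.model_kind)
        self._layout = []  # (component, kind, shape info)
        for comp in self.components:
            k = {"A": self.k_a, "C": self.k_c, "E": self.k_e}[comp]
            if k > 0:
                if self.tie_common:
                    n = k
                else:
                    n = self.p * k - k * (k - 1) // 2
                    if self.p <= k:
                        raise ValueError(
                            f"{k} common factors are not identified with p={self.p}")
                self._layout.append((comp, "common", k, n))
            if {"A": self.specific_a, "C": self.specific_c, "E": self.specific_e}[comp]:
                n = 1 if self.tie_specifics else self.p
                self._layout.append((comp, "specific", 0, n))
        self.n_theta = sum(n for *_, n in self._layout)

    def _paths(self, theta):
        lam = {c: np.zeros((self.p, 0)) for c in "ACE"}
        d = {c: np.zeros(self.p) for c in "ACE"}
        pos = 0
        for comp, kind, k, n in self._layout:
            block = np.asarray(theta[pos:pos + n], dtype=float)
            pos += n
            if kind == "common":
                if self.tie_common:
                    L = np.repeat(block[None, :], self.p, axis=0)
                else:
                    L = np.zeros((self.p, k))
                    m = 0
                    for j in range(k):
                        rows = range(j, self.p)  # echelon: zeros above row j
                        L[j:, j] = block[m:m + self.p - j]
                        m += self.p - j
                lam[comp] = L
            else:
                d[comp] = np.full(self.p, block[0]) if self.tie_specifics else block
        return lam, d

    def build(self, theta):
        lam, d = self._paths(theta)
        out = []
        for comp in "ACE":
            out.append(lam[comp] @ lam[comp].T + np.diag(d[comp] ** 2))
        return tuple(out)

    def to_structure(self, theta):
        lam, d = self._paths(theta)
        return PathwayStructure.from_paths(
            self.p, lambda_a=lam["A"], lambda_c=lam["C"], lambda_e=lam["E"],
            d_a=d["A"], d_c=d["C"], d_e=d["E"])

    def start_points(self, moments, rng, n_starts=5):
        base = []
        for comp, kind, k, n in self._layout:
            M = 0.5 * (moments[comp] + moments[comp].T)
            w, V = np.linalg.eigh(M)
            w = np.clip(w, 1e-6 * max(abs(w).max(), 1e-8), None)
            tr = max(float(np.trace(M)), 1e-8)
            if kind == "common":
                if self.tie_common:
                    off = (np.mean(M[np.triu_indices(self.p, 1)]) if self.p > 1
                           else M[0, 0])
                    base.extend([np.sqrt(max(off, 0.05 * tr / self.p))] * k)
                else:
                    # top-k eigenpairs rotated into echelon form
                    L = V[:, ::-1][:, :k] * np.sqrt(w[::-1][:k])
                    if k > 1:
                        Q, _ = np.linalg.qr(L[:k, :].T)
                        L = L @ Q
                    m = 0
                    vals = np.zeros(n)
                    for j in range(k):
                        vals[m:m + self.p - j] = L[j:, j]
                        m += self.p - j
                    base.extend(vals)
            else:
                resid = np.clip(np.diag(M) * 0.4, 1e-4 * tr / self.p, None)
                v = np.sqrt(resid)
                base.append(np.mean(v)) if self.tie_specifics else base.extend(v)
        base = np.asarray(base, dtype=float)
        scale = max(np.abs(base).max(), 1e-3)
        starts = [base]
        for _ in range(n_starts - 1):
            starts.append(base * (1 + 0.3 * rng.standard_normal(base.size))
                          + 0.1 * scale * rng.standard_normal(base.size))
        return starts
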