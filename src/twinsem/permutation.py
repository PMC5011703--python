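"""Zygosity-group comparisons with pair-preserving permutation p-values.

t and chi-square statistics computed on individuals are not valid at
face value in twin data because the two members of a pair are
dependent; the permutation null therefore relabels whole pairs
(zygosity labels are shuffled over pairs, keeping the MZ/DZ pair counts
fixed), so twins are never split across groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, SchemaError
from .io import PhenotypeTable


@dataclass
class PermutationResult:
    observed: float
    p_value: float
    n_permutations: int
    kind: str
    variable: str
    seed: int


def _t_statistic(values, group):
    """Equal-variance two-sample t on individuals; |t| is the test statistic."""
    x, y = values[group], values[~group]
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    if sp2 <= 0:
        raise DegenerateDataError("pooled variance is zero; variable is constant")
    return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))


def _chi2_statistic(onehot, group):
    """Pearson chi-square of the group x category contingency table."""
    n = onehot.shape[0]
    obs = np.vstack([onehot[group].sum(axis=0), onehot[~group].sum(axis=0)])
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / n
    if (exp == 0).any():
        raise DegenerateDataError("empty contingency cell; category never observed")
    return float(((obs - exp) ** 2 / exp).sum())


def perm_test(table: PhenotypeTable, variable: str, kind: str = "t",
              B: int = 10000, seed: int = 0) -> PermutationResult:
    """Permutation test of an MZ/DZ difference in ``variable``.

    ``kind='t'`` treats the variable as continuous (two-sided via |t|);
    ``kind='chi2'`` as categorical.  The null distribution permutes
    zygosity labels over pairs; the p-value carries the add-one
    finite-sample correction (B+1 in the denominator) and so can never
    be zero.
    """
    df = table.data
    if variable not in df.columns:
        raise SchemaError(f"variable {variable!r} not in table")
    d = df.sort_values(["family_id", "twin_index"]).reset_index(drop=True)
    fam_zyg = d.groupby("family_id", sort=True)["zygosity"].first()
    n_pairs = len(fam_zyg)
    n_mz_pairs = int((fam_zyg == "MZ").sum())
    if n_mz_pairs in (0, n_pairs):
        raise DegenerateDataError("both zygosity groups must be non-empty")
    values = d[variable].to_numpy()
    pair_values = values.reshape(n_pairs, 2)  # rows follow sorted family order

    rng = np.random.default_rng(seed)
    if kind == "t":
        pv = pair_values.astype(float)
        if np.isnan(pv).any():
            raise SchemaError(f"variable {variable!r} has missing values")

        def stat(pair_is_mz):
            return abs(_t_statistic(pv.ravel(), np.repeat(pair_is_mz, 2)))
    elif kind == "chi2":
        cats = np.unique(values)
        if len(cats) < 2:
            raise DegenerateDataError(f"variable {variable!r} is constant")
        onehot = (values[:, None] == cats[None, :]).astype(float)

        def stat(pair_is_mz):
            return _chi2_statistic(onehot, np.repeat(pair_is_mz, 2))
    else:
        raise ValueError("kind must be 't' or 'chi2'")

    observed_mask = (fam_zyg == "MZ").to_numpy()
    observed = stat(observed_mask)
    count = 0
    base = np.zeros(n_pairs, dtype=bool)
    base[:n_mz_pairs] = True
    for _ in range(B):
        perm = rng.permutation(base)
        if stat(perm) >= observed - 1e-12:
            count += 1
    p = (count + 1) / (B + 1)
    return PermutationResult(observed=float(observed), p_value=float(p),
                             n_permutations=B, kind=kind, variable=variable,
                             seed=seed)
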