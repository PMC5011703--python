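import numpy as np
import pandas as pd
import pytest

from twinsem.io import CovariateSpec, PhenotypeTable, TwinPair, assemble_pairs
from twinsem.simulate import GenerativeSpec, simulate_cohort
from twinsem.structures import UnivariateStructure


def small_table_df(n_families: int = 3, seed: int = 0) -> pd.DataFrame:
    """Hand-sized valid table: one phenotype plus the full covariate set."""
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(n_families):
        zyg = "MZ" if f % 2 == 0 else "DZ"
        age = rng.uniform(65, 85)
        scanner = int(rng.integers(1, 5))
        for tw in (1, 2):
            rows.append({
                "family_id": f"fam{f}", "twin_index": tw, "zygosity": zyg,
                "hip_vol": rng.normal(4000, 300), "age": age,
                "sex": int(rng.random() > 0.67), "scanner": scanner,
                "icv": rng.normal(1.45e6, 1e5),
            })
    return pd.DataFrame(rows)


@pytest.fixture
def small_table() -> PhenotypeTable:
    return PhenotypeTable(small_table_df(), ["hip_vol"], CovariateSpec())


def make_pairs(va, vc, ve, n_mz, n_dz, seed):
    """Univariate cohort without covariates, returned as TwinPair list."""
    spec = GenerativeSpec(n_mz=n_mz, n_dz=n_dz,
                          structure=UnivariateStructure.from_variances(va, vc, ve),
                          include_covariates=False)
    table = simulate_cohort(spec, seed=seed)
    pairs, _ = assemble_pairs(table)
    return pairs


@pytest.fixture
def standard_cohort():
    """161-pair cohort at moderate heritability, the workhorse fixture."""
    return make_pairs(0.6, 0.1, 0.3, 93, 68, seed=42)


def pairs_from_arrays(y1, y2, zygosities, x1=None, x2=None):
    """Assemble TwinPairs directly from arrays (bypasses table round-trips)."""
    y1, y2 = np.atleast_2d(np.asarray(y1).T).T, np.atleast_2d(np.asarray(y2).T).T
    if y1.ndim == 1:
        y1, y2 = y1[:, None], y2[:, None]
    n = y1.shape[0]
    out = []
    for i in range(n):
        out.append(TwinPair(
            family_id=f"fam{i}", zygosity=zygosities[i],
            y1=np.atleast_1d(y1[i]), y2=np.atleast_1d(y2[i]),
            x1=np.atleast_1d(x1[i]) if x1 is not None else np.array([1.0]),
            x2=np.atleast_1d(x2[i]) if x2 is not None else np.array([1.0])))
    return out
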