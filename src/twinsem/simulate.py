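"""Synthetic MZ/DZ twin cohorts drawn from a specified ACE structure.

The generator inverts the twin model: for each pair it draws additive
genetic deviates with cross-twin correlation 1 (MZ) or 0.5 (DZ), a
shared environmental deviate common to both twins, and independent
unique-environment deviates, then adds the mean model
``y_i = M + B x_i + g_i + c + e_i``.

Default covariate laws emulate an older-adult multi-site twin cohort of
93 MZ and 68 DZ pairs: age uniform on 65-85 years (shared within pair),
sex 1 = male with P(female) = 0.668 (shared for MZ, independent per twin
for DZ, which yields opposite-sex DZ pairs), four scanners with
probabilities (80, 36, 114, 92)/322 shared within pair, and ICV drawn
as an independent normal covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConvergenceError, ValidityError
from .io import CovariateSpec, PhenotypeTable
from .structures import ACEStructure

DEFAULT_COVARIATE_LAW = {
    "age_range": (65.0, 85.0),
    "p_female": 0.668,
    "scanner_probs": (80 / 322, 36 / 322, 114 / 322, 92 / 322),
    "icv_mean": 1.45e6,   # mm^3
    "icv_sd": 1.5e5,
}


@dataclass
class GenerativeSpec:
    """Full description of a synthetic twin cohort.

    ``beta`` is the p x q matrix of covariate effects on the phenotype
    means (q = 4 for age, sex, scanner-dummy-free coding below, icv);
    covariate effects default to zero so that phenotypes reduce to the
    pure variance-component draw around ``intercept``.
    """

    n_mz: int
    n_dz: int
    structure: ACEStructure
    phenotype_names: Optional[list] = None
    intercept: np.ndarray = None
    beta: np.ndarray = None            # p x 4 effects of (age, sex, scanner dummies..., icv)
    covariate_law: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_LAW))
    include_covariates: bool = True

    def __post_init__(self):
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValidityError("pair counts must be nonnegative")
        p = self.structure.p
        if self.phenotype_names is None:
            self.phenotype_names = [f"pheno_{i + 1}" for i in range(p)]
        if len(self.phenotype_names) != p:
            raise ValidityError("phenotype_names length does not match structure dimension")
        self.intercept = (np.zeros(p) if self.intercept is None
                          else np.asarray(self.intercept, dtype=float))
        self.structure.validate_psd()


def _psd_sqrt(M: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (M + M.T))
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w) @ V.T


def simulate_cohort(spec: GenerativeSpec, seed: int = 0) -> PhenotypeTable:
    """Draw a cohort table; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    p = spec.structure.p
    half_a = _psd_sqrt(0.5 * spec.structure.A)
    sqrt_a = _psd_sqrt(spec.structure.A)
    sqrt_c = _psd_sqrt(spec.structure.C)
    sqrt_e = _psd_sqrt(spec.structure.E)
    law = {**DEFAULT_COVARIATE_LAW, **spec.covariate_law}

    rows = []
    counts = [("MZ", spec.n_mz), ("DZ", spec.n_dz)]
    fam = 0
    for zyg, n in counts:
        for _ in range(n):
            fam += 1
            if zyg == "MZ":
                g = sqrt_a @ rng.standard_normal(p)
                g1 = g2 = g
            else:
                shared = half_a @ rng.standard_normal(p)
                g1 = shared + half_a @ rng.standard_normal(p)
                g2 = shared + half_a @ rng.standard_normal(p)
            c = sqrt_c @ rng.standard_normal(p)
            e1 = sqrt_e @ rng.standard_normal(p)
            e2 = sqrt_e @ rng.standard_normal(p)

            age = rng.uniform(*law["age_range"])
            scanner = int(rng.choice(4, p=law["scanner_probs"])) + 1
            if zyg == "MZ":
                sex1 = sex2 = int(rng.random() > law["p_female"])
            else:
                sex1 = int(rng.random() > law["p_female"])
                sex2 = int(rng.random() > law["p_female"])
            icv1 = rng.normal(law["icv_mean"], law["icv_sd"])
            icv2 = rng.normal(law["icv_mean"], law["icv_sd"])

            for tw, (g_i, e_i, sex, icv) in enumerate(
                    [(g1, e1, sex1, icv1), (g2, e2, sex2, icv2)], start=1):
                y = spec.intercept + g_i + c + e_i
                if spec.beta is not None:
                    x = np.array([age, sex, float(scanner), icv])
                    y = y + np.asarray(spec.beta, dtype=float) @ x
                row = {"family_id": f"fam{fam:04d}", "twin_index": tw, "zygosity": zyg}
                row.update({name: y[i] for i, name in enumerate(spec.phenotype_names)})
                if spec.include_covariates:
                    row.update({"age": age, "sex": sex, "scanner": scanner, "icv": icv})
                rows.append(row)
    df = pd.DataFrame(rows)
    cov = CovariateSpec() if spec.include_covariates else CovariateSpec.none()
    return PhenotypeTable(df, list(spec.phenotype_names), cov)


def simulate_from_fit(fit, n_mz: int, n_dz: int, seed: int = 0,
                      phenotype_names=None) -> PhenotypeTable:
    """Parametric-bootstrap cohort drawn from a converged fit's structure.

    Covariate effects are not replayed (the bootstrap draws around the
    fitted variance components with a zero mean), which is what the
    resampling of heritability estimates needs.
    """
    if not fit.converged:
        raise ConvergenceError("refusing to simulate from a non-converged fit")
    spec = GenerativeSpec(
        n_mz=n_mz, n_dz=n_dz, structure=fit.structure,
        phenotype_names=phenotype_names, include_covariates=False)
    return simulate_cohort(spec, seed=seed)
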