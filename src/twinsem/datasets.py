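"""Reference tables from a published older-adult twin cohort (93 MZ, 68 DZ
pairs; grey-matter volumes of four cortical lobes, seven subcortical
structures and intracranial volume, adjusted for age, sex, scanner and ICV).

These printed estimates serve as worked-example inputs and as generating
truths for simulation studies; they are not outputs of this package.
Region codes: ACC nucleus accumbens, AMY amygdala, HIP hippocampus, THA
thalamus, CAU caudate, PAL pallidum, PUT putamen, TEMP temporal lobe,
PARI parietal lobe, FRON frontal lobe, OCCI occipital lobe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REGION_LABELS = ["ACC", "AMY", "HIP", "THA", "CAU", "PAL", "PUT",
                 "TEMP", "PARI", "FRON", "OCCI"]

N_MZ_PAIRS = 93
N_DZ_PAIRS = 68

# genetic correlations (upper triangle of the published matrix), row-major
_GENETIC_UPPER = [
    [0.11, 0.21, 0.10, -0.02, 0.00, 0.00, 0.07, 0.06, 0.03, 0.04],  # ACC
    [0.54, 0.26, -0.04, 0.01, 0.00, 0.19, 0.15, 0.07, 0.10],        # AMY
    [0.49, -0.08, 0.01, 0.00, 0.36, 0.28, 0.14, 0.18],              # HIP
    [-0.04, 0.01, 0.00, 0.17, 0.14, 0.07, 0.09],                    # THA
    [0.35, 0.44, 0.03, -0.02, -0.01, -0.01],                        # CAU
    [0.54, 0.00, 0.00, 0.00, 0.00],                                 # PAL
    [0.00, 0.00, 0.00, 0.00],                                       # PUT
    [0.75, 0.53, 0.40],                                             # TEMP
    [0.51, 0.38],                                                   # PARI
    [0.27],                                                         # FRON
]

# environmental correlations (lower triangle of the same table)
_ENVIRONMENTAL_LOWER = [
    [0.41],                                                          # AMY
    [0.38, 0.46],                                                    # HIP
    [0.24, 0.29, 0.27],                                              # THA
    [0.12, 0.15, 0.14, 0.09],                                        # CAU
    [0.16, 0.19, 0.18, 0.12, 0.36],                                  # PAL
    [0.33, 0.39, 0.36, 0.24, 0.40, 0.36],                            # PUT
    [0.40, 0.49, 0.45, 0.29, 0.15, 0.19, 0.39],                      # TEMP
    [0.35, 0.42, 0.39, 0.25, 0.12, 0.16, 0.33, 0.56],                # PARI
    [0.23, 0.28, 0.26, 0.16, 0.08, 0.11, 0.22, 0.45, 0.59],          # FRON
    [0.21, 0.26, 0.24, 0.15, 0.08, 0.10, 0.21, 0.39, 0.50, 0.48],    # OCCI
]


def _symmetric_from_triangles(upper, lower=None) -> np.ndarray:
    n = len(REGION_LABELS)
    M = np.eye(n)
    for i, row in enumerate(upper):
        for off, v in enumerate(row):
            M[i, i + 1 + off] = M[i + 1 + off, i] = v
    if lower is not None:
        M2 = np.eye(n)
        for i, row in enumerate(lower):
            for j, v in enumerate(row):
                M2[i + 1, j] = M2[j, i + 1] = v
        return M2
    return M


def genetic_correlation_matrix() -> pd.DataFrame:
    """Published genetic correlations among the eleven regions."""
    return pd.DataFrame(_symmetric_from_triangles(_GENETIC_UPPER),
                        index=REGION_LABELS, columns=REGION_LABELS)


def environmental_correlation_matrix() -> pd.DataFrame:
    """Published environmental correlations among the eleven regions."""
    return pd.DataFrame(_symmetric_from_triangles(_GENETIC_UPPER, _ENVIRONMENTAL_LOWER),
                        index=REGION_LABELS, columns=REGION_LABELS)


# univariate ACE results per region: twin ICCs and variance shares
_UNIVARIATE_ROWS = [
    # region, icc_mz, icc_dz, h2, c2, e2
    ("frontal", 0.79, 0.40, 0.78, 0.01, 0.21),
    ("temporal", 0.75, 0.46, 0.58, 0.17, 0.25),
    ("parietal", 0.70, 0.42, 0.55, 0.15, 0.30),
    ("occipital", 0.70, 0.35, 0.70, 0.00, 0.30),
    ("accumbens", 0.65, 0.44, 0.42, 0.24, 0.35),
    ("amygdala", 0.61, 0.41, 0.41, 0.21, 0.39),
    ("caudate", 0.86, 0.52, 0.67, 0.19, 0.14),
    ("hippocampus", 0.73, 0.37, 0.73, 0.00, 0.27),
    ("pallidum", 0.49, 0.24, 0.49, 0.00, 0.51),
    ("putamen", 0.68, 0.34, 0.68, 0.00, 0.32),
    ("thalamus", 0.50, 0.25, 0.51, 0.00, 0.50),
    ("icv", 0.88, 0.48, 0.79, 0.09, 0.12),
]


def univariate_reference_estimates() -> pd.DataFrame:
    """Published univariate ACE estimates: twin-pair ICCs and variance shares."""
    return pd.DataFrame(_UNIVARIATE_ROWS,
                        columns=["region", "icc_mz", "icc_dz", "h2", "c2", "e2"]
                        ).set_index("region")


def generating_shares(region: str) -> tuple[float, float, float]:
    """(h2, c2, e2) for one region, normalised to sum exactly to one.

    Printed rows can sum to 0.99-1.01 from rounding; simulation truths
    need exact shares.
    """
    row = univariate_reference_estimates().loc[region]
    s = row["h2"] + row["c2"] + row["e2"]
    return (row["h2"] / s, row["c2"] / s, row["e2"] / s)
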