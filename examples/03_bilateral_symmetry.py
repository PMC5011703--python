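"""Test bilateral genetic symmetry of a left/right structure pair.

Simulates left and right volumes sharing one common genetic factor with
no hemisphere-specific genetic variance, fits the bilateral
independent-pathway AE model, and runs the r_G = 1 (perfect symmetry),
r_G = 0 (no shared genetics) and path-equality likelihood-ratio tests.
"""

from twinsem import (GenerativeSpec, PathwayStructure, assemble_pairs,
                     simulate_cohort, test_bilateral_symmetry)

structure = PathwayStructure.from_paths(
    2,
    lambda_a=[0.8, 0.8],   # common genetic factor, equal loadings
    d_a=[0.0, 0.0],        # no hemisphere-specific genetic paths
    lambda_e=[0.3, 0.3],
    d_e=[0.5, 0.5],
)
spec = GenerativeSpec(n_mz=93, n_dz=68, structure=structure,
                      phenotype_names=["left_thalamus", "right_thalamus"],
                      include_covariates=False)
pairs, _ = assemble_pairs(simulate_cohort(spec, seed=21))

res = test_bilateral_symmetry(pairs, "AE")
print(f"bilateral r_G = {res.rg.value:.3f}")
print(f"r_G = 1 test:  stat {res.lrt_rg_one.statistic:6.3f}, df {res.lrt_rg_one.df},"
      f" p = {res.lrt_rg_one.p_value:.3f}")
print(f"r_G = 0 test:  stat {res.lrt_rg_zero.statistic:6.3f}, df {res.lrt_rg_zero.df},"
      f" p = {res.lrt_rg_zero.p_value:.2e}")
print(f"equal paths:   stat {res.lrt_equal_paths.statistic:6.3f},"
      f" df {res.lrt_equal_paths.df}, p = {res.lrt_equal_paths.p_value:.3f}")
print("\nA retained r_G = 1 test (p > 0.05) means the data are compatible "
      "with identical genetic determinants in both hemispheres; the "
      "rejected r_G = 0 test confirms the shared genetic factor is real.")
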