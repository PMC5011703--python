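"""End-to-end analysis pipeline over a twin phenotype table.

Stages mirror a full twin-cohort volumetric study: demographic
permutation tests, optional summation of regional volumes into lobar
phenotypes, the univariate ACE/AE/CE/E ladder per phenotype, bilateral
independent-pathway tests per paired structure, the pairwise genetic
correlation matrix from bivariate Cholesky fits, an eigenvalue screen,
a k-factor independent-pathway model with genetic variance proportions,
and hierarchical clustering of the genetic and phenotypic correlation
matrices.  Outputs are a pure function of (table, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cholesky, clustering, pathway, permutation, univariate
from .errors import SchemaError, TwinSemError
from .io import CovariateSpec, PhenotypeTable, assemble_pairs
from .univariate import lrt

log = logging.getLogger("twinsem.pipeline")


@dataclass
class AnalysisConfig:
    """Declarative description of one pipeline run."""

    phenotypes: list
    roi_groups: dict = dc_field(default_factory=dict)    # new column -> columns to sum
    bilateral: dict = dc_field(default_factory=dict)     # name -> [left, right]
    covariates: Optional[CovariateSpec] = None
    demographic_vars: dict = dc_field(default_factory=lambda: {"age": "t", "sex": "chi2"})
    factors: int = 3
    shared_c: str = "single"
    linkage: str = "complete"
    permutation_B: int = 1000
    seed: int = 0
    with_ci: bool = False
    fdr: bool = False
    fit_saturated: bool = True

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        cov = cfg.pop("covariates", None)
        spec = None
        if cov is not None:
            spec = CovariateSpec(age=cov.get("age"), sex=cov.get("sex"),
                                 scanner=cov.get("scanner"), icv=cov.get("icv"),
                                 scanner_reference=cov.get("scanner_reference"))
        return cls(covariates=spec, **cfg)

    def validate(self, df: pd.DataFrame) -> None:
        needed = list(self.phenotypes)
        for name, members in self.roi_groups.items():
            if len(set(members)) != len(members):
                raise SchemaError(f"roi group {name!r} lists a column twice")
            needed += list(members)
        for name, lr in self.bilateral.items():
            if len(lr) != 2:
                raise SchemaError(f"bilateral entry {name!r} must list [left, right]")
            needed += list(lr)
        base = [c for c in needed if c not in self.roi_groups]
        missing = sorted(set(c for c in base if c not in df.columns))
        if missing:
            raise SchemaError(f"config references missing columns: {missing}")


class StageError(TwinSemError):
    def __init__(self, stage, original):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _aggregate(table: PhenotypeTable, config: AnalysisConfig) -> PhenotypeTable:
    df = table.data.copy()
    for name, members in config.roi_groups.items():
        df[name] = df[list(members)].sum(axis=1)
    names = sorted(set(table.phenotype_names) | set(config.phenotypes))
    return PhenotypeTable(df, names, table.covariates)


def _univariate_stage(table, config, report):
    rows = {}
    for ph in config.phenotypes:
        pairs, _ = assemble_pairs(table, [ph])
        ladder = univariate.fit_model_ladder(pairs, seed=config.seed)
        ace = ladder["ACE"]
        dec = univariate.variance_decomposition(ace, with_ci=config.with_ci)
        tests = {k: vars(lrt(ace, ladder[k])) for k in ("AE", "CE", "E")}
        iccs = {}
        for zyg in ("MZ", "DZ"):
            sub = [p for p in pairs if p.zygosity == zyg]
            r = univariate.icc(sub)
            iccs[zyg] = {"estimate": r.estimate, "ci": r.ci}
        rows[ph] = {
            "decomposition": dec.as_dict(),
            "aic": {k: f.aic for k, f in ladder.items()},
            "loglik": {k: f.loglik for k, f in ladder.items()},
            "lrt_vs_ace": tests,
            "icc": iccs,
            "best_by_aic": min(ladder, key=lambda k: ladder[k].aic),
        }
    report["univariate"] = rows


def run_pipeline(table: PhenotypeTable, config: AnalysisConfig,
                 outdir=None) -> dict:
    """Run every configured stage; halts with a stage-tagged error on failure.

    When ``outdir`` is given, JSON/TSV/newick artefacts are written as
    stages complete, so partial output survives a late failure.
    """
    report: dict = {"config": {"seed": config.seed, "phenotypes": config.phenotypes}}
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def checkpoint(name, obj):
        if outdir is not None:
            with open(outdir / f"{name}.json", "w") as fh:
                json.dump(obj, fh, indent=2, default=_jsonable)

    stage = "validate-config"
    try:
        config.validate(table.data)
        stage = "demographics"
        log.info("stage %s (seed %d)", stage, config.seed)
        demo = {}
        for var, kind in config.demographic_vars.items():
            if var in table.data.columns:
                demo[var] = vars(permutation.perm_test(
                    table, var, kind=kind, B=config.permutation_B, seed=config.seed))
        report["demographics"] = demo
        checkpoint("demographics", demo)

        stage = "aggregate"
        table = _aggregate(table, config)

        stage = "univariate-ladder"
        log.info("stage %s: %d phenotypes", stage, len(config.phenotypes))
        _univariate_stage(table, config, report)
        checkpoint("univariate", report["univariate"])

        stage = "bilateral-ipm"
        bil = {}
        for name, (left, right) in config.bilateral.items():
            pairs, _ = assemble_pairs(table, [left, right])
            res = pathway.test_bilateral_symmetry(pairs, "AE", seed=config.seed)
            bil[name] = {"rg": res.rg.value,
                         "p_rg_one": res.lrt_rg_one.p_value,
                         "p_rg_zero": res.lrt_rg_zero.p_value,
                         "p_equal_paths": res.lrt_equal_paths.p_value}
        report["bilateral"] = bil
        checkpoint("bilateral", bil)

        stage = "pairwise-cholesky"
        phen = list(config.phenotypes)
        p = len(phen)
        rg = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                pairs, _ = assemble_pairs(table, [phen[i], phen[j]])
                fit = cholesky.fit_cholesky(pairs, "ACE", seed=config.seed, n_starts=3)
                est = cholesky.component_correlations(fit.structure, "genetic")
                rg[i, j] = rg[j, i] = est.values[0, 1]
        rg_df = pd.DataFrame(rg, index=phen, columns=phen)
        report["pairwise_rg"] = rg_df
        if outdir is not None:
            rg_df.to_csv(outdir / "pairwise_rg.tsv", sep="\t")

        if len(phen) < 3:  # multivariate structure needs several traits
            return report

        stage = "multivariate"
        log.info("stage %s: %d-factor IPM, shared_c=%s", stage, config.factors,
                 config.shared_c)
        pairs, _ = assemble_pairs(table, phen)
        sat = cholesky.fit_cholesky(pairs, "ACE", seed=config.seed,
                                    n_starts=2) if config.fit_saturated else None
        ipm = pathway.fit_kfactor_ipm(pairs, k_a=config.factors,
                                      shared_c=config.shared_c, seed=config.seed)
        props = pathway.variance_proportions(ipm.structure)
        multi = {
            "ipm_loglik": ipm.loglik, "ipm_aic": ipm.aic,
            "factor_proportions": props.factor_proportions,
            "specific_proportion": props.specific_proportion,
            "loadings_a": ipm.structure.lambda_a,
        }
        if sat is not None:
            multi.update({"saturated_loglik": sat.loglik, "saturated_aic": sat.aic,
                          "lrt_ipm_vs_saturated": vars(lrt(sat, ipm))})
        report["multivariate"] = multi
        checkpoint("multivariate", multi)

        stage = "structure-discovery"
        rg_model = cholesky.component_correlations(
            ipm.structure, "genetic", labels=phen)
        pheno_model = cholesky.component_correlations(
            ipm.structure, "phenotypic", labels=phen)
        scree = clustering.eigen_scree(pheno_model.values, labels=phen)
        trees = {}
        for tag, mat in (("genetic", rg_model.values), ("phenotypic", pheno_model.values)):
            tree = clustering.cluster_correlations(mat, labels=phen,
                                                   linkage=config.linkage)
            k = clustering.select_k(tree)
            trees[tag] = {"k": k, "partition": tree.cut(k), "newick": tree.to_newick()}
            if outdir is not None:
                (outdir / f"dendrogram_{tag}.nwk").write_text(trees[tag]["newick"] + "\n")
                _write_heatmap(mat, phen, tree, outdir / f"heatmap_{tag}.svg")
        report["clusters"] = trees
        report["scree"] = {"eigenvalues": scree.eigenvalues,
                           "elbow": scree.elbow_count, "kaiser": scree.kaiser_count}
        checkpoint("clusters", {"clusters": trees, "scree": report["scree"]})
    except TwinSemError:
        raise
    except Exception as exc:  # tag unexpected failures with their stage
        raise StageError(stage, exc) from exc
    return report


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    return str(obj)


def _write_heatmap(mat, labels, tree, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy as hc

    order = hc.leaves_list(tree.linkage_matrix)
    M = np.asarray(mat)[np.ix_(order, order)]
    labs = [tree.labels[i] for i in order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(M, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(labs)), labs, rotation=90, fontsize=7)
    ax.set_yticks(range(len(labs)), labs, fontsize=7)
    fig.colorbar(im, ax=ax, label="correlation")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
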