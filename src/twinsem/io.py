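"""Reading, validating and pairing wide-format twin phenotype tables.

The expected table has one row per individual: a family id, a twin index
(1 or 2), zygosity (``MZ``/``DZ``), one column per phenotype (volumes in
their raw units) and covariates.  Covariates enter the model means as
intercept, age, sex (1 = male, 0 = female), scanner dummies (four
scanners coded with three indicators against a configurable reference
level) and intracranial volume, in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import PairingError, SchemaError

STRUCTURAL_COLUMNS = ("family_id", "twin_index", "zygosity")


@dataclass
class CovariateSpec:
    """Which table columns enter the mean model, and how.

    ``scanner`` is expanded into ``n_levels - 1`` dummy indicators with
    ``scanner_reference`` as the omitted level.  Set any entry to None to
    drop it; with everything dropped the design is an intercept only.
    """

    age: Optional[str] = "age"
    sex: Optional[str] = "sex"
    scanner: Optional[str] = "scanner"
    icv: Optional[str] = "icv"
    scanner_reference: object = None
    scanner_levels: Optional[list] = None  # declared levels; else observed ones

    @classmethod
    def none(cls) -> "CovariateSpec":
        """Intercept-only mean model."""
        return cls(age=None, sex=None, scanner=None, icv=None)

    @classmethod
    def from_yaml(cls, path) -> "CovariateSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        cov = cfg.get("covariates", cfg)
        return cls(age=cov.get("age"), sex=cov.get("sex"), scanner=cov.get("scanner"),
                   icv=cov.get("icv"), scanner_reference=cov.get("scanner_reference"))

    def columns(self) -> list[str]:
        return [c for c in (self.age, self.sex, self.scanner, self.icv) if c is not None]


@dataclass
class TwinPair:
    """One family: both twins' phenotype vectors and mean-model designs."""

    family_id: str
    zygosity: str
    y1: np.ndarray
    y2: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    mask1: np.ndarray = None  # True where observed
    mask2: np.ndarray = None

    def __post_init__(self):
        self.y1 = np.asarray(self.y1, dtype=float)
        self.y2 = np.asarray(self.y2, dtype=float)
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        if self.y1.shape != self.y2.shape:
            raise SchemaError("twin phenotype vectors differ in length")
        if self.x1.shape != self.x2.shape:
            raise SchemaError("twin covariate designs differ in length")
        if self.zygosity not in ("MZ", "DZ"):
            raise SchemaError(f"zygosity must be MZ or DZ, got {self.zygosity!r}")
        if self.mask1 is None:
            self.mask1 = np.isfinite(self.y1)
        if self.mask2 is None:
            self.mask2 = np.isfinite(self.y2)

    @property
    def p(self) -> int:
        return self.y1.size

    @property
    def complete(self) -> bool:
        return bool(self.mask1.all() and self.mask2.all())


@dataclass
class PhenotypeTable:
    """A validated individual-level table plus its column declarations."""

    data: pd.DataFrame
    phenotype_names: list[str]
    covariates: CovariateSpec = field(default_factory=CovariateSpec)

    def __post_init__(self):
        validate_table(self.data, self.phenotype_names, self.covariates)
        self.data = self.data.copy()
        self.data["family_id"] = self.data["family_id"].astype(str)

    @property
    def n_families(self) -> int:
        return self.data["family_id"].nunique()

    def write(self, path) -> None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        self.data.to_csv(path, sep=sep, index=False)


def validate_table(df: pd.DataFrame, phenotype_names: Sequence[str],
                   covariates: CovariateSpec) -> None:
    missing = [c for c in (*STRUCTURAL_COLUMNS, *phenotype_names, *covariates.columns())
               if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    sizes = df.groupby("family_id").size()
    bad = sizes.index[sizes != 2].tolist()
    if bad:
        raise PairingError(
            f"families without exactly two members: {bad}", families=bad)
    for fid, grp in df.groupby("family_id"):
        if set(grp["twin_index"]) != {1, 2}:
            raise PairingError(
                f"family {fid!r} lacks twin indices {{1, 2}}", families=[fid])
        if grp["zygosity"].nunique() != 1:
            raise PairingError(
                f"family {fid!r} has inconsistent zygosity", families=[fid])
    bad_zyg = set(df["zygosity"].unique()) - {"MZ", "DZ"}
    if bad_zyg:
        raise SchemaError(f"unrecognised zygosity codes: {sorted(bad_zyg)}")


def read_table(path, phenotype_names: Sequence[str],
               covariate_spec: Optional[CovariateSpec] = None,
               column_map: Optional[dict] = None) -> PhenotypeTable:
    """Read a CSV/TSV phenotype table and validate its family structure.

    ``column_map`` renames input columns to the package's snake-case
    dialect (e.g. ``{"famid": "family_id"}``) before validation.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    spec = covariate_spec or CovariateSpec()
    return PhenotypeTable(df, list(phenotype_names), spec)


def design_matrix(table: PhenotypeTable) -> tuple[np.ndarray, list[str]]:
    """Per-individual mean-model design: intercept, age, sex, scanner dummies, ICV."""
    df, spec = table.data, table.covariates
    cols = [np.ones(len(df))]
    names = ["intercept"]
    if spec.age:
        cols.append(df[spec.age].to_numpy(dtype=float))
        names.append(spec.age)
    if spec.sex:
        cols.append(df[spec.sex].to_numpy(dtype=float))
        names.append(spec.sex)
    if spec.scanner:
        observed = set(df[spec.scanner].unique())
        levels = (list(spec.scanner_levels) if spec.scanner_levels is not None
                  else sorted(observed, key=str))
        stray = observed - set(levels)
        if stray:
            raise SchemaError(f"scanner levels {sorted(stray, key=str)} not declared")
        ref = spec.scanner_reference if spec.scanner_reference is not None else levels[0]
        if ref not in levels:
            raise SchemaError(f"scanner reference level {ref!r} not among levels")
        for lev in levels:
            if lev == ref:
                continue
            cols.append((df[spec.scanner] == lev).to_numpy(dtype=float))
            names.append(f"{spec.scanner}[{lev}]")
    if spec.icv:
        cols.append(df[spec.icv].to_numpy(dtype=float))
        names.append(spec.icv)
    return np.column_stack(cols), names


def assemble_pairs(table: PhenotypeTable,
                   phenotypes: Optional[Sequence[str]] = None
                   ) -> tuple[list[TwinPair], list[str]]:
    """Build one TwinPair per family, ordered by family id then twin index.

    Returns the pair list and the design-column names.  Requested
    phenotypes keep the order in which they are asked for.
    """
    phenotypes = list(phenotypes) if phenotypes is not None else list(table.phenotype_names)
    absent = [ph for ph in phenotypes if ph not in table.data.columns]
    if absent:
        raise SchemaError(f"requested phenotypes not in table: {absent}")
    X, names = design_matrix(table)
    df = table.data.reset_index(drop=True)
    Y = df[phenotypes].to_numpy(dtype=float)
    order = np.lexsort((df["twin_index"].to_numpy(), df["family_id"].to_numpy()))
    pairs = []
    for k in range(0, len(order), 2):
        i1, i2 = order[k], order[k + 1]
        pairs.append(TwinPair(
            family_id=df.at[i1, "family_id"],
            zygosity=df.at[i1, "zygosity"],
            y1=Y[i1], y2=Y[i2], x1=X[i1], x2=X[i2],
        ))
    return pairs, names
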