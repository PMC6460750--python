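"""Readers/writers for the exchanged tables, run configuration and manifest.

Dialects: comma-separated record tables (pedigree, phenotypes), tab-separated
matrices (kernels, genotypes, LD curves), decimal point always ``.``.  Every
writer can stamp a provenance header (``# key=value`` comment lines) carrying
the config hash and master seed; readers skip such lines.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genomics import GenotypeMatrix
from .mixed_model import TrialData
from .pedigree import Pedigree, RelationshipMatrix

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_genotypes",
    "read_plink_raw",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_matrix",
    "write_matrix",
    "write_matrix_long",
    "read_tables",
    "RunConfig",
    "config_hash",
    "write_manifest",
]

log = logging.getLogger(__name__)

MISSING_TOKENS = {"NA", "NaN", "nan", ""}


def _header_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def _read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


# ----------------------------------------------------------------------
# Pedigree
# ----------------------------------------------------------------------

def read_pedigree(path) -> Pedigree:
    df = _read_table(path, dtype=str)
    return Pedigree.from_frame(df)


def write_pedigree(ped: Pedigree, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        ped.to_frame().to_csv(fh, index=False)


# ----------------------------------------------------------------------
# Genotypes
# ----------------------------------------------------------------------

def _parse_dosages(df: pd.DataFrame, source: str) -> np.ndarray:
    values = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].astype(str)):
            s = raw.strip()
            if s in MISSING_TOKENS:
                continue
            try:
                v = float(s)
            except ValueError:
                v = -1.0
            if v not in (0.0, 1.0, 2.0):
                raise ValueError(
                    f"{source}: invalid dosage {raw!r} at row {df.index[i]!r}, "
                    f"marker {col!r} (expected 0/1/2 or NA)"
                )
            values[i, j] = v
    return values


def read_genotypes(path, meta_path=None) -> GenotypeMatrix:
    """Dosage TSV: rows = individuals (first column id), header = marker ids."""
    df = _read_table(path, sep="\t", dtype=str)
    id_col = df.columns[0]
    df = df.set_index(id_col)
    dos = _parse_dosages(df, str(path))
    marker_ids = [str(c) for c in df.columns]
    meta = _read_marker_meta(meta_path, marker_ids)
    return GenotypeMatrix([str(i) for i in df.index], marker_ids, dos, meta)


def read_plink_raw(path, meta_path=None) -> GenotypeMatrix:
    """PLINK-RAW dialect: FID IID PAT MAT SEX PHENOTYPE then dosage columns."""
    df = _read_table(path, sep=r"\s+", dtype=str)
    expected = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[:6]) != expected:
        raise ValueError(
            f"{path}: not a PLINK-RAW header (expected {expected}, got {list(df.columns[:6])})"
        )
    ids = df["IID"].astype(str).tolist()
    dose_df = df.iloc[:, 6:].copy()
    dose_df.index = ids
    dos = _parse_dosages(dose_df, str(path))
    # strip the _ALLELE suffix PLINK appends to marker names, if present
    marker_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in dose_df.columns]
    meta = _read_marker_meta(meta_path, marker_ids)
    return GenotypeMatrix(ids, marker_ids, dos, meta)


def _read_marker_meta(meta_path, marker_ids: list[str]) -> pd.DataFrame:
    if meta_path is None:
        return pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(1, len(marker_ids) + 1),
             "qa": 1.0, "qb": 1.0},
            index=marker_ids,
        )
    meta = _read_table(meta_path, sep="\t").set_index("marker")
    meta.index = meta.index.astype(str)
    missing = [m for m in marker_ids if m not in meta.index]
    if missing:
        raise ValueError(f"marker metadata missing entries for: {missing[:10]}")
    return meta.loc[marker_ids, ["chrom", "pos", "qa", "qb"]]


def write_genotypes(g: GenotypeMatrix, path, meta_path=None, meta: dict | None = None) -> None:
    df = pd.DataFrame(g.dosages, index=g.individual_ids, columns=g.marker_ids)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        out = df.copy()
        if not g.imputed:
            out = out.astype("object")
            for c in out.columns:
                col = out[c]
                out[c] = col.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
        out.to_csv(fh, sep="\t", index_label="id", na_rep="NA")
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            fh.write(_header_lines(meta))
            g.marker_meta.to_csv(fh, sep="\t", index_label="marker")


# ----------------------------------------------------------------------
# Phenotypes
# ----------------------------------------------------------------------

def read_phenotypes(path) -> TrialData:
    """Long-format phenotype CSV: id, trait, value, seed_source, replicate, set, orchard."""
    df = _read_table(path, dtype={"id": str})
    need = {"id", "trait", "value", "seed_source", "replicate", "set", "orchard"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns {sorted(missing)}")
    wide = df.pivot_table(
        index=["id", "seed_source", "replicate", "set", "orchard"],
        columns="trait",
        values="value",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    traits = [c for c in wide.columns if c not in TrialData.REQUIRED]
    return TrialData(wide, [str(t) for t in traits])


def write_phenotypes(data: TrialData, path, meta: dict | None = None) -> None:
    long = data.frame.melt(
        id_vars=list(TrialData.REQUIRED),
        value_vars=data.trait_columns,
        var_name="trait",
        value_name="value",
    )
    long = long[["id", "trait", "value", "seed_source", "replicate", "set", "orchard"]]
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        long.to_csv(fh, index=False)


# ----------------------------------------------------------------------
# Matrices
# ----------------------------------------------------------------------

def read_matrix(path, kind: str = "A") -> RelationshipMatrix:
    df = _read_table(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return RelationshipMatrix(list(df.index), df.to_numpy(dtype=float), kind=kind)


def write_matrix(K: RelationshipMatrix, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        K.to_frame().to_csv(fh, sep="\t", index_label="id")


def write_matrix_long(K: RelationshipMatrix, path, meta: dict | None = None) -> None:
    """Sparse-exchange long format: one (i, j, value) row per upper-triangle pair."""
    n = len(K.labels)
    iu, ju = np.triu_indices(n)
    df = pd.DataFrame(
        {
            "i": [K.labels[a] for a in iu],
            "j": [K.labels[b] for b in ju],
            "value": K.values[iu, ju],
        }
    )
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep="\t", index=False)


# ----------------------------------------------------------------------
# Reconciliation + combined reader
# ----------------------------------------------------------------------

def read_tables(
    pedigree_path, genotype_path, phenotype_path, marker_meta_path=None
) -> tuple[Pedigree, GenotypeMatrix, TrialData, dict]:
    """Load the three tables, validating invariants and reconciling ids.

    Phenotyped ids absent from the genotype matrix or pedigree are *listed* in
    the reconciliation report (never silently dropped).
    """
    ped = read_pedigree(pedigree_path)
    geno = (
        read_plink_raw(genotype_path, marker_meta_path)
        if str(genotype_path).endswith(".raw")
        else read_genotypes(genotype_path, marker_meta_path)
    )
    pheno = read_phenotypes(phenotype_path)

    ped_ids = set(ped.topological_ids())
    geno_ids = set(geno.individual_ids)
    pheno_ids = set(pheno.ids)
    report = {
        "n_pedigree": len(ped),
        "n_genotyped": len(geno.individual_ids),
        "n_phenotyped": len(pheno_ids),
        "phenotyped_not_genotyped": sorted(pheno_ids - geno_ids),
        "phenotyped_not_in_pedigree": sorted(pheno_ids - ped_ids),
        "genotyped_not_phenotyped": sorted(geno_ids - pheno_ids),
    }
    for key in ("phenotyped_not_genotyped", "phenotyped_not_in_pedigree"):
        if report[key]:
            log.warning("%s: %d ids (e.g. %s)", key, len(report[key]), report[key][:5])
    return ped, geno, pheno, report


# ----------------------------------------------------------------------
# Run configuration and manifest
# ----------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``orchard-gblup run``)."""

    out_dir: str
    seed: int = 0
    simulation: dict | None = None
    pedigree_path: str | None = None
    genotype_path: str | None = None
    marker_meta_path: str | None = None
    phenotype_path: str | None = None
    filter_thresholds: dict = field(default_factory=dict)
    traits: list | None = None
    cv_scenarios: list = field(default_factory=lambda: ["W-W", "T-T", "W-T", "T-W", "WT-WT"])
    n_folds: int = 10
    n_replications: int = 30
    selection_proportion: float = 0.2
    trait_directions: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulation is None:
            for name in ("pedigree_path", "genotype_path", "phenotype_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(
                        f"config needs either a simulation block or {name}"
                    )
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")
        for key, lo, hi in (
            ("quality_a", 0, 1), ("quality_b", 0, 1), ("maf", 0, 0.5),
            ("call_rate", 0, 1), ("ld_r2", 0, 1),
        ):
            v = self.filter_thresholds.get(key)
            if v is not None and not lo <= v <= hi:
                raise ValueError(f"filter threshold {key}={v} outside [{lo}, {hi}]")
        if not 0 < self.selection_proportion <= 1:
            raise ValueError("selection_proportion must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_manifest(path, config: dict, seed: int, artifacts: dict[str, str]) -> dict:
    import orchard_gblup

    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "package_version": orchard_gblup.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "artifacts": artifacts,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
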