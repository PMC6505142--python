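"""Readers and writers for the plain-text formats the package touches.

Genotypes travel as TSV (header = locus labels, one row per individual,
values 0/1/2) or in the PLINK ``.raw`` dialect (six pedigree columns
``FID IID PAT MAT SEX PHENOTYPE`` followed by allele-count SNP columns).
Missing values are rejected: the model has no missingness concept, so a
hole in the data is an input error, reported with its row and column.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .haplotypes import GenotypeMatrix, HaplotypeDistribution

__all__ = [
    "GenotypeParseError",
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "write_phenotype",
    "read_covariates",
    "read_distribution",
    "write_distribution",
    "RunManifest",
]

_PLINK_PEDIGREE = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class GenotypeParseError(ValueError):
    """Malformed genotype file; message names the offending cell."""


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in {"tsv", "plink_raw"}:
            raise ValueError(f"unknown genotype format {fmt!r}")
        return fmt
    return "plink_raw" if path.suffix == ".raw" else "tsv"


def _validate_codes(df: pd.DataFrame, path: Path) -> np.ndarray:
    arr = df.to_numpy()
    bad = pd.isna(df)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise GenotypeParseError(
            f"{path}: missing value at row {r + 1}, column {df.columns[c]!r}"
        )
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1, 2)).all() or not np.allclose(arr, np.round(arr)):
        mask = ~np.isin(arr, (0, 1, 2))
        r, c = np.argwhere(mask)[0]
        raise GenotypeParseError(
            f"{path}: non-{{0,1,2}} genotype {arr[r, c]!r} at row {r + 1}, "
            f"column {df.columns[c]!r}"
        )
    return arr.astype(np.int8)


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Read raw allele-count genotypes from TSV or PLINK ``.raw``.

    The format is auto-detected from the extension (``.raw`` -> plink_raw)
    unless ``fmt`` overrides it.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(path, sep=r"\s+")
        missing = [c for c in _PLINK_PEDIGREE if c not in df.columns]
        if missing:
            raise GenotypeParseError(f"{path}: .raw header lacks pedigree columns {missing}")
        df = df.drop(columns=_PLINK_PEDIGREE)
    if df.shape[1] == 0:
        raise GenotypeParseError(f"{path}: no genotype columns found")
    codes = _validate_codes(df, path)
    return GenotypeMatrix(codes, locus_labels=tuple(df.columns))


def write_genotypes(G: GenotypeMatrix, path: str | Path, fmt: str | None = None) -> Path:
    """Write raw genotypes as TSV or PLINK ``.raw`` (no missing values)."""
    if G.centered:
        raise ValueError("only raw (0/1/2) genotypes are written to disk")
    path = Path(path)
    fmt = _detect_format(path, fmt)
    df = pd.DataFrame(G.codes, columns=list(G.locus_labels))
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        ped = pd.DataFrame(
            {
                "FID": [f"F{i + 1}" for i in range(G.n)],
                "IID": [f"I{i + 1}" for i in range(G.n)],
                "PAT": 0,
                "MAT": 0,
                "SEX": 0,
                "PHENOTYPE": -9,
            }
        )
        pd.concat([ped, df], axis=1).to_csv(path, sep=" ", index=False)
    return path


def read_phenotype(path: str | Path) -> pd.Series:
    """Phenotype TSV with columns (IID, value)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: phenotype file must have exactly two columns (IID, value)")
    if df.iloc[:, 1].isna().any():
        raise ValueError(f"{path}: phenotype contains missing values")
    return pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0], name="phenotype")


def write_phenotype(values: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    values = np.asarray(values).ravel()
    pd.DataFrame(
        {"IID": [f"I{i + 1}" for i in range(values.size)], "value": values}
    ).to_csv(path, sep="\t", index=False)
    return path


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Covariate TSV: first column IID, remaining columns numeric covariates."""
    df = pd.read_csv(path, sep="\t")
    cov = df.iloc[:, 1:]
    if cov.isna().to_numpy().any():
        raise ValueError(f"{path}: covariates contain missing values")
    return cov.astype(float)


def read_distribution(path: str | Path) -> HaplotypeDistribution:
    return HaplotypeDistribution.from_json(Path(path).read_text())


def write_distribution(dist: HaplotypeDistribution, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(dist.to_json())
    return path


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every experiment output."""

    config: dict
    master_seed: int
    package_version: str
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S%z"))
    file_digests: dict[str, str] = field(default_factory=dict)

    def add_file(self, path: str | Path) -> None:
        p = Path(path)
        self.file_digests[p.name] = _sha256(p)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "config": self.config,
                    "master_seed": self.master_seed,
                    "package_version": self.package_version,
                    "timestamp": self.timestamp,
                    "file_digests": self.file_digests,
                },
                indent=1,
            )
        )
        return path
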