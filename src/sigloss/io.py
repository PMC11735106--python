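"""Tabular and gene-set I/O.

Expression matrices travel as TSV (first column = gene id, header row =
sample ids), clinical tables as TSV with ``sample_id``, ``time``, ``event``
and covariate columns, gene signatures as GMT, ranked lists as RNK, and
per-study hazard-ratio tables as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

SCALES = ("raw_counts", "normalized", "log2")


class SiglossError(Exception):
    """Base class for user-facing errors."""


class ConfigError(SiglossError):
    """Invalid configuration value; message names the offending field."""


class ScaleError(SiglossError):
    """Operation applied to an expression matrix on the wrong scale."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression with a declared scale.

    ``values`` is a genes x samples DataFrame (index = gene ids, columns =
    sample ids). ``scale`` is one of ``raw_counts`` (nonnegative integers),
    ``normalized`` (nonnegative reals) or ``log2``.
    """

    values: pd.DataFrame
    scale: str = "normalized"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ConfigError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise SiglossError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise SiglossError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            raise SiglossError("expression matrix contains missing values")
        if self.scale != "log2" and (arr < 0).any():
            raise SiglossError(f"negative values not allowed on scale {self.scale!r}")
        if self.scale == "raw_counts" and not np.allclose(arr, np.round(arr)):
            raise ScaleError("raw_counts matrix must contain integers")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def log2_values(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """Return values on the log2 scale (log2(x + pseudocount) unless already log2)."""
        if self.scale == "log2":
            return self.values
        return np.log2(self.values + pseudocount)


@dataclass
class GeneSignature:
    """Directed gene list: genes up- and down-regulated in the loss phenotype."""

    name: str
    up_genes: set[str] = field(default_factory=set)
    down_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.up_genes = set(self.up_genes)
        self.down_genes = set(self.down_genes)
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise SiglossError(f"signature up/down sets overlap: {sorted(overlap)[:5]}")
        if not (self.up_genes or self.down_genes):
            import warnings
            warnings.warn(f"signature {self.name!r} is empty", stacklevel=2)

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


def read_expression(path: str | Path, scale: str = "normalized") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, scale=scale)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise SiglossError(f"clinical table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise SiglossError("duplicate sample ids in clinical table")
    return df.set_index("sample_id")


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    out = clinical.reset_index() if clinical.index.name == "sample_id" else clinical
    out.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: gene list} (description field discarded)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SiglossError(f"malformed GMT line (need name, description, genes): {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, list[str] | set[str]], path: str | Path,
              description: str = "sigloss") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def signature_to_gmt(sig: GeneSignature, path: str | Path) -> None:
    write_gmt({f"{sig.name}_UP": sig.up_genes, f"{sig.name}_DOWN": sig.down_genes}, path)


def signature_from_gmt(path: str | Path, name: str | None = None) -> GeneSignature:
    sets = read_gmt(path)
    up = set().union(*[v for k, v in sets.items() if k.upper().endswith("_UP")] or [set()])
    down = set().union(*[v for k, v in sets.items() if k.upper().endswith("_DOWN")] or [set()])
    if not (up or down):  # single unsuffixed set -> treat as up
        first = next(iter(sets))
        up = set(sets[first])
        name = name or first
    return GeneSignature(name or Path(path).stem, up_genes=up, down_genes=down)


def read_rnk(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "metric"], comment="#")
    s = pd.Series(df["metric"].to_numpy(float), index=df["gene_id"].astype(str))
    if s.index.has_duplicates:
        raise SiglossError("duplicate gene ids in RNK file")
    return s


def write_rnk(metric: pd.Series, path: str | Path) -> None:
    metric.to_csv(path, sep="\t", header=False)


def read_studies(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"study_id", "hr", "ci_low", "ci_high"}
    missing = required - set(df.columns)
    if missing:
        raise SiglossError(f"study table missing columns: {sorted(missing)}")
    return df
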