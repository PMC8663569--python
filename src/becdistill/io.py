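"""Core data containers and file formats.

The pipeline moves three kinds of objects between stages: a log2
expression matrix (genes x samples), a per-sample clinical metadata
table, and a library of typed gene sets.  All three are thin,
validated wrappers around pandas objects and round-trip through
plain-text formats (TSV/CSV for tables, GMT for gene sets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEVERITY_LEVELS = ("HC", "MMA", "SA")
SEX_LEVELS = ("F", "M")
SET_TYPES = ("BP", "TFT", "OTHER")


class FormatError(ValueError):
    """Raised when an input file or table violates a format contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    counts = pd.Series(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise FormatError(f"duplicate {what}: {sorted(dups.index.tolist())}")


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes as rows, samples as columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index.astype(str), "gene IDs")
        _check_unique(self.data.columns.astype(str), "sample IDs")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            bad = self.data.map(lambda v: not isinstance(v, (int, float, np.number)))
            r, c = np.argwhere(bad.to_numpy())[0]
            raise FormatError(
                f"non-numeric value at gene {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if values.size and not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at gene {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns.astype(str))

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[genes])


@dataclass
class SampleMetadata:
    """Per-sample clinical annotations.

    Required columns: severity (HC/MMA/SA), sex (F/M), ics_dose
    (ordinal 0..4), ocs_use (bool), fev1_pct (percent predicted,
    0..200).  Optional: cluster.  Indexed by sample ID.
    """

    table: pd.DataFrame

    REQUIRED = ("severity", "sex", "ics_dose", "ocs_use", "fev1_pct")

    def __post_init__(self) -> None:
        t = self.table
        if "sample_id" in t.columns:
            t = t.set_index("sample_id")
        _check_unique(t.index.astype(str), "sample IDs")
        for col in self.REQUIRED:
            if col not in t.columns:
                raise FormatError(f"metadata missing required column {col!r}")
        bad_sev = set(t["severity"]) - set(SEVERITY_LEVELS)
        if bad_sev:
            raise FormatError(f"unknown severity values {sorted(bad_sev)}")
        bad_sex = set(t["sex"]) - set(SEX_LEVELS)
        if bad_sex:
            raise FormatError(f"unknown sex values {sorted(bad_sex)}")
        fev1 = t["fev1_pct"].astype(float)
        if ((fev1 < 0) | (fev1 > 200)).any():
            raise FormatError("fev1_pct outside [0, 200]")
        t = t.copy()
        t["ocs_use"] = t["ocs_use"].astype(bool)
        t["ics_dose"] = t["ics_dose"].astype(int)
        t["fev1_pct"] = fev1
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index.astype(str))

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples absent from metadata: {missing}")
        return SampleMetadata(self.table.loc[list(sample_ids)])


@dataclass(frozen=True)
class GeneSet:
    name: str
    set_type: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.set_type not in SET_TYPES:
            raise FormatError(
                f"gene set {self.name!r}: type {self.set_type!r} not in {SET_TYPES}"
            )
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetLibrary:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise FormatError(f"duplicate gene set name {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set

    def of_type(self, set_type: str) -> "GeneSetLibrary":
        return GeneSetLibrary(
            {n: s for n, s in self.sets.items() if s.set_type == set_type}
        )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetLibrary):
            return NotImplemented
        return self.sets == other.sets


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample table (first column = gene ID, header = samples)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.argmax()]
                raise FormatError(
                    f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}"
                ) from None
        raise
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.data.to_csv(path, sep=_sep_for(path), index_label="gene_id", float_format="%.10g")


def read_metadata(path: str | Path) -> SampleMetadata:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: metadata needs a 'sample_id' column")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    path = Path(path)
    meta.table.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Read a GMT gene-set file; the description field carries the set type."""
    path = Path(path)
    lib = GeneSetLibrary()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not any(ln.strip() for ln in lines):
        logger.warning("GMT file %s is empty", path)
        return lib
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{i}: GMT line has {len(fields)} fields, need >=3")
        name, desc = fields[0], fields[1]
        set_type = desc if desc in SET_TYPES else "OTHER"
        lib.add(GeneSet(name, set_type, tuple(fields[2:])))
    return lib


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in library:
            fh.write("\t".join([gs.name, gs.set_type, *gs.genes]) + "\n")
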