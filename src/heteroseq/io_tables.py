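"""Tabular input/output and validation for the three-library heterosis pipeline.

Everything the pipeline touches is plain tab-separated text with a header row;
lines starting with ``#`` are comments.  Counts are uniquely-mapped reads, so
library sizes are never inferred from column sums -- they arrive in a small
YAML/JSON sidecar (or are passed explicitly) and must dominate every per-gene
count of their library.

The two domain containers are :class:`CountTable` (per-gene counts for the two
parents P1/P2 and the hybrid F1, with gene lengths and library totals) and
:class:`GeneAnnotation` (chromosome, derived subgenome, GO terms, transposable
element status).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

LIBRARIES = ("P1", "P2", "F1")
A_CHROMOSOMES = tuple(f"A{i:02d}" for i in range(1, 11))
C_CHROMOSOMES = tuple(f"C{i:02d}" for i in range(1, 10))
CHROMOSOMES = A_CHROMOSOMES + C_CHROMOSOMES
UNPLACED = "unplaced"

COUNT_COLUMNS = ("gene_id", "length_bp", "count_P1", "count_P2", "count_F1")
ANNOTATION_COLUMNS = ("gene_id", "chromosome", "go_terms", "is_te", "te_family")
CT_COLUMNS = ("gene_id", "sample", "replicate", "ct_target", "ct_reference")


class FormatError(ValueError):
    """A table is structurally malformed (missing column, bad header)."""


class ValidationError(ValueError):
    """A table row violates a stated invariant; the message names the gene."""


@dataclass
class CountTable:
    """Per-gene read counts for the P1/P2/F1 libraries.

    ``genes`` holds columns ``gene_id, length_bp, count_P1, count_P2,
    count_F1``; ``lib_sizes`` maps each library to its total number of mapped
    reads.  Row order is preserved from the source file.
    """

    genes: pd.DataFrame
    lib_sizes: dict[str, int]

    def __post_init__(self) -> None:
        self.genes = self.genes.reset_index(drop=True)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        for col in COUNT_COLUMNS:
            if col not in self.genes.columns:
                raise FormatError(f"count table is missing required column {col!r}")
        for lib in LIBRARIES:
            if lib not in self.lib_sizes:
                raise FormatError(f"library size for {lib!r} not supplied")
            if int(self.lib_sizes[lib]) < 1:
                raise ValidationError(f"library size for {lib!r} must be positive")
            self.lib_sizes[lib] = int(self.lib_sizes[lib])
        g = self.genes
        dup = g["gene_id"].duplicated()
        if dup.any():
            offender = g.loc[dup, "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene_id {offender!r} in count table")
        for col in ("length_bp", "count_P1", "count_P2", "count_F1"):
            vals = g[col]
            numeric = pd.to_numeric(vals, errors="coerce")
            bad = numeric.isna() | (numeric != np.floor(numeric))
            if bad.any():
                offender = g.loc[bad, "gene_id"].iloc[0]
                raise ValidationError(
                    f"non-integer value in {col!r} for gene {offender!r}"
                )
            g[col] = numeric.astype(np.int64)
        short = g["length_bp"] < 1
        if short.any():
            offender = g.loc[short, "gene_id"].iloc[0]
            raise ValidationError(f"length_bp < 1 for gene {offender!r}")
        for lib in LIBRARIES:
            col = f"count_{lib}"
            neg = g[col] < 0
            if neg.any():
                offender = g.loc[neg, "gene_id"].iloc[0]
                raise ValidationError(f"negative count in {col!r} for gene {offender!r}")
            if len(g) and int(g[col].max()) > self.lib_sizes[lib]:
                offender = g.loc[g[col].idxmax(), "gene_id"]
                raise ValidationError(
                    f"count for gene {offender!r} exceeds library size of {lib}"
                )

    # -- convenience ------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Series:
        return self.genes["gene_id"]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def counts(self, lib: str) -> np.ndarray:
        return self.genes[f"count_{lib}"].to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.lib_sizes == other.lib_sizes and self.genes.equals(other.genes)


@dataclass(frozen=True)
class GeneAnnotation:
    """Chromosome placement, GO terms and TE status for one gene."""

    gene_id: str
    chromosome: str = UNPLACED
    go_terms: frozenset[str] = field(default_factory=frozenset)
    is_te: bool = False
    te_family: str = ""

    @property
    def subgenome(self) -> str:
        if self.chromosome.startswith("A") and self.chromosome in A_CHROMOSOMES:
            return "A"
        if self.chromosome.startswith("C") and self.chromosome in C_CHROMOSOMES:
            return "C"
        return "unassigned"


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_lib_sizes(path: str | Path) -> dict[str, int]:
    """Read a YAML (or JSON) sidecar mapping library name -> total mapped reads."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise FormatError(f"library-size sidecar {path} is not a mapping")
    missing = [lib for lib in LIBRARIES if lib not in data]
    if missing:
        raise FormatError(f"library-size sidecar missing entries for {missing}")
    return {lib: int(data[lib]) for lib in LIBRARIES}


def write_lib_sizes(lib_sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: int(v) for k, v in lib_sizes.items()}, fh)


def read_count_table(
    path: str | Path,
    lib_sizes: Mapping[str, int] | None = None,
    sizes_path: str | Path | None = None,
) -> CountTable:
    """Read and validate a counts TSV.

    Library sizes come either from ``lib_sizes`` directly or from the YAML
    sidecar at ``sizes_path``; they are never inferred from column sums because
    the counts are uniquely-mapped reads only.
    """
    if lib_sizes is None:
        if sizes_path is None:
            raise FormatError("library sizes required: pass lib_sizes or sizes_path")
        lib_sizes = read_lib_sizes(sizes_path)
    df = _read_tsv(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"count table {path} missing column(s) {missing}")
    return CountTable(df[list(COUNT_COLUMNS)].copy(), dict(lib_sizes))


def write_count_table(
    table: CountTable, path: str | Path, sizes_path: str | Path | None = None
) -> None:
    table.genes.to_csv(path, sep="\t", index=False)
    if sizes_path is not None:
        write_lib_sizes(table.lib_sizes, sizes_path)


def _parse_bool(value: str, gene_id: str, column: str) -> bool:
    v = value.strip().lower()
    if v in ("1", "true", "yes", "y", "te"):
        return True
    if v in ("", "0", "false", "no", "n"):
        return False
    raise ValidationError(f"cannot parse {column}={value!r} for gene {gene_id!r}")


def read_annotation(
    path: str | Path, strict: bool = False
) -> dict[str, GeneAnnotation]:
    """Read a gene annotation TSV into a ``gene_id -> GeneAnnotation`` map.

    Only ``gene_id`` and ``chromosome`` are required; GO terms are
    semicolon-joined and TE columns optional.  Unknown chromosome labels are
    demoted to ``unplaced`` with a warning in lenient mode (the default) and
    raise in strict mode.  Genes absent from the table are simply absent from
    the map; consumers treat them as unplaced/unannotated.
    """
    df = _read_tsv(path)
    for col in ("gene_id", "chromosome"):
        if col not in df.columns:
            raise FormatError(f"annotation table {path} missing column {col!r}")
    out: dict[str, GeneAnnotation] = {}
    for row in df.itertuples(index=False):
        gene_id = getattr(row, "gene_id")
        if gene_id in out:
            raise ValidationError(f"duplicate gene_id {gene_id!r} in annotation")
        chrom = getattr(row, "chromosome").strip()
        if chrom not in CHROMOSOMES and chrom != UNPLACED:
            if strict:
                raise ValidationError(
                    f"unknown chromosome {chrom!r} for gene {gene_id!r}"
                )
            if chrom:
                warnings.warn(
                    f"unknown chromosome {chrom!r} for gene {gene_id!r}; "
                    "treating as unplaced",
                    stacklevel=2,
                )
            chrom = UNPLACED
        raw_go = getattr(row, "go_terms", "") if "go_terms" in df.columns else ""
        go = frozenset(t.strip() for t in raw_go.split(";") if t.strip())
        is_te = (
            _parse_bool(getattr(row, "is_te"), gene_id, "is_te")
            if "is_te" in df.columns
            else False
        )
        te_family = getattr(row, "te_family", "") if "te_family" in df.columns else ""
        out[gene_id] = GeneAnnotation(gene_id, chrom, go, is_te, te_family)
    return out


def annotation_to_frame(annot: Mapping[str, GeneAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": a.gene_id,
            "chromosome": a.chromosome,
            "go_terms": ";".join(sorted(a.go_terms)),
            "is_te": a.is_te,
            "te_family": a.te_family,
        }
        for a in annot.values()
    ]
    return pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))


def write_annotation(annot: Mapping[str, GeneAnnotation], path: str | Path) -> None:
    annotation_to_frame(annot).to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table (gene_id, sample, replicate, ct_target, ct_reference)."""
    df = _read_tsv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"Ct table {path} missing column(s) {missing}")
    df = df[list(CT_COLUMNS)].copy()
    df["replicate"] = df["replicate"].astype(int)
    for col in ("ct_target", "ct_reference"):
        df[col] = df[col].astype(float)
        bad = ~np.isfinite(df[col]) | (df[col] <= 0)
        if bad.any():
            offender = df.loc[bad, "gene_id"].iloc[0]
            raise ValidationError(f"non-positive {col} for gene {offender!r}")
    unknown = ~df["sample"].isin(LIBRARIES)
    if unknown.any():
        offender = df.loc[unknown, "sample"].iloc[0]
        raise ValidationError(f"unknown sample label {offender!r} in Ct table")
    return df


# -- generic result serialization -----------------------------------------

_BOOL_COLUMNS = {"expressed_P1", "expressed_P2", "expressed_F1", "is_te"}


def write_results(
    records: pd.DataFrame | Iterable, path: str | Path, fmt: str | None = None
) -> None:
    """Write a homogeneous result collection to TSV or JSON-lines.

    ``records`` is either a DataFrame or an iterable of dataclass instances of
    a single type (a mixed iterable raises ``TypeError``).  Column order is the
    frame/dataclass field order, so output is deterministic and round-trips
    losslessly through :func:`read_results`.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records:
            first_type = type(records[0])
            if not dataclasses.is_dataclass(first_type):
                raise TypeError(f"cannot serialize records of type {first_type}")
            if any(type(r) is not first_type for r in records):
                raise TypeError("mixed record types in one result collection")
            cols = [f.name for f in dataclasses.fields(first_type)]
            df = pd.DataFrame(
                [
                    {
                        c: (";".join(sorted(v)) if isinstance(v, frozenset) else v)
                        for c, v in dataclasses.asdict(r).items()
                    }
                    for r in records
                ],
                columns=cols,
            )
        else:
            raise TypeError("cannot infer columns from an empty record list; "
                            "pass an empty DataFrame with columns instead")
    if fmt is None:
        fmt = "jsonl" if str(path).endswith((".jsonl", ".ndjson")) else "tsv"
    if fmt == "jsonl":
        with open(path, "w") as fh:
            for rec in df.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")
    else:
        df.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_results`, restoring basic dtypes."""
    if str(path).endswith((".jsonl", ".ndjson")):
        return pd.read_json(path, lines=True)
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                     na_values=["nan", "NaN"])
    for col in _BOOL_COLUMNS.intersection(df.columns):
        if df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False})
    return df
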