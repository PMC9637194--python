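"""Readers and writers for the on-disk formats of the pipeline.

Coordinate conventions are fixed here once for the whole package:

* All intervals are 0-based, half-open.  A CpG (or CpA) site occupies
  ``[start, start + 2)``, i.e. the two bases of the dinucleotide, which is
  why site identifiers look like ``chr17:80943940-80943942``.
* Chromosome names are ``chr``-prefixed and compared *naturally*
  (``chr2`` sorts before ``chr10``).
* Per-sample methylation lives in a 6-column, tab-separated, bedGraph-like
  table: ``chrom  start  end  ratio  meth_reads  total_reads``.  One file
  per sequence context (``<sample>.cpg.bedgraph`` / ``<sample>.cpa.bedgraph``)
  keeps the column set fixed.
* Every writer emits a single header line prefixed with ``#``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

METH_COLUMNS = ["chrom", "start", "end", "ratio", "meth_reads", "total_reads"]

SHEET_COLUMNS = [
    "sample_id",
    "patient_id",
    "subtype",
    "role",
    "timepoint",
    "matched_normal_id",
    "pdox_of",
    "recurred",
]

ROLES = {"normal_cerebrum", "normal_cerebellum", "primary", "relapse", "pdox"}
SUBTYPES = {"RELA", "PFA"}

#: normal tissue matched to each tumor subtype (supratentorial RELA tumors are
#: referenced to cerebrum, posterior-fossa group A tumors to cerebellum)
NORMAL_TISSUE_FOR_SUBTYPE = {"RELA": "normal_cerebrum", "PFA": "normal_cerebellum"}


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key placing chr2 before chr10 and named contigs (chrX...) last."""
    body = chrom[3:] if chrom.startswith("chr") else chrom
    if body.isdigit():
        return (0, int(body), "")
    return (1, 0, body)


def sort_sites(df: pd.DataFrame) -> pd.DataFrame:
    """Stable (chrom, start) sort with natural chromosome order."""
    return df.sort_values(
        by=["chrom", "start"],
        key=lambda s: s.map(natural_chrom_key) if s.name == "chrom" else s,
        kind="stable",
    ).reset_index(drop=True)


@dataclass(frozen=True)
class SampleMeta:
    """One row of the sample sheet (see :data:`SHEET_COLUMNS`)."""

    sample_id: str
    patient_id: str
    subtype: str
    role: str
    timepoint: int
    matched_normal_id: str = ""
    pdox_of: str = ""
    recurred: bool = False


# ---------------------------------------------------------------------------
# methylation tables
# ---------------------------------------------------------------------------

def read_methylation_table(path: str | Path, context: str = "CpG") -> pd.DataFrame:
    """Read a 6-column bedGraph-like methylation table.

    Returns a frame with :data:`METH_COLUMNS` plus a ``context`` column,
    sorted by (chrom, start) in natural chromosome order.  Malformed rows
    raise :class:`FormatError` naming the first offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=METH_COLUMNS,
            dtype={"chrom": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:  # wrong column count etc.
        raise FormatError(f"{path}: cannot parse 6-column methylation table: {exc}") from exc

    if df.empty:
        out = df.assign(context=pd.Series(dtype=str))
        return out

    for col in ("start", "end", "meth_reads", "total_reads"):
        if not np.issubdtype(df[col].dtype, np.integer):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise FormatError(f"{path}: non-integer {col} at line {line}")

    # line numbers: one '#' header line precedes the data
    lines = df.index.to_numpy() + 2
    bad = df["end"].to_numpy() != df["start"].to_numpy() + 2
    if bad.any():
        raise FormatError(f"{path}: end != start+2 at line {lines[bad][0]}")
    bad = df["meth_reads"].to_numpy() > df["total_reads"].to_numpy()
    if bad.any():
        raise FormatError(f"{path}: meth_reads > total_reads at line {lines[bad][0]}")
    if (df["meth_reads"] < 0).any() or (df["total_reads"] < 0).any():
        raise FormatError(f"{path}: negative read count")
    tot = df["total_reads"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = np.where(tot > 0, df["meth_reads"].to_numpy() / np.maximum(tot, 1), 0.0)
    bad = (tot > 0) & (np.abs(df["ratio"].to_numpy() - expected) > 1e-6)
    if bad.any():
        raise FormatError(f"{path}: ratio inconsistent with counts at line {lines[bad][0]}")

    df = df.assign(context=context)
    df = df.sort_values(
        by=["chrom", "start"],
        key=lambda s: s.map(natural_chrom_key) if s.name == "chrom" else s,
        kind="stable",
    ).reset_index(drop=True)
    return df


def write_methylation_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(METH_COLUMNS) + "\n")
        if len(df):
            out = df[METH_COLUMNS].copy()
            out["ratio"] = out["ratio"].map(lambda r: format(r, ".10g"))
            out.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def validate_sample_sheet(df: pd.DataFrame) -> None:
    """Check cross-references and the subtype/normal-tissue pairing."""
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r}")
    ids = set(df["sample_id"])
    by_id = df.set_index("sample_id")
    for row in df.itertuples(index=False):
        if row.role not in ROLES:
            raise ValidationError(f"{row.sample_id}: unknown role {row.role!r}")
        if row.subtype not in SUBTYPES:
            raise ValidationError(f"{row.sample_id}: unknown subtype {row.subtype!r}")
        if row.role == "relapse" and int(row.timepoint) < 1:
            raise ValidationError(f"{row.sample_id}: relapse with timepoint < 1")
        if row.role == "primary" and int(row.timepoint) != 0:
            raise ValidationError(f"{row.sample_id}: primary must have timepoint 0")
        if row.role == "pdox":
            if not row.pdox_of:
                raise ValidationError(f"{row.sample_id}: pdox sample without pdox_of")
            if row.pdox_of not in ids:
                raise ValidationError(f"{row.sample_id}: pdox_of {row.pdox_of!r} not in sheet")
        if row.role in ("primary", "relapse", "pdox"):
            if not row.matched_normal_id:
                raise ValidationError(f"{row.sample_id}: tumor sample without matched_normal_id")
            if row.matched_normal_id not in ids:
                raise ValidationError(
                    f"{row.sample_id}: matched_normal_id {row.matched_normal_id!r} not in sheet"
                )
            normal_role = by_id.loc[row.matched_normal_id, "role"]
            want = NORMAL_TISSUE_FOR_SUBTYPE[row.subtype]
            if normal_role != want:
                raise ValidationError(
                    f"{row.sample_id}: {row.subtype} sample must be matched to a "
                    f"{want} reference, got {normal_role}"
                )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(
        path,
        comment=None,
        header=None,
        names=SHEET_COLUMNS,
        skiprows=1,
        dtype=str,
        keep_default_na=False,
    )
    with open(path) as fh:
        header = fh.readline().strip().lstrip("#")
    if header.split(",") != SHEET_COLUMNS:
        raise ValidationError(f"{path}: unexpected sample sheet header {header!r}")
    df["timepoint"] = df["timepoint"].astype(int)
    df["recurred"] = df["recurred"].map({"True": True, "False": False, "1": True, "0": False})
    if df["recurred"].isna().any():
        raise ValidationError(f"{path}: recurred column must be boolean")
    validate_sample_sheet(df)
    return df


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + ",".join(SHEET_COLUMNS) + "\n")
        df[SHEET_COLUMNS].to_csv(fh, header=False, index=False)


# ---------------------------------------------------------------------------
# gene annotation (BED6, TSS as a 1-bp feature)
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read BED6 TSS annotation -> frame[gene_id, chrom, tss, strand]."""
    path = Path(path)
    bed = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    if len(bed) and (bed["end"] != bed["start"] + 1).any():
        raise FormatError(f"{path}: TSS features must be 1 bp (end == start+1)")
    if bed["gene_id"].duplicated().any():
        dup = bed.loc[bed["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene_id {dup!r}")
    if len(bed) and not bed["strand"].isin(["+", "-"]).all():
        raise FormatError(f"{path}: strand must be '+' or '-'")
    out = bed.rename(columns={"start": "tss"})[["gene_id", "chrom", "tss", "strand"]]
    return out.reset_index(drop=True)


def write_gene_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        bed = pd.DataFrame(
            {
                "chrom": genes["chrom"],
                "start": genes["tss"],
                "end": genes["tss"] + 1,
                "name": genes["gene_id"],
                "score": 0,
                "strand": genes["strand"],
            }
        )
        bed.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# expression counts and generic tables
# ---------------------------------------------------------------------------

def read_expression_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples integer count matrix (TSV, '#'-prefixed header)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
    df = pd.read_csv(path, sep="\t", skiprows=1, header=None, names=header, index_col=0)
    if (df < 0).any().any():
        raise FormatError(f"{path}: negative counts")
    return df


def write_expression_counts(counts: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\t" + "\t".join(map(str, counts.columns)) + "\n")
        counts.to_csv(fh, sep="\t", header=False)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any result table as TSV with a '#'-prefixed header line."""
    with open(path, "w") as fh:
        cols = (list(df.index.names) if index else []) + list(map(str, df.columns))
        fh.write("#" + "\t".join(str(c) for c in cols) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
    return pd.read_csv(Path(path), sep="\t", skiprows=1, header=None, names=header)
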