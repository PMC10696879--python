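"""Readers and writers for the external formats the pipeline touches.

Conventions: genomic intervals are 0-based half-open (BED) everywhere;
matrices travel as MatrixMarket coordinate files with plain-text sidecars
listing row and column names; tables are TSV/CSV via pandas.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

log = logging.getLogger("hashatac")


@dataclass(frozen=True)
class FragmentRecord:
    """One ATAC fragment: half-open interval plus cell barcode and read count."""

    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"fragment start must be < end, got [{self.start}, {self.end})")
        if self.count < 1:
            raise ValueError(f"fragment count must be >= 1, got {self.count}")


@dataclass
class LabeledMatrix:
    """Sparse matrix with row (cell/peak) and column (feature) names."""

    matrix: sp.spmatrix
    row_names: list
    col_names: list

    def __post_init__(self):
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape[0] != len(self.row_names):
            raise ValueError(
                f"matrix has {self.matrix.shape[0]} rows but "
                f"{len(self.row_names)} row names")
        if self.matrix.shape[1] != len(self.col_names):
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns but "
                f"{len(self.col_names)} column names")

    @property
    def shape(self):
        return self.matrix.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.toarray(), index=self.row_names,
                            columns=self.col_names)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fragments(path, whitelist: set | None = None) -> Iterator[FragmentRecord]:
    """Stream FragmentRecords from a (possibly gzipped) fragments TSV.

    Columns: chrom, start, end, barcode, count[, ...]. Malformed lines raise
    with the offending line number; out-of-whitelist barcodes are dropped and
    their count logged at the end of iteration.
    """
    dropped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 5 tab-separated fields, "
                    f"got {len(parts)}")
            chrom, start_s, end_s, barcode, count_s = parts[:5]
            try:
                start, end, count = int(start_s), int(end_s), int(count_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field: {exc}")
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}")
            if whitelist is not None and barcode not in whitelist:
                dropped += 1
                continue
            yield FragmentRecord(chrom, start, end, barcode, count)
    if dropped:
        log.info("read_fragments: dropped %d out-of-whitelist records", dropped)


def write_fragments(records: Iterable[FragmentRecord], path) -> None:
    with open(path, "wt") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.barcode}\t{r.count}\n")


def _sidecar_paths(path):
    path = Path(path)
    stem = path.with_suffix("")
    return Path(f"{stem}.rownames.txt"), Path(f"{stem}.colnames.txt")


def write_matrix(lm: LabeledMatrix, path) -> None:
    """Write MatrixMarket coordinate file plus row/col name sidecars."""
    path = Path(path)
    scipy.io.mmwrite(str(path), sp.coo_matrix(lm.matrix))
    rows, cols = _sidecar_paths(path)
    rows.write_text("".join(f"{n}\n" for n in lm.row_names))
    cols.write_text("".join(f"{n}\n" for n in lm.col_names))


def read_matrix(path) -> LabeledMatrix:
    """Read a MatrixMarket file and its sidecars; dimensions must agree."""
    path = Path(path)
    mat = sp.csr_matrix(scipy.io.mmread(str(path)))
    rows_p, cols_p = _sidecar_paths(path)
    row_names = rows_p.read_text().splitlines()
    col_names = cols_p.read_text().splitlines()
    if mat.shape[0] != len(row_names):
        raise ValueError(
            f"{path}: matrix has {mat.shape[0]} rows but sidecar lists "
            f"{len(row_names)} names")
    if mat.shape[1] != len(col_names):
        raise ValueError(
            f"{path}: matrix has {mat.shape[1]} columns but sidecar lists "
            f"{len(col_names)} names")
    return LabeledMatrix(mat, row_names, col_names)


SAMPLE_SHEET_COLUMNS = [
    "well", "hash_barcode", "sample", "drug", "dose", "replicate",
    "stimulation",
]


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet CSV mapping hash barcodes to wells/treatments/doses."""
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if df["hash_barcode"].duplicated().any():
        raise ValueError("sample sheet hash barcodes must be unique")
    if (df["dose"] < 0).any():
        raise ValueError("doses must be >= 0")
    df["vehicle"] = df["dose"] == 0
    return df


def read_bed(path) -> pd.DataFrame:
    """BED3(+name) intervals as a DataFrame with half-open coordinates."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs >= 3 columns")
    cols = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, df.shape[1])]
    if df.shape[1] >= 4:
        cols[3] = "name"
    df.columns = cols
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValueError(f"{path}: interval {bad} has start >= end")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in df.columns else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
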