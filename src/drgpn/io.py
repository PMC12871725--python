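"""Readers/writers for the formats the pipeline touches.

10x triplet layout (matrix.mtx[.gz] + features.tsv[.gz] + barcodes.tsv[.gz]),
GMT gene-set files, tab-separated annotation tables.  Matrix Market parsing is
delegated to scipy.io; everything is UTF-8 with LF line endings.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .dataset import CELL_FIELDS, CellDataset
from .errors import FormatError, IntegrityError

log = logging.getLogger(__name__)

MITO_PREFIX = "MT-"  # human mitochondrial gene symbols (case-sensitive)


@dataclass
class GeneSetCollection:
    """Named, ordered gene lists (hallmark-style modules)."""

    sets: Dict[str, List[str]] = field(default_factory=dict)

    def __getitem__(self, name: str) -> List[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> List[str]:
        return list(self.sets)

    def add(self, name: str, genes: List[str]) -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene set name {name!r}")
        deduped = list(dict.fromkeys(genes))
        if not deduped:
            raise FormatError(f"gene set {name!r} is empty")
        self.sets[name] = deduped


def _find(directory: str, stem: str) -> str:
    for suffix in ("", ".gz"):
        path = os.path.join(directory, stem + suffix)
        if os.path.exists(path):
            return path
    raise FormatError(f"missing file {stem}[.gz] in {directory}")


def _read_tsv_column(path: str, column: int = 0) -> List[str]:
    opener = gzip.open if path.endswith(".gz") else open
    rows: List[str] = []
    with opener(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            rows.append(parts[min(column, len(parts) - 1)])
    return rows


def _dedupe_symbols(symbols: List[str]) -> List[str]:
    """Suffix duplicate gene symbols with .1, .2, ... (warns once)."""
    seen: Dict[str, int] = {}
    out = []
    n_dup = 0
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
            n_dup += 1
        else:
            seen[s] = 0
            out.append(s)
    if n_dup:
        log.warning("%d duplicate gene symbols suffixed with .1, .2, ...", n_dup)
    return out


def read_counts_10x(directory: str) -> CellDataset:
    """Read a 10x triplet directory into a :class:`CellDataset`.

    Mitochondrial genes are flagged by the case-sensitive symbol prefix
    ``MT-``.  The log-normalized layer is left absent.
    """
    mtx_path = _find(directory, "matrix.mtx")
    feat_path = _find(directory, "features.tsv")
    bc_path = _find(directory, "barcodes.tsv")
    try:
        mat = scipy.io.mmread(mtx_path)
    except Exception as exc:  # noqa: BLE001 - rewrap with filename
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    # 10x features.tsv: gene_id <tab> gene_symbol <tab> feature_type; use the
    # symbol column when present, else the sole column.
    first = _read_tsv_column(feat_path, 0)
    second = _read_tsv_column(feat_path, 1)
    symbols = second if second != first else first
    barcodes = _read_tsv_column(bc_path, 0)
    if mat.shape[0] != len(symbols):
        raise IntegrityError(
            f"matrix declares {mat.shape[0]} genes but features.tsv has "
            f"{len(symbols)} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise IntegrityError(
            f"matrix declares {mat.shape[1]} cells but barcodes.tsv has "
            f"{len(barcodes)} rows"
        )
    symbols = _dedupe_symbols(symbols)
    genes = pd.DataFrame(
        {"is_mito": [s.startswith(MITO_PREFIX) for s in symbols]},
        index=pd.Index(symbols, name="gene"),
    )
    cells = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return CellDataset(counts=sp.csr_matrix(mat), cells=cells, genes=genes)


def write_counts_10x(ds: CellDataset, directory: str) -> None:
    """Write the counts of a dataset as an uncompressed 10x triplet."""
    os.makedirs(directory, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(directory, "matrix.mtx"), sp.coo_matrix(ds.counts), field="integer"
    )
    with open(os.path.join(directory, "features.tsv"), "w", encoding="utf-8") as fh:
        for s in ds.gene_names:
            fh.write(f"{s}\t{s}\tGene Expression\n")
    with open(os.path.join(directory, "barcodes.tsv"), "w", encoding="utf-8") as fh:
        for b in ds.barcodes:
            fh.write(f"{b}\n")


def read_gene_sets_gmt(path: str) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name <tab> description <tab> genes...``.

    The description column is discarded; within-set duplicate symbols are
    dropped keeping the first occurrence.
    """
    coll = GeneSetCollection()
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(parts)} fields, need >= 3"
                )
            coll.add(parts[0], [g for g in parts[2:] if g])
    return coll


def write_gene_sets_gmt(coll: GeneSetCollection, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in coll.sets.items():
            fh.write(name + "\t-\t" + "\t".join(genes) + "\n")


def read_cells_tsv(path: str) -> pd.DataFrame:
    """Read a per-cell annotation table (TSV with header, barcode column first)."""
    df = pd.read_csv(path, sep="\t", dtype={"donor_id": str})
    if df.columns[0] != "barcode":
        raise FormatError(f"{path}: first column must be 'barcode'")
    df = df.set_index("barcode")
    for col in CELL_FIELDS:
        if col not in df.columns:
            df[col] = pd.NA
    if "nodule_adjacent" in df.columns:
        df["nodule_adjacent"] = df["nodule_adjacent"].astype("boolean")
    return df


def write_cells_tsv(cells: pd.DataFrame, path: str) -> None:
    cells.to_csv(path, sep="\t", index_label="barcode", lineterminator="\n")


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    """Stable TSV writer used by every stage (fixed float format, LF endings)."""
    df.to_csv(
        path, sep="\t", index=index, float_format="%.10g", lineterminator="\n"
    )
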