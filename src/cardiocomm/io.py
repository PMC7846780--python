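"""Readers and writers for all on-disk artifacts.

Two count-matrix dialects are supported:

* **TSV** — genes as rows (first column the gene symbol), cells as
  columns (header row of cell ids).
* **MatrixMarket triplet** — a ``.mtx`` coordinate file (1-based
  indices, per the standard) plus ``genes.tsv`` / ``barcodes.tsv``
  index files with one id per line.

Everything else (annotations, ligand-receptor pairs, cluster labels,
network edge lists) is plain TSV. Indices are converted to 0-based at
this boundary only.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import (
    CellAnnotation,
    CommNetwork,
    CountMatrix,
    FormatError,
    LRPairTable,
)

log = logging.getLogger(__name__)


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} id {x!r}")
        seen.add(x)


def read_count_matrix(
    path,
    format: str = "tsv",
    genes_path=None,
    cells_path=None,
    stage: str = "observed_umi",
    umi_space: Optional[int] = None,
) -> CountMatrix:
    """Read a gene x cell count matrix.

    ``format='tsv'`` reads the genes-in-rows dialect; ``format='mtx_triplet'``
    reads a MatrixMarket coordinate file with companion gene/cell index
    files (required).
    """
    path = Path(path)
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        _check_unique(header[1:], "cell")
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str).rename(None)
        df.columns = df.columns.astype(str)
        _check_unique(df.index, "gene")
    elif format == "mtx_triplet":
        if genes_path is None or cells_path is None:
            raise FormatError("mtx_triplet needs genes_path and cells_path")
        genes = [l.split("\t")[0] for l in Path(genes_path).read_text().splitlines() if l]
        cells = [l.split("\t")[0] for l in Path(cells_path).read_text().splitlines() if l]
        _check_unique(genes, "gene")
        _check_unique(cells, "cell")
        _validate_mtx_indices(path, len(genes), len(cells))
        mat = scipy.io.mmread(str(path))
        mat = scipy.sparse.coo_matrix(mat)
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix shape {mat.shape} does not match index files "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        df = pd.DataFrame(mat.toarray(), index=genes, columns=cells)
    else:
        raise FormatError(f"unknown count-matrix format {format!r}")
    arr = df.to_numpy()
    if arr.size and np.nanmin(arr) < 0:
        g, c = np.argwhere(arr < 0)[0]
        raise FormatError(f"negative value at gene {df.index[g]!r}, cell {df.columns[c]!r}")
    return CountMatrix(values=df, stage=stage, umi_space=umi_space)


def _validate_mtx_indices(path, n_genes: int, n_cells: int) -> None:
    """MatrixMarket coordinate indices are 1-based; 0 is a format error."""
    with open(path) as fh:
        first = True
        for line in fh:
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            if first:  # size line
                first = False
                continue
            parts = line.split()
            i, j = int(parts[0]), int(parts[1])
            if i < 1 or j < 1:
                raise FormatError(
                    f"MatrixMarket indices are 1-based; found entry ({i}, {j})"
                )
            if i > n_genes or j > n_cells:
                raise FormatError(f"MatrixMarket entry ({i}, {j}) out of range")


def write_count_matrix(matrix: CountMatrix, path, format: str = "tsv",
                       genes_path=None, cells_path=None) -> None:
    """Write a count matrix in either supported dialect."""
    path = Path(path)
    if format == "tsv":
        df = matrix.values
        if matrix.stage in ("observed_umi", "downsampled"):
            df = df.astype(np.int64)
        df.to_csv(path, sep="\t", index_label="gene")
    elif format == "mtx_triplet":
        if genes_path is None or cells_path is None:
            raise FormatError("mtx_triplet needs genes_path and cells_path")
        arr = matrix.values.to_numpy()
        sp = scipy.sparse.coo_matrix(arr)
        field = "integer" if matrix.stage in ("observed_umi", "downsampled") else "real"
        if field == "integer":
            sp = sp.astype(np.int64)
        scipy.io.mmwrite(str(path), sp, field=field)
        Path(genes_path).write_text("".join(f"{g}\n" for g in matrix.gene_ids))
        Path(cells_path).write_text("".join(f"{c}\n" for c in matrix.cell_ids))
    else:
        raise FormatError(f"unknown count-matrix format {format!r}")


def read_lr_pairs(path) -> LRPairTable:
    """Read a two-column ligand/receptor TSV; duplicates are logged and dropped."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[:2] != ["ligand", "receptor"] or len(header) < 2:
        raise FormatError(
            "ligand-receptor table must start with a 'ligand<TAB>receptor' header"
        )
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("ligand-receptor table needs two columns")
    df = df[["ligand", "receptor"]]
    dup = df.duplicated()
    if dup.any():
        for _, row in df[dup].iterrows():
            log.info("dropping duplicate ligand-receptor row (%s, %s)",
                     row["ligand"], row["receptor"])
        df = df[~dup]
    return LRPairTable(df.reset_index(drop=True))


def write_lr_pairs(table: LRPairTable, path) -> None:
    table.pairs.to_csv(path, sep="\t", index=False)


def read_annotation(path, condition_vocab=None) -> CellAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    kwargs = {} if condition_vocab is None else {"condition_vocab": tuple(condition_vocab)}
    return CellAnnotation(df, **kwargs)


def write_annotation(annotation: CellAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="cell_id")


def write_network(network: CommNetwork, path, summary_path=None) -> None:
    """Write a network as an edge list TSV plus a couple-count summary TSV.

    The edge list has one row per supporting ligand-receptor couple
    (source_type, target_type, ligand, receptor); the summary carries
    the couple count per directed type pair.
    """
    network.couples_frame().to_csv(path, sep="\t", index=False)
    if summary_path is not None:
        network.couple_counts().to_csv(summary_path, sep="\t", index=False)


def read_network(path, condition=None) -> CommNetwork:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = ["source_type", "target_type", "ligand", "receptor"]
    if list(df.columns[:4]) != need:
        raise FormatError(f"network edge list must have columns {need}")
    edges: dict = {}
    for _, row in df.iterrows():
        edges.setdefault((row["source_type"], row["target_type"]), set()).add(
            (row["ligand"], row["receptor"])
        )
    return CommNetwork(condition=condition, edges=edges)


def write_cluster_labels(result, path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False)


def write_cluster_report(result, path) -> None:
    mean, sd = result.intercluster_distance_mean_sd
    rows = [
        {"cluster": c, "jaccard": j, "k": result.k, "robust": result.robust,
         "intercluster_mean": mean, "intercluster_sd": sd}
        for c, j in sorted(result.jaccard.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
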