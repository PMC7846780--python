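"""Core in-memory containers shared across the pipeline.

The pipeline passes a gene x cell count matrix through three stages:

``observed_umi``
    distinct-UMI counts straight out of quantification; integer,
    bounded above by the UMI-space size K.
``downsampled``
    integer counts after per-cell downsampling to a fixed transcript
    total.
``expected``
    real-valued expected molecule counts after Poisson collision
    correction.

All containers are thin dataclasses around :class:`pandas.DataFrame`
with the invariants checked at construction time, so downstream code can
rely on them without re-validating.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """An on-disk artifact violates its declared format."""


class ContractError(ValueError):
    """An in-memory value violates an operation's precondition."""


STAGES = ("observed_umi", "downsampled", "expected")
INTEGER_STAGES = ("observed_umi", "downsampled")

#: Condition labels of the ischemia-reperfusion time course: days post
#: IR or sham surgery at which hearts were collected.
DEFAULT_CONDITIONS = ("1dpSham", "1dpIR", "3dpIR", "14dpSham", "14dpIR")

#: The main cardiac cell types: cardiomyocytes, fibroblasts,
#: macrophages, neutrophils, endothelial cells.
CELL_TYPES = ("CM", "FB", "MP", "NP", "EC", "other")


@dataclass
class CountMatrix:
    """Gene x cell matrix of non-negative counts with a stage tag.

    Parameters
    ----------
    values
        DataFrame with gene symbols as index and cell ids as columns.
    stage
        One of ``observed_umi``, ``downsampled``, ``expected``.
    umi_space
        UMI-space size K; when given and stage is ``observed_umi``,
        every entry must be <= K.
    """

    values: pd.DataFrame
    stage: str
    umi_space: Optional[int] = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ContractError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate cell id {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and np.nanmin(arr) < 0:
            g, c = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {idx[g]!r}, cell {cols[c]!r}"
            )
        if self.stage in INTEGER_STAGES and arr.size:
            if not np.allclose(arr, np.rint(arr), atol=1e-9):
                raise ContractError(f"stage {self.stage!r} requires integer counts")
        if self.stage == "observed_umi" and self.umi_space is not None and arr.size:
            if arr.max() > self.umi_space:
                raise ContractError(
                    f"observed UMI count {arr.max()} exceeds UMI-space size {self.umi_space}"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        return replace(self, values=self.values.loc[list(genes)])

    def subset_cells(self, cells: Sequence[str]) -> "CountMatrix":
        return replace(self, values=self.values[list(cells)])

    def with_values(self, values: pd.DataFrame, stage: Optional[str] = None) -> "CountMatrix":
        return CountMatrix(values=values, stage=stage or self.stage, umi_space=self.umi_space)


@dataclass
class CellAnnotation:
    """Per-cell metadata: condition, optional cell type and cluster id.

    ``table`` is indexed by cell id with columns ``condition`` and
    optionally ``cell_type`` and ``cluster``.
    """

    table: pd.DataFrame
    condition_vocab: tuple = DEFAULT_CONDITIONS

    def __post_init__(self) -> None:
        if "condition" not in self.table.columns:
            raise FormatError("annotation table needs a 'condition' column")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"duplicate cell id {dup!r} in annotation")
        bad = set(self.table["condition"]) - set(self.condition_vocab)
        if bad:
            raise FormatError(
                f"condition labels {sorted(bad)} not in declared vocabulary {self.condition_vocab}"
            )
        if "cluster" in self.table.columns:
            cl = self.table["cluster"].dropna()
            if len(cl) and (cl < 1).any():
                raise ContractError("cluster ids must be >= 1")

    @property
    def cell_ids(self) -> pd.Index:
        return self.table.index

    @property
    def condition(self) -> pd.Series:
        return self.table["condition"]

    @property
    def cell_type(self) -> Optional[pd.Series]:
        return self.table["cell_type"] if "cell_type" in self.table.columns else None

    def validate_against(self, matrix: CountMatrix) -> None:
        """Every annotated cell must exist in the paired count matrix."""
        missing = self.table.index.difference(matrix.cell_ids)
        if len(missing):
            raise ContractError(
                f"annotation cell(s) {list(missing[:3])} absent from count matrix"
            )

    def subset(self, cells: Sequence[str]) -> "CellAnnotation":
        return CellAnnotation(self.table.loc[list(cells)], self.condition_vocab)


@dataclass
class LRPairTable:
    """Directed ligand -> receptor gene pairs."""

    pairs: pd.DataFrame  # columns: ligand, receptor

    def __post_init__(self) -> None:
        need = {"ligand", "receptor"}
        if not need.issubset(self.pairs.columns):
            raise FormatError("pair table needs 'ligand' and 'receptor' columns")
        self.pairs = self.pairs[["ligand", "receptor"]].reset_index(drop=True)
        if self.pairs.duplicated().any():
            raise ContractError("duplicate (ligand, receptor) rows")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def ligands(self) -> pd.Index:
        return pd.Index(self.pairs["ligand"].unique())

    @property
    def receptors(self) -> pd.Index:
        return pd.Index(self.pairs["receptor"].unique())

    def receptors_for(self, ligand: str) -> list:
        return self.pairs.loc[self.pairs["ligand"] == ligand, "receptor"].tolist()

    def as_tuples(self) -> list:
        return list(self.pairs.itertuples(index=False, name=None))


@dataclass
class ClusterResult:
    """Outcome of robust k-medoids clustering.

    ``labels`` maps cell id -> cluster id in 1..k; ``jaccard`` maps
    cluster id -> mean bootstrap Jaccard coefficient; ``robust`` is true
    when at most one cluster has Jaccard <= the configured threshold.
    """

    labels: pd.Series
    medoid_cell_ids: list
    k: int
    jaccard: Mapping[int, float]
    robust: bool
    intercluster_distance_mean_sd: tuple

    def __post_init__(self) -> None:
        present = set(self.labels.unique())
        if present != set(range(1, self.k + 1)):
            raise ContractError(f"labels must cover 1..{self.k}, got {sorted(present)}")
        for cid, medoid in zip(range(1, self.k + 1), self.medoid_cell_ids):
            if self.labels[medoid] != cid:
                raise ContractError(f"medoid {medoid!r} is not a member of cluster {cid}")

    def members(self, cluster: int) -> pd.Index:
        return self.labels.index[self.labels == cluster]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.labels.index, "cluster": self.labels.values})


@dataclass
class CommNetwork:
    """Directed cell-type communication network.

    Each edge (source_type, target_type) carries the set of ligand ->
    receptor couples supporting it: the ligand is expressed by the
    source type and the receptor by the target type. Autocrine loops
    (source == target) are allowed. An edge exists iff its couple set is
    non-empty.
    """

    condition: Optional[str]
    edges: dict = field(default_factory=dict)  # (src, tgt) -> set[(ligand, receptor)]

    def __post_init__(self) -> None:
        for key, couples in self.edges.items():
            if not couples:
                raise ContractError(f"edge {key} has an empty couple set")
            self.edges[key] = set(couples)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def total_couples(self) -> int:
        return sum(len(c) for c in self.edges.values())

    def couple_counts(self) -> pd.DataFrame:
        """Couple count per directed type pair (link-strength summary)."""
        rows = [
            {"source_type": s, "target_type": t, "n_couples": len(c)}
            for (s, t), c in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["source_type", "target_type", "n_couples"])

    def couples_frame(self) -> pd.DataFrame:
        rows = [
            {"source_type": s, "target_type": t, "ligand": l, "receptor": r}
            for (s, t), couples in sorted(self.edges.items())
            for (l, r) in sorted(couples)
        ]
        return pd.DataFrame(rows, columns=["source_type", "target_type", "ligand", "receptor"])

    def to_networkx(self):
        """Directed multigraph view (one edge attribute holds the couples)."""
        import networkx as nx

        g = nx.DiGraph()
        for (s, t), couples in self.edges.items():
            g.add_edge(s, t, couples=sorted(couples), weight=len(couples))
        return g
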