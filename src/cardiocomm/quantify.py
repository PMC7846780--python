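"""From observed distinct-UMI counts to a filtered expression matrix.

A SORT-seq library tags each captured molecule with one of K = 4096
random UMIs, so two molecules of the same gene can collide on the same
barcode and be counted once. If n molecules are thrown uniformly into K
slots, the expected number of occupied slots is K(1 - (1 - 1/K)^n) ~
K(1 - e^(-n/K)); inverting that occupancy relation converts an observed
distinct-UMI count k into the expected molecule count

    n_hat = -K * ln(1 - k/K).

The full quantification pipeline is: remove mitochondrial/blacklisted
genes, downsample every cell to a common transcript total (discarding
cells below it), filter genes by minimum expression, then apply the
collision correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import RunConfig
from .types import ContractError, CountMatrix

log = logging.getLogger(__name__)

ArrayLike = Union[float, int, np.ndarray]


@dataclass
class FilterReport:
    """Ledger of what the pipeline removed and why."""

    cells_discarded: list = field(default_factory=list)  # (cell_id, reason)
    genes_removed: list = field(default_factory=list)  # (gene, reason)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"id": c, "kind": "cell", "reason": r} for c, r in self.cells_discarded]
        rows += [{"id": g, "kind": "gene", "reason": r} for g, r in self.genes_removed]
        return pd.DataFrame(rows, columns=["id", "kind", "reason"])

    def merge(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            self.cells_discarded + other.cells_discarded,
            self.genes_removed + other.genes_removed,
        )


def correct_umi_count(k_observed: ArrayLike, K: int, clamp_saturated: bool = False) -> ArrayLike:
    """Expected molecule count from an observed distinct-UMI count.

    Parameters
    ----------
    k_observed
        Distinct-UMI count(s), 0 <= k <= K.
    K
        UMI-space size.
    clamp_saturated
        A fully saturated gene (k = K) has no finite inverse; by default
        that raises, with ``clamp_saturated=True`` it is treated as K-1.

    Returns
    -------
    -K * ln(1 - k/K), elementwise; 0 maps to 0 and the result always
    weakly exceeds the input (collisions only ever hide molecules).
    """
    k = np.asarray(k_observed, dtype=float)
    if K < 2:
        raise ContractError("K must be >= 2")
    if k.size and (np.nanmin(k) < 0 or np.nanmax(k) > K):
        raise ContractError(f"observed counts must lie in [0, {K}]")
    if np.any(k == K):
        if not clamp_saturated:
            raise ContractError(
                f"observed count equals UMI-space size K={K} (saturated); "
                "pass clamp_saturated=True to clamp to K-1"
            )
        k = np.where(k == K, K - 1, k)
    out = -K * np.log1p(-k / K)
    if np.isscalar(k_observed) or np.ndim(k_observed) == 0:
        return float(out)
    return out


def remove_blacklisted_genes(
    m: CountMatrix,
    mito_prefix: str = "mt-",
    blacklist: Sequence[str] = ("Rn45s",),
) -> Tuple[CountMatrix, FilterReport]:
    """Drop mitochondrial genes (by case-sensitive symbol prefix) and
    explicitly blacklisted genes; all other rows pass through unchanged.

    Mitochondrial transcripts dominate cardiomyocyte libraries and
    interfere with clustering; Rn45s detection is a library-prep
    artefact.
    """
    report = FilterReport()
    keep = []
    blacklist = set(blacklist)
    for g in m.gene_ids:
        if g.startswith(mito_prefix):
            report.genes_removed.append((g, "mitochondrial"))
        elif g in blacklist:
            report.genes_removed.append((g, "blacklist"))
        else:
            keep.append(g)
    return m.subset_genes(keep), report


def downsample_cell(
    counts: np.ndarray, T: int, rng: np.random.Generator
) -> Optional[np.ndarray]:
    """Downsample one cell's transcripts to exactly T without replacement.

    Returns ``None`` (discard) when the cell has fewer than T
    transcripts. Sampling is uniform over the multiset of transcripts,
    so the marginal count of each gene is multivariate hypergeometric.
    """
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.rint(counts), atol=1e-9):
            raise ContractError("downsampling requires integer counts")
        counts = np.rint(counts).astype(np.int64)
    total = int(counts.sum())
    if total < T:
        return None
    if total == T:
        return counts.astype(np.int64)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), T, method="count")


def downsample_matrix(
    m: CountMatrix, T: int, rng: np.random.Generator
) -> Tuple[CountMatrix, FilterReport]:
    """Downsample every cell; cells below T transcripts are discarded."""
    report = FilterReport()
    cols = {}
    arr = m.values.to_numpy()
    if not np.allclose(arr, np.rint(arr), atol=1e-9):
        raise ContractError("downsampling requires integer counts")
    arr = np.rint(arr).astype(np.int64)
    for j, cell in enumerate(m.cell_ids):
        v = downsample_cell(arr[:, j], T, rng)
        if v is None:
            report.cells_discarded.append((cell, f"fewer than {T} transcripts"))
        else:
            cols[cell] = v
    if cols:
        df = pd.DataFrame(cols, index=m.gene_ids)
    else:
        df = pd.DataFrame(index=m.gene_ids)
    return CountMatrix(df, stage="downsampled", umi_space=m.umi_space), report


def filter_genes(
    m: CountMatrix, min_expr: int = 3, min_number: int = 1
) -> Tuple[CountMatrix, FilterReport]:
    """Keep genes with a count of at least ``min_expr`` in at least
    ``min_number`` cells (the ``min.expr`` / ``min.number`` rule).
    Idempotent by construction."""
    report = FilterReport()
    if m.n_cells == 0:
        return m, report
    ok = (m.values.to_numpy() >= min_expr).sum(axis=1) >= min_number
    for g in m.gene_ids[~ok]:
        report.genes_removed.append((g, "low_expression"))
    return m.subset_genes(list(m.gene_ids[ok])), report


def quantify_pipeline(
    m: CountMatrix,
    cfg: RunConfig,
    order: str = "downsample_first",
) -> Tuple[CountMatrix, FilterReport]:
    """Full quantification: blacklist removal, per-cell downsampling,
    gene filtering and Poisson collision correction.

    ``order='downsample_first'`` (default) downsamples the observed
    integer UMI counts and corrects the downsampled counts;
    ``order='correct_first'`` corrects the observed counts, rounds, and
    downsamples the rounded expectations. Deterministic given
    ``cfg.seed``.
    """
    if m.stage != "observed_umi":
        raise ContractError("quantify_pipeline expects an observed_umi matrix")
    if order not in ("downsample_first", "correct_first"):
        raise ContractError(f"unknown order {order!r}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))

    work, report = remove_blacklisted_genes(m, cfg.mito_prefix, cfg.blacklist_genes)

    if order == "correct_first":
        corrected = correct_umi_count(work.values.to_numpy(), cfg.K)
        work = work.with_values(
            pd.DataFrame(np.rint(corrected), index=work.gene_ids, columns=work.cell_ids),
            stage="downsampled",  # integer again after rounding
        )

    draws = []
    down = None
    for rep in range(cfg.downsample_reps):
        down, rep_report = downsample_matrix(work, cfg.T, rng)
        if rep == 0:
            report = report.merge(rep_report)
        draws.append(down)
    down = draws[0]

    filtered, gene_report = filter_genes(down, cfg.min_expr, cfg.min_number)
    report = report.merge(gene_report)
    kept_genes = list(filtered.gene_ids)
    kept_cells = list(filtered.cell_ids)

    if order == "downsample_first":
        mats = [
            correct_umi_count(d.values.loc[kept_genes, kept_cells].to_numpy(), cfg.K)
            for d in draws
        ]
        expected = np.mean(mats, axis=0)
    else:
        expected = np.mean(
            [d.values.loc[kept_genes, kept_cells].to_numpy() for d in draws], axis=0
        )
    out = CountMatrix(
        pd.DataFrame(expected, index=kept_genes, columns=kept_cells),
        stage="expected",
        umi_space=m.umi_space,
    )
    return out, report
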