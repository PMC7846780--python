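"""Cluster marker enrichment and condition fold changes.

Marker enrichment follows the binomial counting logic of RaceID-style
``clustdiffgenes``: for a gene g and a cluster C, the background
probability p_bg is g's share of all transcripts outside C; inside C,
with N total transcripts, the observed count x is compared to
Binomial(N, p_bg) and the one-sided upper-tail P(X >= x) is the
enrichment p-value. Benjamini-Hochberg q-values control the FDR across
genes.

Condition fold changes use median-of-ratios size factors (the DESeq
normalization) and a pseudocounted ratio of normalized group means; the
ligand screen consumes only the fold-change threshold.
"""

from __future__ import annotations

import logging
from typing import Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .types import ContractError, CountMatrix

log = logging.getLogger(__name__)


def _as_frame(expr) -> pd.DataFrame:
    return expr.values if isinstance(expr, CountMatrix) else expr


def cluster_enrichment(
    expr, labels: pd.Series, cluster: int
) -> pd.DataFrame:
    """Binomial enrichment of every gene in one cluster vs the rest.

    Parameters
    ----------
    expr
        Genes x cells matrix (downsampled or expected counts; totals
        are rounded to the nearest integer for the binomial model).
    labels
        Cell id -> cluster id.
    cluster
        The cluster to test; the background is all cells *not* in it.

    Returns
    -------
    DataFrame with columns gene, cluster, count_in, expected_in, fold,
    p_value, q_value, sorted by p ascending then fold descending.
    """
    df = _as_frame(expr)
    labels = labels.loc[df.columns]
    in_mask = (labels == cluster).to_numpy()
    if not in_mask.any():
        raise ContractError(f"cluster {cluster} has no cells")
    if in_mask.all():
        raise ContractError("background (cells not in cluster) is empty")

    arr = df.to_numpy(dtype=float)
    x = arr[:, in_mask].sum(axis=1)
    bg = arr[:, ~in_mask].sum(axis=1)
    N = int(np.rint(x.sum()))
    total_bg = bg.sum()
    p_floor = 1.0 / (total_bg + 1.0)  # avoids zero-probability degeneracy
    p_bg = np.maximum(bg / total_bg, p_floor) if total_bg > 0 else np.full(len(bg), p_floor)

    x_int = np.rint(x).astype(np.int64)
    # upper tail P(X >= x) under Binomial(N, p_bg); x = 0 gives p = 1
    p_value = stats.binom.sf(x_int - 1, N, p_bg)
    expected_in = N * p_bg
    fold = x / expected_in

    q_value = np.ones_like(p_value)
    if len(p_value):
        q_value = stats.false_discovery_control(np.clip(p_value, 0, 1), method="bh")

    out = pd.DataFrame(
        {
            "gene": df.index,
            "cluster": cluster,
            "count_in": x,
            "expected_in": expected_in,
            "fold": fold,
            "p_value": p_value,
            "q_value": q_value,
        }
    )
    return out.sort_values(
        ["p_value", "fold"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)


def size_factors(df: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Each cell's factor is the median, over genes whose gene-wise
    geometric mean across all cells is nonzero, of the cell's count to
    that geometric mean. Falls back to total-count factors (scaled to
    mean 1) when no gene is expressed in every cell, with a log entry.
    """
    arr = df.to_numpy(dtype=float)
    log_arr = np.full_like(arr, -np.inf)
    np.log(arr, out=log_arr, where=arr > 0)
    all_pos = (arr > 0).all(axis=1)
    if all_pos.any():
        log_geo = log_arr[all_pos].mean(axis=1)
        ratios = arr[all_pos] / np.exp(log_geo)[:, None]
        sf = np.median(ratios, axis=0)
    else:
        log.warning("no gene expressed in every cell; using total-count size factors")
        totals = arr.sum(axis=0)
        sf = totals / totals.mean()
    if np.any(sf <= 0):
        raise ContractError("non-positive size factor (cell with no counts?)")
    return pd.Series(sf, index=df.columns)


def condition_fold_change(
    expr,
    groups: Tuple[Sequence[str], Sequence[str]],
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Fold change of normalized group means, B over A.

    ``groups = (A_cells, B_cells)``; for the cardiomyocyte ligand
    screen A is 1 dp sham and B is 1 dp IR. Size factors are estimated
    on the union of both groups, so uniformly scaling one group's
    libraries leaves every fold change unchanged.

    Returns a DataFrame with columns gene, mean_A, mean_B, fold_change
    where fold_change = (mean_B + c) / (mean_A + c).
    """
    if pseudocount <= 0:
        raise ContractError("pseudocount must be positive")
    df = _as_frame(expr)
    a_cells, b_cells = list(groups[0]), list(groups[1])
    if not a_cells or not b_cells:
        raise ContractError("both groups must be non-empty")
    sub = df[a_cells + b_cells]
    sf = size_factors(sub)
    norm = sub / sf
    mean_a = norm[a_cells].mean(axis=1)
    mean_b = norm[b_cells].mean(axis=1)
    fold = (mean_b + pseudocount) / (mean_a + pseudocount)
    return pd.DataFrame(
        {"gene": df.index, "mean_A": mean_a.values, "mean_B": mean_b.values,
         "fold_change": fold.values}
    )
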