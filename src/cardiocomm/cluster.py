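"""Robust k-medoids clustering of cells on 1 - Pearson distances.

The clustering strategy mirrors RaceID2-style practice:

1. cell-cell distance = 1 - Pearson correlation of expression vectors;
2. PAM (partitioning around medoids, BUILD + SWAP) at a given k;
3. the initial k is chosen where the within-cluster dispersion W(k)
   saturates (relative decrease below epsilon);
4. cluster stability is scored by the mean Jaccard coefficient between
   each cluster and its best match across bootstrap reclusterings; a
   partition is *robust* when at most one cluster scores at or below
   the threshold (default 0.6), and k is decremented one step at a
   time until robustness is reached.
"""

from __future__ import annotations

import itertools
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import RunConfig
from .types import CellAnnotation, ClusterResult, ContractError, CountMatrix


def pearson_distance(expr) -> Tuple[np.ndarray, pd.Index]:
    """1 - Pearson correlation between cell gene-expression vectors.

    Accepts a :class:`CountMatrix` or a genes x cells DataFrame.
    Returns the symmetric distance matrix (zero diagonal, values in
    [0, 2]) and the cell ids in matrix order.
    """
    df = expr.values if isinstance(expr, CountMatrix) else expr
    arr = np.asarray(df.to_numpy(), dtype=float)
    if arr.shape[0] < 2:
        raise ContractError("need at least 2 genes to correlate cells")
    sd = arr.std(axis=0)
    if np.any(sd == 0):
        bad = df.columns[int(np.argmax(sd == 0))]
        raise ContractError(f"cell {bad!r} has zero-variance expression vector")
    r = np.corrcoef(arr, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return d, pd.Index(df.columns)


def _assign(d: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    """Nearest-medoid assignment; ties go to the lower medoid index."""
    return np.argmin(d[:, medoids], axis=1)


def _pam_build(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=0)))]
    dist_near = d[:, medoids[0]].copy()
    for _ in range(1, k):
        # gain of adding each candidate: total reduction in nearest distance
        gain = np.maximum(dist_near[:, None] - d, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        c = int(np.argmax(gain))
        medoids.append(c)
        dist_near = np.minimum(dist_near, d[:, c])
    return np.array(sorted(medoids))


def _pam_swap(d: np.ndarray, medoids: np.ndarray, max_iter: int = 200) -> np.ndarray:
    n = d.shape[0]
    medoids = medoids.copy()
    tol = 1e-12
    for _ in range(max_iter):
        sub = d[:, medoids]
        order = np.argsort(sub, axis=1, kind="stable")
        nearest = order[:, 0]
        d1 = sub[np.arange(n), nearest]
        d2 = sub[np.arange(n), order[:, 1]] if len(medoids) > 1 else np.full(n, np.inf)
        cost = d1.sum()
        best_delta, best_swap = -tol, None
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        for mi in range(len(medoids)):
            base = np.where(nearest == mi, d2, d1)
            # candidate cost after swapping medoid mi for each non-medoid o
            new_costs = np.minimum(base[:, None], d[:, non_medoids]).sum(axis=0)
            deltas = new_costs - cost
            oi = int(np.argmin(deltas))
            if deltas[oi] < best_delta:
                best_delta, best_swap = float(deltas[oi]), (mi, int(non_medoids[oi]))
        if best_swap is None:
            break
        mi, o = best_swap
        medoids[mi] = o
        medoids = np.array(sorted(medoids))
    return medoids


def kmedoids(
    d: np.ndarray, k: int, seed: Optional[int] = None, n_restarts: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """PAM clustering of a precomputed distance matrix.

    BUILD initialization followed by SWAP until no single medoid swap
    lowers the total within-cluster distance-to-medoid. Deterministic;
    ``seed`` is used only for the optional random restarts, whose best
    solution (by cost, ties to the deterministic run) is returned.

    Returns
    -------
    labels : 0-based cluster index per cell (cluster order follows the
        sorted medoid indices)
    medoids : sorted medoid indices
    """
    n = d.shape[0]
    if d.shape[0] != d.shape[1]:
        raise ContractError("distance matrix must be square")
    if not 1 <= k <= n:
        raise ContractError(f"k={k} outside [1, {n}]")
    if k == n:
        return np.arange(n), np.arange(n)

    def run(init: np.ndarray) -> Tuple[float, np.ndarray]:
        med = _pam_swap(d, init)
        cost = d[:, med][np.arange(n), _assign(d, med)].sum()
        return float(cost), med

    best_cost, best_med = run(_pam_build(d, k))
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            init = np.sort(rng.choice(n, size=k, replace=False))
            cost, med = run(init)
            if cost < best_cost - 1e-12:
                best_cost, best_med = cost, med
    return _assign(d, best_med), best_med


def _dispersion(d: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Mean within-cluster dispersion: the mean over all intra-cluster
    cell pairs of their distance (clusters pooled pair-weighted;
    singleton clusters contribute no pairs). At k = 1 this is the
    plain mean pairwise distance."""
    num = 0.0
    cnt = 0
    for c in range(k):
        idx = np.flatnonzero(labels == c)
        if len(idx) >= 2:
            num += d[np.ix_(idx, idx)].sum()
            cnt += len(idx) * (len(idx) - 1)
    return num / cnt if cnt else 0.0


def dispersion_sweep(
    d: np.ndarray,
    k_max: int = 20,
    seed: Optional[int] = None,
    n_restarts: int = 0,
) -> list:
    """W(k) for k = 1..k_max.

    W(1) is the mean pairwise distance; for k >= 2, W(k) pools the
    intra-cluster pairs of the PAM partition. Splitting removes the
    longest (cross-cluster) pairs from the pool, so the sweep decreases
    while genuine structure remains and flattens once clusters are
    internally homogeneous.
    """
    n = d.shape[0]
    k_max = min(k_max, n)
    out = [_dispersion(d, np.zeros(n, dtype=int), 1)]
    for k in range(2, k_max + 1):
        labels, _ = kmedoids(d, k, seed=seed, n_restarts=n_restarts)
        out.append(_dispersion(d, labels, k))
    return out


def choose_k_by_dispersion(
    d: np.ndarray,
    k_max: int = 20,
    epsilon: float = 0.05,
    seed: Optional[int] = None,
    n_restarts: int = 0,
) -> int:
    """Smallest k at which the within-cluster dispersion saturates.

    Returns the smallest k with (W(k) - W(k+1)) / W(k) < epsilon: the
    first k past which adding a cluster buys less than an epsilon
    relative reduction in within-cluster dispersion.
    """
    n = d.shape[0]
    k_max = min(k_max, n - 1)
    if k_max < 1:
        return 1
    w_prev = _dispersion(d, np.zeros(n, dtype=int), 1)
    for k in range(1, k_max + 1):
        labels, _ = kmedoids(d, k + 1, seed=seed, n_restarts=n_restarts)
        w_next = _dispersion(d, labels, k + 1)
        if w_prev <= 0 or (w_prev - w_next) / w_prev < epsilon:
            return k
        w_prev = w_next
    return k_max


def bootstrap_jaccard(
    d: np.ndarray,
    labels: np.ndarray,
    B: int = 50,
    seed: Optional[int] = None,
    k: Optional[int] = None,
    n_restarts: int = 0,
) -> Dict[int, float]:
    """Mean bootstrap Jaccard stability per cluster (0-based keys).

    Each of B resamples draws cells with replacement, reclusters the
    resample with PAM at the same k, and scores every original cluster
    by its best Jaccard overlap with a bootstrap cluster, computed over
    the distinct cells of the resample. Clusters with no member in a
    resample are skipped for that resample.
    """
    if B < 1:
        raise ContractError("B must be >= 1")
    n = d.shape[0]
    k = k if k is not None else int(labels.max()) + 1
    if k == 1:
        return {0: 1.0}
    rng = np.random.default_rng(seed)
    sums = np.zeros(k)
    counts = np.zeros(k)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        distinct = np.unique(idx)
        sub = d[np.ix_(idx, idx)]
        boot_labels, _ = kmedoids(
            sub,
            min(k, len(distinct)),
            seed=int(rng.integers(2**31)),
            n_restarts=n_restarts,
        )
        # label per distinct cell (duplicated rows are identical, PAM's
        # deterministic tie-break assigns them alike)
        first_pos = {}
        for pos, cell in enumerate(idx):
            first_pos.setdefault(int(cell), pos)
        boot_of = {cell: int(boot_labels[pos]) for cell, pos in first_pos.items()}
        boot_sets: Dict[int, set] = {}
        for cell, bl in boot_of.items():
            boot_sets.setdefault(bl, set()).add(cell)
        distinct_set = set(int(c) for c in distinct)
        for c in range(k):
            orig = set(np.flatnonzero(labels == c)) & distinct_set
            if not orig:
                continue
            best = max(
                (len(orig & bs) / len(orig | bs) for bs in boot_sets.values()),
                default=0.0,
            )
            sums[c] += best
            counts[c] += 1
    return {c: (sums[c] / counts[c] if counts[c] else 0.0) for c in range(k)}


def robust_cluster(
    d: np.ndarray, cfg: RunConfig, cell_ids: Sequence[str]
) -> ClusterResult:
    """Iterative k-medoids with bootstrap robustness.

    Starts at the dispersion-saturation k and, while more than one
    cluster has mean Jaccard at or below ``cfg.jaccard_threshold``,
    reduces k in steps of one. Stops at k = 2 regardless, reporting the
    robustness flag honestly.
    """
    cell_ids = pd.Index(cell_ids)
    n = d.shape[0]
    if len(cell_ids) != n:
        raise ContractError("cell_ids length must match the distance matrix")
    k0 = choose_k_by_dispersion(
        d, cfg.k_max, cfg.dispersion_epsilon, seed=cfg.seed, n_restarts=cfg.pam_restarts
    )
    seed_seq = np.random.SeedSequence([cfg.seed, 202])
    boot_seed = int(seed_seq.generate_state(1)[0] % (2**31))

    k = max(k0, 1)
    if k == 1:
        medoid = int(np.argmin(d.sum(axis=0)))
        labels = pd.Series(np.ones(n, dtype=int), index=cell_ids)
        return ClusterResult(
            labels=labels,
            medoid_cell_ids=[cell_ids[medoid]],
            k=1,
            jaccard={1: 1.0},
            robust=True,
            intercluster_distance_mean_sd=(float("nan"), float("nan")),
        )

    while True:
        labels0, medoids = kmedoids(d, k, seed=cfg.seed, n_restarts=cfg.pam_restarts)
        jacc = bootstrap_jaccard(
            d, labels0, B=cfg.n_bootstrap, seed=boot_seed, k=k,
            n_restarts=cfg.pam_restarts,
        )
        n_weak = sum(1 for v in jacc.values() if v <= cfg.jaccard_threshold)
        robust = n_weak <= 1
        if robust or k <= 2:
            break
        k -= 1

    pair_d = [d[a, b] for a, b in itertools.combinations(medoids, 2)]
    if len(pair_d) >= 2:
        inter = (float(np.mean(pair_d)), float(np.std(pair_d, ddof=1)))
    elif len(pair_d) == 1:
        inter = (float(pair_d[0]), 0.0)
    else:
        inter = (float("nan"), float("nan"))

    labels = pd.Series(labels0 + 1, index=cell_ids)
    return ClusterResult(
        labels=labels,
        medoid_cell_ids=[cell_ids[m] for m in medoids],
        k=k,
        jaccard={c + 1: float(v) for c, v in jacc.items()},
        robust=robust,
        intercluster_distance_mean_sd=inter,
    )


def enriched_condition_fraction(
    labels: pd.Series, annotation: CellAnnotation
) -> pd.DataFrame:
    """Per-cluster condition composition (rows sum to 1).

    The table answers "which condition do the cells of each cluster
    come from", the bar-graph view used to spot condition-enriched
    clusters (e.g. neutrophils appearing only in the acute phase).
    """
    missing = labels.index.difference(annotation.cell_ids)
    if len(missing):
        raise ContractError(f"cell(s) {list(missing[:3])} missing from annotation")
    cond = annotation.condition.loc[labels.index]
    tab = pd.crosstab(labels, cond)
    frac = tab.div(tab.sum(axis=1), axis=0)
    frac.index.name = "cluster"
    frac.columns.name = "condition"
    return frac
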