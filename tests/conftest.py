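import numpy as np
import pandas as pd
import pytest

import cardiocomm as cc


@pytest.fixture
def toy_counts() -> cc.CountMatrix:
    """3 genes x 2 cells, observed-UMI stage."""
    df = pd.DataFrame(
        [[5, 0], [1, 3], [0, 7]],
        index=["Nppb", "B2m", "Col1a1"],
        columns=["cellA", "cellB"],
    )
    return cc.CountMatrix(df, stage="observed_umi", umi_space=4096)


@pytest.fixture(scope="session")
def default_pipeline():
    """Seed-0 default fixture taken through quantification and robust
    clustering once per session (several tests inspect it)."""
    cfg = cc.RunConfig(seed=0)
    sim = cc.default_config(seed=0)
    matrix, annot, truth = cc.simulate_dataset(sim)
    expr, report = cc.quantify_pipeline(matrix, cfg)
    d, cells = cc.pearson_distance(expr)
    result = cc.robust_cluster(d, cfg, cells)
    return {
        "cfg": cfg,
        "sim": sim,
        "matrix": matrix,
        "annot": annot,
        "truth": truth,
        "expr": expr,
        "report": report,
        "distance": d,
        "cells": cells,
        "result": result,
    }


def blob_distance(
    n_per_blob, n_blobs: int, separation: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distance matrix of Gaussian blobs with unit noise and
    the planted labels."""
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for b in range(n_blobs):
        center = np.zeros(4)
        center[b % 4] = separation * (1 + b // 4)
        m = n_per_blob if np.isscalar(n_per_blob) else n_per_blob[b]
        pts.append(center + rng.normal(size=(m, 4)))
        labels += [b] * m
    pts = np.vstack(pts)
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return d, np.array(labels)
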