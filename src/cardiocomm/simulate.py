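"""Synthetic SORT-seq datasets with known ground truth.

The generator emulates the statistical structure the pipeline exploits:

* a mixture of cardiac cell types (CM, FB, MP, NP, EC) whose
  proportions shift with condition (e.g. neutrophils appearing only in
  the acute post-ischemic phase);
* per-type gene-expression programs with marker blocks, plus an
  optional continuous gradient between two program variants within a
  type (emulating the Myh6/Atp2a2-style marker continuum in
  cardiomyocytes);
* negative-binomial molecule counts scaled to a log-normal library
  size, then an explicit UMI-collision observation step: every
  molecule is assigned one of K UMI slots uniformly and the distinct
  (gene, UMI) combinations are counted — exactly the observation
  process the Poisson correction inverts;
* planted ligand-receptor co-expression with condition-dependent
  up-regulation, so the communication network and the ligand funnel
  have a known answer.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import CellAnnotation, ContractError, CountMatrix, LRPairTable


@dataclass
class CellTypeProgram:
    """Per-gene mean expression weights for one cell type.

    ``program_alt``, when present, is a second endpoint: each cell of
    the type draws a scalar u ~ U[0, 1] and expresses the interpolated
    program (1 - u) * program + u * program_alt.
    """

    name: str
    program: np.ndarray
    program_alt: Optional[np.ndarray] = None
    marker_genes: tuple = ()

    def __post_init__(self) -> None:
        self.program = np.asarray(self.program, dtype=float)
        if (self.program < 0).any():
            raise ContractError(f"negative program mean for type {self.name}")
        if self.program_alt is not None:
            self.program_alt = np.asarray(self.program_alt, dtype=float)
            if self.program_alt.shape != self.program.shape:
                raise ContractError("program_alt must match program length")
            if (self.program_alt < 0).any():
                raise ContractError(f"negative program_alt mean for type {self.name}")


@dataclass
class PlantedPair:
    """A planted ligand -> receptor couple with its IR up-regulation."""

    ligand: str
    receptor: str
    source_type: str
    target_type: str
    ir_fold: float = 5.0

    def __post_init__(self) -> None:
        if self.ir_fold <= 0:
            raise ContractError("ir_fold must be positive")


@dataclass
class SimConfig:
    gene_ids: List[str]
    cell_types: List[CellTypeProgram]
    #: (condition name, {type name: proportion}); proportions sum to 1.
    conditions: List[Tuple[str, Dict[str, float]]]
    n_cells_per_condition: int = 100
    #: log-normal library-size parameters (molecules per cell).
    library_log_mean: float = math.log(2600.0)
    library_log_sd: float = 0.35
    #: lower truncation of regular libraries (plate-level quality
    #: screening keeps ordinary cells safely above the downsample
    #: target; sub-threshold cells are planted explicitly instead).
    library_floor: int = 1500
    #: UMI-space size.
    K: int = 4096
    #: negative-binomial size (inverse dispersion); None = Poisson.
    dispersion: Optional[float] = 4.0
    planted_lr: List[PlantedPair] = field(default_factory=list)
    #: planted ligands that count as extracellular-matrix genes.
    ecm_ligands: tuple = ()
    #: number of low-quality cells planted with sub-threshold libraries.
    n_low_quality: int = 0
    low_quality_library: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        names = {t.name for t in self.cell_types}
        for cond, comp in self.conditions:
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ContractError(f"composition of condition {cond!r} does not sum to 1")
            if set(comp) - names:
                raise ContractError(f"unknown cell type in condition {cond!r}")
        n = len(self.gene_ids)
        for t in self.cell_types:
            if len(t.program) != n:
                raise ContractError(f"program length mismatch for type {t.name}")

    @property
    def condition_names(self) -> tuple:
        return tuple(c for c, _ in self.conditions)

    def gene_index(self, gene: str) -> int:
        return self.gene_ids.index(gene)

    def lr_table(self) -> LRPairTable:
        """The ligand-receptor pair table implied by the planted couples."""
        df = pd.DataFrame(
            [(p.ligand, p.receptor) for p in self.planted_lr],
            columns=["ligand", "receptor"],
        ).drop_duplicates()
        return LRPairTable(df.reset_index(drop=True))


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    cell_types: pd.Series
    conditions: pd.Series
    true_counts: pd.DataFrame
    marker_genes: Dict[str, tuple]
    planted_lr: List[PlantedPair]
    low_quality_cells: tuple = ()


def default_config(
    seed: int = 0,
    n_genes: int = 2000,
    n_cells_per_condition: int = 100,
    n_markers: int = 40,
    marker_strength: float = 24.0,
    np_marker_boost: float = 3.0,
    gradient_amplitude: float = 0.3,
    planted_mean_overrides: Optional[Dict[str, Dict[str, float]]] = None,
    ir_fold_overrides: Optional[Dict[str, float]] = None,
) -> SimConfig:
    """The standard 5-type, 5-condition cardiac fixture.

    2000 genes including 5 mitochondrial ("mt-") genes and Rn45s at
    artificially high abundance (so blacklist removal matters), 40
    marker genes per type at ``marker_strength`` x baseline, a marker
    gradient within cardiomyocytes, and planted cardiomyocyte ligands:
    four up-regulated 5-fold 1 dp IR vs sham (one of them ECM-like)
    plus two fold-1 decoys.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    types = ["CM", "FB", "MP", "NP", "EC"]

    gene_ids: List[str] = []
    for t in types:
        gene_ids += [f"{t}.mk{i:02d}" for i in range(n_markers)]
    mito = ["mt-Nd1", "mt-Co1", "mt-Co2", "mt-Cytb", "mt-Atp6"]
    gene_ids += mito + ["Rn45s"]
    ligands = ["LigCM1", "LigCM2", "LigCM3", "LigCM4", "LigCM5", "LigFB1"]
    receptors = ["RecFB1", "RecMP1", "RecEC1", "RecCM1", "RecFB2", "RecCM2"]
    gene_ids += ligands + receptors
    n_rest = n_genes - len(gene_ids)
    if n_rest < 0:
        raise ContractError("n_genes too small for the default fixture")
    gene_ids += [f"g{i:04d}" for i in range(n_rest)]
    idx = {g: i for i, g in enumerate(gene_ids)}

    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=len(gene_ids))
    base_mean = float(np.mean(baseline))
    for g in mito:
        baseline[idx[g]] = base_mean * 20.0  # mitochondrial dominance
    baseline[idx["Rn45s"]] = base_mean * 10.0
    for g in ligands + receptors:
        baseline[idx[g]] = 0.0  # planted genes are placed explicitly

    #: sham-condition molecule-mean weights of the planted genes, per type.
    planted_means = {
        "LigCM1": {"CM": 6.0},
        "LigCM2": {"CM": 6.0},
        "LigCM3": {"CM": 6.0, "FB": 30.0},  # highly enriched in fibroblasts
        "LigCM4": {"CM": 6.0},
        "LigCM5": {"CM": 6.0},  # decoy: expressed but not up-regulated
        "LigFB1": {"FB": 8.0},  # decoy: not a cardiomyocyte ligand
        "RecFB1": {"FB": 8.0},
        "RecMP1": {"MP": 8.0},
        "RecEC1": {"EC": 8.0},
        "RecCM1": {"CM": 8.0},
        "RecFB2": {"FB": 8.0},
        "RecCM2": {"CM": 8.0},
    }
    for gene, per_type in (planted_mean_overrides or {}).items():
        planted_means.setdefault(gene, {}).update(per_type)

    programs = []
    for t in types:
        prog = baseline.copy()
        markers = tuple(f"{t}.mk{i:02d}" for i in range(n_markers))
        # neutrophil libraries are dominated by a few extreme markers
        # (the S100a8/a9 pattern), so their program is boosted
        strength = marker_strength * (np_marker_boost if t == "NP" else 1.0)
        for g in markers:
            prog[idx[g]] = base_mean * strength
        for g, per_type in planted_means.items():
            if t in per_type:
                prog[idx[g]] = per_type[t]
        alt = None
        if t == "CM" and gradient_amplitude > 0:
            # marker continuum: first half of the markers up, second half
            # down along the per-cell gradient axis
            alt = prog.copy()
            half = n_markers // 2
            for i, g in enumerate(markers):
                scale = 1 + gradient_amplitude if i < half else 1 - gradient_amplitude
                alt[idx[g]] = prog[idx[g]] * scale
        programs.append(CellTypeProgram(t, prog, alt, markers))

    conditions = [
        ("1dpSham", {"CM": 0.50, "FB": 0.18, "MP": 0.10, "EC": 0.22}),
        ("1dpIR", {"CM": 0.30, "FB": 0.15, "MP": 0.13, "NP": 0.30, "EC": 0.12}),
        ("3dpIR", {"CM": 0.34, "FB": 0.26, "MP": 0.25, "EC": 0.15}),
        ("14dpSham", {"CM": 0.50, "FB": 0.18, "MP": 0.10, "EC": 0.22}),
        ("14dpIR", {"CM": 0.46, "FB": 0.20, "MP": 0.12, "EC": 0.22}),
    ]

    folds = {"LigCM1": 5.0, "LigCM2": 5.0, "LigCM3": 5.0, "LigCM4": 5.0,
             "LigCM5": 1.0, "LigFB1": 1.0}
    folds.update(ir_fold_overrides or {})
    planted = [
        PlantedPair("LigCM1", "RecFB1", "CM", "FB", folds["LigCM1"]),
        PlantedPair("LigCM2", "RecMP1", "CM", "MP", folds["LigCM2"]),
        PlantedPair("LigCM3", "RecEC1", "CM", "EC", folds["LigCM3"]),
        PlantedPair("LigCM4", "RecCM1", "CM", "CM", folds["LigCM4"]),
        PlantedPair("LigCM5", "RecFB2", "CM", "FB", folds["LigCM5"]),
        PlantedPair("LigFB1", "RecCM2", "FB", "CM", folds["LigFB1"]),
    ]

    return SimConfig(
        gene_ids=gene_ids,
        cell_types=programs,
        conditions=conditions,
        n_cells_per_condition=n_cells_per_condition,
        planted_lr=planted,
        ecm_ligands=("LigCM4",),
        seed=seed,
    )


def _observe_umis(true_counts: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Distinct (gene, UMI) combinations when each molecule draws one of
    K UMI slots uniformly. Vectorized over the whole cell."""
    total = int(true_counts.sum())
    if total == 0:
        return np.zeros_like(true_counts)
    gene_idx = np.repeat(np.arange(len(true_counts), dtype=np.int64), true_counts)
    umis = rng.integers(0, K, size=total, dtype=np.int64)
    codes = np.unique(gene_idx * K + umis)
    return np.bincount(codes // K, minlength=len(true_counts)).astype(np.int64)


def _draw_counts(mean: np.ndarray, dispersion: Optional[float],
                 rng: np.random.Generator) -> np.ndarray:
    if dispersion is None:
        return rng.poisson(mean)
    r = float(dispersion)
    p = r / (r + mean)
    out = np.zeros(len(mean), dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def simulate_dataset(
    cfg: SimConfig, ligand_scale: Optional[Dict[Tuple[str, str], float]] = None
) -> Tuple[CountMatrix, CellAnnotation, SimTruth]:
    """Draw a full observed-UMI dataset plus its ground truth.

    ``ligand_scale`` optionally multiplies the mean of (gene, type)
    entries — used by :func:`ir_vs_sham_pair` to plant condition
    effects without touching the shared programs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 13]))
    prog_by_name = {t.name: t for t in cfg.cell_types}
    ligand_scale = ligand_scale or {}

    cell_ids, types_out, conds_out = [], [], []
    true_cols, obs_cols = [], []
    low_quality = []
    cell_no = 0
    for cond, comp in cfg.conditions:
        type_names = list(comp)
        probs = np.array([comp[t] for t in type_names])
        drawn = rng.choice(len(type_names), size=cfg.n_cells_per_condition, p=probs)
        for j in drawn:
            t = prog_by_name[type_names[j]]
            cid = f"{cond}_c{cell_no:04d}"
            cell_no += 1
            weights = t.program
            if t.program_alt is not None:
                u = rng.uniform()
                weights = (1 - u) * t.program + u * t.program_alt
            if ligand_scale:
                weights = weights.copy()
                for (gene, tname), s in ligand_scale.items():
                    if tname == t.name:
                        weights[cfg.gene_ids.index(gene)] *= s
            if cell_no <= cfg.n_low_quality:
                lib = float(rng.uniform(0.4, 1.0) * cfg.low_quality_library)
                low_quality.append(cid)
            else:
                lib = float(rng.lognormal(cfg.library_log_mean, cfg.library_log_sd))
                lib = max(lib, float(cfg.library_floor))
            mean = weights / weights.sum() * lib
            true = _draw_counts(mean, cfg.dispersion, rng)
            obs = _observe_umis(true, cfg.K, rng)
            cell_ids.append(cid)
            types_out.append(t.name)
            conds_out.append(cond)
            true_cols.append(true)
            obs_cols.append(obs)

    genes = pd.Index(cfg.gene_ids)
    true_df = pd.DataFrame(np.column_stack(true_cols), index=genes, columns=cell_ids)
    obs_df = pd.DataFrame(np.column_stack(obs_cols), index=genes, columns=cell_ids)
    matrix = CountMatrix(obs_df, stage="observed_umi", umi_space=cfg.K)
    annot = CellAnnotation(
        pd.DataFrame(
            {"condition": conds_out, "cell_type": types_out}, index=pd.Index(cell_ids)
        ),
        condition_vocab=cfg.condition_names,
    )
    truth = SimTruth(
        cell_types=pd.Series(types_out, index=cell_ids),
        conditions=pd.Series(conds_out, index=cell_ids),
        true_counts=true_df,
        marker_genes={t.name: tuple(t.marker_genes) for t in cfg.cell_types},
        planted_lr=list(cfg.planted_lr),
        low_quality_cells=tuple(low_quality),
    )
    return matrix, annot, truth


def simulate_null_dataset(
    cfg: SimConfig, n_cells: Optional[int] = None
) -> Tuple[CountMatrix, CellAnnotation, SimTruth]:
    """Exchangeable cells from a single program (Poisson counts).

    Used to calibrate the binomial enrichment test: with one shared
    program and Poisson molecule counts, per-cell gene composition is
    multinomial, which is the sampling model the binomial tail assumes.
    """
    cond = cfg.conditions[0][0]
    null_cfg = replace(
        cfg,
        cell_types=[CellTypeProgram("null", cfg.cell_types[0].program.copy())],
        conditions=[(cond, {"null": 1.0})],
        dispersion=None,
        planted_lr=[],
        n_cells_per_condition=n_cells or cfg.n_cells_per_condition,
        n_low_quality=0,
    )
    return simulate_dataset(null_cfg)


def ir_vs_sham_pair(
    cfg: SimConfig, ir_fold: Optional[float] = None
) -> Tuple[
    Tuple[CountMatrix, CellAnnotation, SimTruth],
    Tuple[CountMatrix, CellAnnotation, SimTruth],
]:
    """A sham dataset and an IR dataset sharing programs.

    Both use the same cell-type composition; the only systematic
    difference is that each planted ligand's mean in its source type is
    multiplied by its ``ir_fold`` (or the override) in the IR dataset.
    Returns ``(sham, ir)`` tuples of (matrix, annotation, truth).
    """
    if not cfg.planted_lr:
        raise ContractError("ir_vs_sham_pair needs planted ligand-receptor pairs")
    comp = dict(next(c for n, c in cfg.conditions if n == "1dpIR"))
    sham_cfg = replace(
        cfg,
        conditions=[("1dpSham", comp)],
        seed=cfg.seed,
        n_low_quality=0,
    )
    ir_cfg = replace(
        cfg,
        conditions=[("1dpIR", comp)],
        seed=cfg.seed + 1,
        n_low_quality=0,
    )
    scale = {
        (p.ligand, p.source_type): (ir_fold if ir_fold is not None else p.ir_fold)
        for p in cfg.planted_lr
    }
    sham = simulate_dataset(sham_cfg)
    ir = simulate_dataset(ir_cfg, ligand_scale=scale)
    return sham, ir
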