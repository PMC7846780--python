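"""Ligand-receptor intercellular communication networks and the
cardiomyocyte ligand-screening funnel.

A gene counts as *expressed* by a cell type when at least a fraction
tau (default 20%) of that type's cells carry at least ``presence_count``
(default 1) of it. A ligand-receptor couple (L, R) supports a directed
link S -> T when S expresses L and T expresses R; autocrine loops
(S = T) are allowed.

The screening funnel for a source cell type (cardiomyocytes in the
acute phase) proceeds in three stages:

1. couples whose ligand is expressed by the source type and whose
   receptor is expressed by at least one cell type;
2. couples whose ligand is up-regulated at least ``fold_threshold``
   (default 3x) in the source type, IR vs sham — reported as a
   combination count and a unique-ligand count;
3. exclusion of ligands on the extracellular-matrix list and of
   ligands whose expressing fraction in another cell type exceeds
   ``enrichment_exclusion_factor`` times the source type's fraction,
   each exclusion carrying its reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .types import CellAnnotation, CommNetwork, ContractError, CountMatrix, LRPairTable

log = logging.getLogger(__name__)


def _as_frame(expr) -> pd.DataFrame:
    return expr.values if isinstance(expr, CountMatrix) else expr


def expression_fractions(
    expr, annotation: CellAnnotation, presence_count: float = 1.0
) -> pd.DataFrame:
    """Fraction of each type's cells expressing each gene.

    Returns a long-format DataFrame (gene, cell_type, fraction) with
    one row per gene x type; fraction = share of the type's cells with
    count >= presence_count.
    """
    df = _as_frame(expr)
    ctypes = annotation.cell_type
    if ctypes is None or ctypes.loc[df.columns].isna().any():
        raise ContractError("every cell needs a cell_type for expression fractions")
    ctypes = ctypes.loc[df.columns]
    present = df.to_numpy(dtype=float) >= presence_count
    rows = []
    for t in pd.unique(ctypes):
        mask = (ctypes == t).to_numpy()
        n = int(mask.sum())
        if n == 0:
            log.info("cell type %s has no cells; excluded", t)
            continue
        frac = present[:, mask].mean(axis=1)
        rows.append(pd.DataFrame({"gene": df.index, "cell_type": t, "fraction": frac}))
    return pd.concat(rows, ignore_index=True)


def _fraction_lookup(fractions: pd.DataFrame) -> pd.DataFrame:
    return fractions.pivot(index="gene", columns="cell_type", values="fraction")


def build_network(
    fractions: pd.DataFrame,
    pairs: LRPairTable,
    tau: float = 0.20,
    condition: Optional[str] = None,
) -> CommNetwork:
    """Directed type-to-type network from expression fractions.

    A couple (L, R) contributes an edge S -> T iff fraction(L, S) >= tau
    and fraction(R, T) >= tau. Pairs whose ligand or receptor is absent
    from the fraction table are skipped with a log entry. Monotone in
    tau: raising tau never adds a couple.
    """
    if not 0 < tau < 1:
        raise ContractError("tau must lie in (0, 1)")
    lut = _fraction_lookup(fractions)
    types = list(lut.columns)
    edges: Dict[tuple, set] = {}
    for ligand, receptor in pairs.as_tuples():
        if ligand not in lut.index or receptor not in lut.index:
            log.info("pair (%s, %s) skipped: gene absent from matrix", ligand, receptor)
            continue
        lig_types = [t for t in types if lut.at[ligand, t] >= tau]
        rec_types = [t for t in types if lut.at[receptor, t] >= tau]
        for s in lig_types:
            for t in rec_types:
                edges.setdefault((s, t), set()).add((ligand, receptor))
    return CommNetwork(condition=condition, edges=edges)


def build_condition_networks(
    expr, annotation: CellAnnotation, pairs: LRPairTable, cfg: RunConfig
) -> Dict[str, CommNetwork]:
    """One network per condition, over the cell types observed in it."""
    df = _as_frame(expr)
    out = {}
    for cond in pd.unique(annotation.condition.loc[df.columns]):
        cells = [c for c in df.columns if annotation.condition[c] == cond]
        frac = expression_fractions(
            df[cells], annotation.subset(cells), cfg.presence_count
        )
        out[cond] = build_network(frac, pairs, cfg.expr_fraction_tau, condition=cond)
    return out


@dataclass
class LigandScreenResult:
    """Outcome of the three-stage source-ligand funnel."""

    source_type: str
    #: (ligand, receptor) couples surviving stages 1-2.
    combinations: list
    #: unique ligands surviving stages 1-2.
    ligands_after_fold: list
    #: ligands surviving stage 3 exclusions.
    ligands_final: list
    #: per-ligand record table: ligand, fold_change, receptors,
    #: receptor_types, exclusion_reason (empty string if retained).
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_combinations(self) -> int:
        return len(self.combinations)

    @property
    def n_unique_ligands(self) -> int:
        return len(self.ligands_after_fold)

    @property
    def n_final(self) -> int:
        return len(self.ligands_final)


def screen_source_ligands(
    network: CommNetwork,
    fold_changes: pd.DataFrame,
    fractions: pd.DataFrame,
    cfg: RunConfig,
    source_type: str = "CM",
) -> LigandScreenResult:
    """Run the ligand-screening funnel for one source cell type.

    ``fold_changes`` must be the source type's IR-vs-sham table
    (columns gene, fold_change, B over A with B = IR); ``fractions``
    the expression-fraction table of the IR condition. See the module
    docstring for the three stages.
    """
    sources = {s for s, _ in network.edges}
    if source_type not in sources:
        raise ContractError(f"source type {source_type!r} has no outgoing edges")
    fc = fold_changes.set_index("gene")["fold_change"]
    lut = _fraction_lookup(fractions)

    # stage 1: couples carried by any edge out of the source type
    stage1: Dict[str, set] = {}
    receptor_types: Dict[str, set] = {}
    for (s, t), couples in network.edges.items():
        if s != source_type:
            continue
        for ligand, receptor in couples:
            stage1.setdefault(ligand, set()).add(receptor)
            receptor_types.setdefault(receptor, set()).add(t)

    # stage 2: fold filter on the ligand
    combinations = []
    ligands_after_fold = []
    dropped_missing = []
    for ligand in sorted(stage1):
        if ligand not in fc.index:
            log.info("ligand %s dropped: no fold-change entry", ligand)
            dropped_missing.append(ligand)
            continue
        if fc[ligand] >= cfg.fold_threshold:
            ligands_after_fold.append(ligand)
            for receptor in sorted(stage1[ligand]):
                combinations.append((ligand, receptor))

    # stage 3: ECM and enriched-elsewhere exclusions
    ecm = set(cfg.ecm_genes)
    records = []
    ligands_final = []
    for ligand in ligands_after_fold:
        reason = ""
        src_frac = float(lut.at[ligand, source_type])
        other = lut.loc[ligand].drop(source_type)
        if ligand in ecm:
            reason = "ECM"
        elif len(other) and float(other.max()) >= cfg.enrichment_exclusion_factor * src_frac:
            reason = f"enriched elsewhere ({other.idxmax()})"
        if reason:
            log.info("ligand %s excluded: %s", ligand, reason)
        else:
            ligands_final.append(ligand)
        records.append(
            {
                "ligand": ligand,
                "fold_change": float(fc[ligand]),
                "receptors": ",".join(sorted(stage1[ligand])),
                "receptor_types": ",".join(
                    sorted(set().union(*(receptor_types[r] for r in stage1[ligand])))
                ),
                "exclusion_reason": reason,
            }
        )
    for ligand in dropped_missing:
        records.append(
            {
                "ligand": ligand,
                "fold_change": float("nan"),
                "receptors": ",".join(sorted(stage1[ligand])),
                "receptor_types": "",
                "exclusion_reason": "no fold-change entry",
            }
        )
    rec_df = pd.DataFrame(
        records,
        columns=["ligand", "fold_change", "receptors", "receptor_types", "exclusion_reason"],
    )
    return LigandScreenResult(
        source_type=source_type,
        combinations=combinations,
        ligands_after_fold=ligands_after_fold,
        ligands_final=ligands_final,
        records=rec_df,
    )


def receptor_expression_bubble(
    fractions: pd.DataFrame, ligands: Sequence[str], pairs: LRPairTable
) -> pd.DataFrame:
    """Long-format receptor-by-type fraction table for bubble plots.

    One row per (ligand, receptor, cell_type) with the receptor's
    expressing fraction in that type — the data behind a
    receptor-expression bubble plot across cardiac cell types.
    Ligands without any receptor in the pair table yield no rows
    (logged).
    """
    lut = _fraction_lookup(fractions)
    rows = []
    for ligand in ligands:
        receptors = pairs.receptors_for(ligand)
        if not receptors:
            log.info("ligand %s has no receptor in the pair table", ligand)
            continue
        for receptor in receptors:
            if receptor not in lut.index:
                continue
            for t in lut.columns:
                rows.append(
                    {"ligand": ligand, "receptor": receptor, "cell_type": t,
                     "fraction": float(lut.at[receptor, t])}
                )
    return pd.DataFrame(rows, columns=["ligand", "receptor", "cell_type", "fraction"])
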