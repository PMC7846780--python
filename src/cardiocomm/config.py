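"""Run configuration: every tunable of the pipeline in one place.

Defaults reproduce the published analysis settings: a SORT-seq UMI
space of 4096, downsampling to 1000 transcripts per cell, the
``min.expr = 3 / min.number = 1`` gene filter, the bootstrap-Jaccard
robustness threshold of 0.6, the 20% expressed-fraction rule with a
presence count of 1, and the 3-fold up-regulation cut of the
cardiomyocyte ligand screen.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .types import ContractError


@dataclass
class RunConfig:
    #: UMI-space size (6 bp UMI -> 4**6 = 4096 distinct barcodes).
    K: int = 4096
    #: per-cell downsampling target (unique transcripts).
    T: int = 1000
    #: gene filter: minimum downsampled count ...
    min_expr: int = 3
    #: ... required in at least this many cells.
    min_number: int = 1
    #: bootstrap Jaccard robustness threshold.
    jaccard_threshold: float = 0.6
    #: number of bootstrap resamples for cluster stability.
    n_bootstrap: int = 50
    #: fraction of a type's cells that must express a gene to call it
    #: "expressed" by the type.
    expr_fraction_tau: float = 0.20
    #: a cell "expresses" a gene at a count of at least this.
    presence_count: float = 1.0
    #: minimum IR-vs-sham fold change for the ligand screen.
    fold_threshold: float = 3.0
    #: within-cluster dispersion saturation threshold for choosing k.
    dispersion_epsilon: float = 0.05
    #: largest k considered by the dispersion sweep.
    k_max: int = 20
    #: random PAM restarts per clustering call (0 = deterministic
    #: BUILD+SWAP only); restarts guard against PAM local optima.
    pam_restarts: int = 3
    #: master seed; every stage derives its own named stream from it.
    seed: int = 0
    #: mitochondrial gene symbol prefix (mouse convention).
    mito_prefix: str = "mt-"
    #: genes removed outright (Rn45s lacks a poly-A tail and its
    #: detection is a SORT-seq artefact).
    blacklist_genes: tuple = ("Rn45s",)
    #: extracellular-matrix genes excluded from the paracrine screen.
    ecm_genes: tuple = ()
    #: a ligand is "highly enriched elsewhere" when another type's
    #: expressing fraction reaches this multiple of the source type's.
    enrichment_exclusion_factor: float = 2.0
    #: number of downsampling draws averaged (1 = single draw).
    downsample_reps: int = 1
    #: pseudocount for condition fold changes (expected counts).
    fold_pseudocount: float = 0.1

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ContractError("T must be positive")
        if not 0 < self.expr_fraction_tau < 1:
            raise ContractError("expr_fraction_tau must lie in (0, 1)")
        if not 0 < self.jaccard_threshold < 1:
            raise ContractError("jaccard_threshold must lie in (0, 1)")
        if self.fold_threshold <= 1:
            raise ContractError("fold_threshold must exceed 1")
        if self.K < 2:
            raise ContractError("K must be >= 2")
        if self.n_bootstrap < 1 or self.downsample_reps < 1:
            raise ContractError("n_bootstrap and downsample_reps must be >= 1")
        if self.dispersion_epsilon <= 0:
            raise ContractError("dispersion_epsilon must be positive")
        self.blacklist_genes = tuple(self.blacklist_genes)
        self.ecm_genes = tuple(self.ecm_genes)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["blacklist_genes"] = list(self.blacklist_genes)
        data["ecm_genes"] = list(self.ecm_genes)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ContractError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)
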