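"""Synthetic negative-binomial count data with planted gene-program structure.

The generator mirrors the model's own generative family so that parameter
recovery is well-posed: latent activities ``Z ~ N(0, I)`` for the active
programs feed a linear map into softmax-linked NB counts, with per-batch
offsets and per-cell library sizes.  Null programs appear in the emitted
gene-set collection but contribute nothing to expression — a trained model
should switch them off.  Optional extras plant a two-group latent shift in
one program (for differential testing) and a query-only perturbation
signature (for reference-mapping tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gene_sets import GeneSetCollection
from .model import CellData, one_hot

__all__ = [
    "SimConfig",
    "PlantedQueryProgram",
    "GroupEffect",
    "SimTruth",
    "Simulation",
    "simulate",
    "simulate_query",
    "write_fixture",
]


@dataclass
class PlantedQueryProgram:
    """A perturbation signature present only in (a fraction of) query cells."""

    gene_indices: list[int]
    effect: float = 3.0
    affected_fraction: float = 0.5


@dataclass
class GroupEffect:
    """Latent shift of one program in group 'a' cells (for the GP test)."""

    program_index: int = 0
    shift: float = 2.5


@dataclass
class SimConfig:
    n_cells: int = 2000
    n_genes: int = 500
    n_programs_active: int = 10
    n_programs_null: int = 10
    n_conditions: int = 2
    genes_per_program: int = 22
    effect_sd: float = 2.0
    batch_shift_sd: float = 0.3
    dispersion: float = 5.0
    library_log_mean: float = np.log(500.0)
    library_log_sd: float = 0.35
    misspecified_noise_sd: float = 0.0  # log-normal noise on NB means, off by default
    planted_query_program: PlantedQueryProgram | None = None
    group_effect: GroupEffect | None = None
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cells, self.n_genes, self.n_conditions, self.genes_per_program) < 1:
            raise ValueError("all sizes must be positive")
        need = (self.n_programs_active + self.n_programs_null) * self.genes_per_program
        if need > self.n_genes:
            raise ValueError(
                f"cannot allocate {need} program genes from {self.n_genes} genes; "
                "reduce programs or genes_per_program"
            )


@dataclass
class SimTruth:
    active_programs: list[str]
    null_programs: list[str]
    program_genes: dict
    group_labels: np.ndarray | None = None  # 'a'/'b' per cell when a group effect is planted
    perturbed: np.ndarray | None = None  # bool per cell when a query program is planted
    group_effect_program: str | None = None
    latent: np.ndarray | None = None  # true per-cell activities of the active programs

    def to_json(self) -> dict:
        return {
            "active_programs": self.active_programs,
            "null_programs": self.null_programs,
            "program_genes": self.program_genes,
            "group_labels": None if self.group_labels is None else list(map(str, self.group_labels)),
            "perturbed": None if self.perturbed is None else [bool(b) for b in self.perturbed],
            "group_effect_program": self.group_effect_program,
        }


@dataclass
class Simulation:
    data: CellData
    gene_sets: GeneSetCollection
    truth: SimTruth
    cfg: SimConfig
    W_true: np.ndarray = field(repr=False, default=None)
    L_true: np.ndarray = field(repr=False, default=None)


def _draw_counts(logits, library, dispersion, rng, missp_sd=0.0):
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    mean = p * library[:, None]
    if missp_sd > 0:
        mean = mean * rng.lognormal(0.0, missp_sd, mean.shape)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam).astype(np.int64)


def simulate(cfg: SimConfig) -> Simulation:
    """Generate a reference dataset; deterministic for a given config/seed."""
    rng = np.random.default_rng(cfg.seed)
    gene_names = [f"g{i:04d}" for i in range(cfg.n_genes)]
    perm = rng.permutation(cfg.n_genes)
    n_prog = cfg.n_programs_active + cfg.n_programs_null
    program_genes = {}
    sets = []
    for j in range(n_prog):
        block = np.sort(perm[j * cfg.genes_per_program : (j + 1) * cfg.genes_per_program])
        name = f"active_{j}" if j < cfg.n_programs_active else f"null_{j - cfg.n_programs_active}"
        program_genes[name] = [gene_names[i] for i in block]
        sets.append((name, program_genes[name]))
    gene_sets = GeneSetCollection(sets)
    active_names = [n for n, _ in sets[: cfg.n_programs_active]]
    null_names = [n for n, _ in sets[cfg.n_programs_active :]]

    W_true = np.zeros((cfg.n_genes, cfg.n_programs_active))
    for j, name in enumerate(active_names):
        rows = [gene_names.index(g) for g in program_genes[name]]
        W_true[rows, j] = rng.normal(0.0, cfg.effect_sd, len(rows))
    L_true = rng.normal(0.0, cfg.batch_shift_sd, (cfg.n_genes, cfg.n_conditions))

    conditions = np.array([f"cond{i % cfg.n_conditions}" for i in range(cfg.n_cells)])
    rng.shuffle(conditions)
    categories = [f"cond{i}" for i in range(cfg.n_conditions)]
    C = one_hot(conditions, categories)

    Z = rng.standard_normal((cfg.n_cells, cfg.n_programs_active))
    group_labels = None
    ge_name = None
    if cfg.group_effect is not None:
        group_labels = np.where(rng.random(cfg.n_cells) < 0.5, "a", "b")
        Z[group_labels == "a", cfg.group_effect.program_index] += cfg.group_effect.shift
        ge_name = active_names[cfg.group_effect.program_index]

    logits = Z @ W_true.T + C @ L_true.T
    perturbed = None
    if cfg.planted_query_program is not None:
        pq = cfg.planted_query_program
        perturbed = rng.random(cfg.n_cells) < pq.affected_fraction
        logits[np.ix_(perturbed, np.asarray(pq.gene_indices))] += pq.effect

    library = rng.lognormal(cfg.library_log_mean, cfg.library_log_sd, cfg.n_cells)
    X = _draw_counts(logits, library, cfg.dispersion, rng, cfg.misspecified_noise_sd)

    data = CellData(
        X=X,
        conditions=conditions,
        condition_categories=categories,
        gene_names=gene_names,
        cell_ids=[f"cell{i:05d}" for i in range(cfg.n_cells)],
    )
    truth = SimTruth(
        active_programs=active_names,
        null_programs=null_names,
        program_genes=program_genes,
        group_labels=group_labels,
        perturbed=perturbed,
        group_effect_program=ge_name,
        latent=Z,
    )
    return Simulation(data=data, gene_sets=gene_sets, truth=truth, cfg=cfg,
                      W_true=W_true, L_true=L_true)


def simulate_query(
    ref: Simulation,
    n_cells: int = 1000,
    conditions=("query0",),
    planted: PlantedQueryProgram | None = None,
    seed: int = 1,
) -> Simulation:
    """Generate query cells from the reference generative process.

    Shares the reference ``W_true`` (same biology), draws fresh batch
    offsets for the new condition labels, and optionally plants a
    query-only perturbation signature in a fraction of cells.
    """
    cfg = ref.cfg
    rng = np.random.default_rng(seed)
    conditions = list(conditions)
    if set(conditions) & set(ref.data.condition_categories):
        raise ValueError("query condition labels must be new")
    L_q = rng.normal(0.0, cfg.batch_shift_sd, (cfg.n_genes, len(conditions)))
    labels = np.array([conditions[i % len(conditions)] for i in range(n_cells)])
    rng.shuffle(labels)
    C = one_hot(labels, conditions)
    Z = rng.standard_normal((n_cells, cfg.n_programs_active))
    logits = Z @ ref.W_true.T + C @ L_q.T
    perturbed = None
    if planted is not None:
        perturbed = rng.random(n_cells) < planted.affected_fraction
        logits[np.ix_(perturbed, np.asarray(planted.gene_indices))] += planted.effect
    library = rng.lognormal(cfg.library_log_mean, cfg.library_log_sd, n_cells)
    X = _draw_counts(logits, library, cfg.dispersion, rng, cfg.misspecified_noise_sd)
    data = CellData(
        X=X,
        conditions=labels,
        condition_categories=conditions,
        gene_names=ref.data.gene_names,
        cell_ids=[f"query{i:05d}" for i in range(n_cells)],
    )
    truth = SimTruth(
        active_programs=ref.truth.active_programs,
        null_programs=ref.truth.null_programs,
        program_genes=ref.truth.program_genes,
        perturbed=perturbed,
        latent=Z,
    )
    return Simulation(data=data, gene_sets=ref.gene_sets, truth=truth, cfg=cfg,
                      W_true=ref.W_true, L_true=L_q)


def write_fixture(sim: Simulation, directory) -> dict:
    """Write counts (.mtx), cell/gene TSVs, gene sets (GMT) and the truth JSON."""
    import pandas as pd
    import scipy.io
    import scipy.sparse as sp

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.mtx",
        "cells": directory / "cells.tsv",
        "genes": directory / "genes.tsv",
        "gene_sets": directory / "programs.gmt",
        "truth": directory / "truth.json",
    }
    scipy.io.mmwrite(str(paths["counts"]), sp.csr_matrix(sim.data.X.astype(np.int64)))
    obs = pd.DataFrame({"cell_id": sim.data.cell_ids, "condition": sim.data.conditions})
    if sim.truth.group_labels is not None:
        obs["group"] = sim.truth.group_labels
    if sim.truth.perturbed is not None:
        obs["perturbed"] = sim.truth.perturbed.astype(int)
    obs.to_csv(paths["cells"], sep="\t", index=False)
    pd.DataFrame({"gene": sim.data.gene_names}).to_csv(paths["genes"], sep="\t", index=False)
    with open(paths["gene_sets"], "w") as fh:
        for name, genes in sim.gene_sets.sets:
            fh.write("\t".join([name, "synthetic"] + genes) + "\n")
    with open(paths["truth"], "w") as fh:
        json.dump(sim.truth.to_json(), fh, indent=1)
    return paths
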