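"""Query-to-reference mapping by architecture surgery.

A trained reference model is expanded in place-preserving fashion: new
condition inputs (one-hot columns) are added with zero-initialised weights
so that reference cells' representations are untouched, and optionally new
latent program nodes — unconstrained (L1-sparse, HSIC-pushed toward
independence from existing programs) or constrained to a user gene set
(soft mask, own L1 strength).  Query training then updates only the new
weights; everything learned on the reference stays bit-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_sets import GPMask
from .model import CellData, GPModel
from .regularizers import ROLE_NEW_CONSTRAINED, ROLE_NEW_UNCONSTRAINED
from .training import TrainConfig, TrainReport, fit

__all__ = ["ExtensionSpec", "PartitionedModel", "extend_model", "map_query", "get_latent"]


@dataclass
class ExtensionSpec:
    new_conditions: list
    n_new_unconstrained: int = 10
    new_constrained: GPMask | None = None
    hsic_on_new_unconstrained: bool = True

    def __post_init__(self):
        if self.n_new_unconstrained < 0:
            raise ValueError("n_new_unconstrained must be >= 0")


@dataclass
class PartitionedModel:
    """An extended model whose reference partition is frozen.

    ``model.trainable`` holds binary masks marking the new weights; the
    frozen partition is everything else.  ``frozen_checksum`` digests the
    frozen entries so the freezing contract can be asserted bit-exactly.
    """

    model: GPModel
    n_ref_programs: int
    n_ref_conditions: int
    new_program_names: list = field(default_factory=list)

    def frozen_checksum(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.model.params):
            arr = np.ascontiguousarray(self.model.params[name], dtype=np.float64)
            tmask = self.model.trainable.get(name)
            frozen = arr if tmask is None else arr[tmask == 0]
            h.update(name.encode())
            h.update(np.ascontiguousarray(frozen).tobytes())
        return h.hexdigest()


def extend_model(ref_model: GPModel, ext: ExtensionSpec, seed: int = 0) -> PartitionedModel:
    """Expand a finalized reference model with new conditions and program nodes.

    New condition columns (encoder input and decoder L) are zero-initialised,
    so reference cells — whose new one-hot entries are zero — decode and
    encode exactly as before the extension.  New encoder output rows get a
    small random init (they must break symmetry); new decoder columns start
    at zero.
    """
    collide = set(ext.new_conditions) & set(ref_model.condition_labels)
    if collide:
        raise ValueError(f"new condition(s) already in reference: {sorted(collide)}")
    if ext.new_constrained is not None:
        if list(ext.new_constrained.gene_names) != list(ref_model.mask.gene_names):
            raise ValueError("constrained extension must share the reference gene axis")
        name_clash = set(ext.new_constrained.program_names) & set(ref_model.program_names)
        if name_clash:
            raise ValueError(f"extension program name(s) already present: {sorted(name_clash)}")

    rng = np.random.default_rng(seed)
    model = ref_model.copy()
    spec = model.spec
    n_genes = spec.n_genes
    n_old_cond = spec.n_conditions
    n_old_prog = spec.n_programs
    n_new_cond = len(ext.new_conditions)

    constrained_names = list(ext.new_constrained.program_names) if ext.new_constrained else []
    n_con = len(constrained_names)
    n_unc = ext.n_new_unconstrained
    n_new_prog = n_con + n_unc

    p = model.params
    trainable: dict[str, np.ndarray] = {}

    # encoder input: [genes | old conditions | new conditions]
    W0 = p["enc.h0.W"]
    p["enc.h0.W"] = np.concatenate([W0, np.zeros((W0.shape[0], n_new_cond))], axis=1)
    t = np.zeros_like(p["enc.h0.W"])
    t[:, n_genes + n_old_cond :] = 1.0
    trainable["enc.h0.W"] = t

    for name in list(p):
        if name not in trainable and name not in (
            "enc.mu.W", "enc.mu.b", "enc.sv.W", "enc.sv.b", "dec.W", "dec.L", "dec.D",
        ):
            trainable[name] = np.zeros_like(p[name])

    h_last = p["enc.mu.W"].shape[1]
    for head in ("mu", "sv"):
        Wh = p[f"enc.{head}.W"]
        new_rows = rng.normal(0.0, 1e-2, (n_new_prog, h_last))
        p[f"enc.{head}.W"] = np.concatenate([Wh, new_rows], axis=0)
        t = np.zeros_like(p[f"enc.{head}.W"])
        t[n_old_prog:, :] = 1.0
        trainable[f"enc.{head}.W"] = t
        p[f"enc.{head}.b"] = np.concatenate([p[f"enc.{head}.b"], np.zeros(n_new_prog)])
        tb = np.zeros_like(p[f"enc.{head}.b"])
        tb[n_old_prog:] = 1.0
        trainable[f"enc.{head}.b"] = tb

    p["dec.W"] = np.concatenate([p["dec.W"], np.zeros((n_genes, n_new_prog))], axis=1)
    t = np.zeros_like(p["dec.W"])
    t[:, n_old_prog:] = 1.0
    trainable["dec.W"] = t

    p["dec.L"] = np.concatenate([p["dec.L"], np.zeros((n_genes, n_new_cond))], axis=1)
    t = np.zeros_like(p["dec.L"])
    t[:, n_old_cond:] = 1.0
    trainable["dec.L"] = t

    # new conditions need their own dispersions; start from the reference mean
    d_init = np.tile(p["dec.D"].mean(axis=0, keepdims=True), (n_new_cond, 1))
    p["dec.D"] = np.concatenate([p["dec.D"], d_init], axis=0)
    t = np.zeros_like(p["dec.D"])
    t[n_old_cond:, :] = 1.0
    trainable["dec.D"] = t

    # extend the mask: constrained columns first, then unconstrained sparse ones
    new_names = constrained_names + [f"new_{k}" for k in range(n_unc)]
    B_new = np.zeros((n_genes, n_new_prog), dtype=np.int8)
    if n_con:
        B_new[:, :n_con] = ext.new_constrained.B
    mask = model.mask
    model.mask = GPMask(
        program_names=mask.program_names + new_names,
        gene_names=mask.gene_names,
        B=np.concatenate([mask.B, B_new], axis=1),
        M=np.concatenate([mask.M, (1 - B_new).astype(np.int8)], axis=1),
        membership_mode=mask.membership_mode
        + [ROLE_NEW_CONSTRAINED] * n_con
        + [ROLE_NEW_UNCONSTRAINED] * n_unc,
        orphan_genes=mask.orphan_genes,
    )

    model.spec.n_programs = n_old_prog + n_new_prog
    model.spec.n_conditions = n_old_cond + n_new_cond
    model.condition_labels = list(model.condition_labels) + list(ext.new_conditions)
    model.trainable = trainable
    if ext.hsic_on_new_unconstrained:
        model.new_unconstrained_idx = list(range(n_old_prog + n_con, n_old_prog + n_new_prog))
    else:
        model.new_unconstrained_idx = []

    return PartitionedModel(
        model=model,
        n_ref_programs=n_old_prog,
        n_ref_conditions=n_old_cond,
        new_program_names=new_names,
    )


def map_query(
    pmodel: PartitionedModel, query: CellData, cfg: TrainConfig
) -> tuple[PartitionedModel, TrainReport]:
    """Fine-tune the trainable partition on query cells only.

    Query cells must carry only new condition labels (a query batch is by
    definition not a reference batch).  The frozen partition is asserted
    bit-identical after training.
    """
    model = pmodel.model
    ref_conditions = set(model.condition_labels[: pmodel.n_ref_conditions])
    new_conditions = set(model.condition_labels[pmodel.n_ref_conditions :])
    seen = set(query.conditions)
    if seen & ref_conditions:
        raise ValueError(
            f"query contains reference condition label(s) {sorted(seen & ref_conditions)}; "
            "query batches must be mapped as new conditions"
        )
    if not seen <= new_conditions:
        raise ValueError(f"unknown query condition(s): {sorted(seen - new_conditions)}")

    mapped = PartitionedModel(
        model=model.copy(),
        n_ref_programs=pmodel.n_ref_programs,
        n_ref_conditions=pmodel.n_ref_conditions,
        new_program_names=list(pmodel.new_program_names),
    )
    # train with the model's full condition vocabulary (one-hot includes ref slots)
    qdata = CellData(
        X=query.X,
        conditions=query.conditions,
        condition_categories=mapped.model.condition_labels,
        gene_names=query.gene_names,
        cell_ids=query.cell_ids,
    )
    before = pmodel.frozen_checksum()
    report = fit(mapped.model, qdata, cfg)
    after = mapped.frozen_checksum()
    if before != after:
        raise AssertionError("frozen reference weights changed during query training")
    return mapped, report


def get_latent(model: GPModel, X, conditions) -> pd.DataFrame:
    """Posterior mean latent program scores, columns labelled by program name."""
    post = model.encode(X, conditions)
    return pd.DataFrame(post.mu, columns=model.program_names)
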