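"""Dataset readers and the model archive.

Counts are read from Matrix Market plus TSV metadata into an AnnData
(cells x genes, raw integer counts — the NB likelihood needs them raw;
normalised input is rejected).  Trained models round-trip losslessly
through a single HDF5 archive holding every parameter tensor, the
program mask, the trainability masks and the configuration.
"""

from __future__ import annotations

import json

import anndata as ad
import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .gene_sets import GPMask
from .model import GPModel, ModelSpec

__all__ = ["read_dataset", "save_model", "load_model"]

ARCHIVE_VERSION = "1"


def read_dataset(
    mtx_path,
    cells_tsv,
    genes_tsv,
    condition_column: str = "condition",
    orientation: str = "cells_by_genes",
) -> ad.AnnData:
    """Read a Matrix Market count matrix with cell/gene TSV metadata.

    ``orientation="genes_by_cells"`` transposes on read.  The condition
    column must exist in the cells TSV; entries must be raw non-negative
    integer counts.
    """
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValueError("orientation must be 'cells_by_genes' or 'genes_by_cells'")
    X = scipy.io.mmread(str(mtx_path))
    X = sp.csr_matrix(X)
    if orientation == "genes_by_cells":
        X = X.T.tocsr()
    if (X.data < 0).any() or np.any(X.data != np.round(X.data)):
        raise ValueError(
            "count matrix contains negative or non-integer entries; the negative-"
            "binomial likelihood requires raw counts"
        )
    obs = pd.read_csv(cells_tsv, sep="\t")
    if condition_column not in obs.columns:
        raise KeyError(
            f"condition column {condition_column!r} not in {cells_tsv} "
            f"(available: {list(obs.columns)})"
        )
    var = pd.read_csv(genes_tsv, sep="\t")
    gene_col = var.columns[0]
    if X.shape != (len(obs), len(var)):
        raise ValueError(
            f"matrix shape {X.shape} does not match {len(obs)} cells x {len(var)} genes"
        )
    if "cell_id" in obs.columns:
        obs = obs.set_index("cell_id")
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=var[gene_col].astype(str)))
    adata.obs["condition"] = adata.obs[condition_column].astype(str)
    return adata


def _write_strings(group, name, values):
    group.create_dataset(name, data=np.array(list(values), dtype=h5py.string_dtype()))


def _read_strings(group, name):
    return [v.decode() if isinstance(v, bytes) else str(v) for v in group[name][()]]


def save_model(model: GPModel, path) -> None:
    """Serialise a model to HDF5; the round-trip is bit-exact."""
    with h5py.File(path, "w") as f:
        f.attrs["archive_version"] = ARCHIVE_VERSION
        f.attrs["spec"] = json.dumps(
            {
                "n_genes": model.spec.n_genes,
                "n_programs": model.spec.n_programs,
                "n_conditions": model.spec.n_conditions,
                "hidden_sizes": list(model.spec.hidden_sizes),
                "link": model.spec.link,
                "dispersion_mode": model.spec.dispersion_mode,
            }
        )
        f.attrs["new_unconstrained_idx"] = json.dumps(model.new_unconstrained_idx)
        params = f.create_group("params")
        for name, arr in model.params.items():
            params.create_dataset(name, data=np.asarray(arr, dtype=np.float64))
        trainable = f.create_group("trainable")
        for name, arr in model.trainable.items():
            trainable.create_dataset(name, data=np.asarray(arr, dtype=np.int8))
        mg = f.create_group("mask")
        mg.create_dataset("B", data=model.mask.B)
        mg.create_dataset("M", data=model.mask.M)
        _write_strings(mg, "program_names", model.mask.program_names)
        _write_strings(mg, "gene_names", model.mask.gene_names)
        _write_strings(mg, "membership_mode", model.mask.membership_mode)
        _write_strings(mg, "orphan_genes", model.mask.orphan_genes)
        _write_strings(f, "condition_labels", model.condition_labels)


def load_model(path) -> GPModel:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("archive_version")
        if version != ARCHIVE_VERSION:
            raise ValueError(
                f"archive version {version!r} does not match library version "
                f"{ARCHIVE_VERSION!r}"
            )
        spec_d = json.loads(f.attrs["spec"])
        spec = ModelSpec(
            n_genes=spec_d["n_genes"],
            n_programs=spec_d["n_programs"],
            n_conditions=spec_d["n_conditions"],
            hidden_sizes=tuple(spec_d["hidden_sizes"]),
            link=spec_d["link"],
            dispersion_mode=spec_d["dispersion_mode"],
        )
        params = {name: f["params"][name][()] for name in f["params"]}
        trainable = {name: f["trainable"][name][()].astype(float) for name in f["trainable"]}
        mg = f["mask"]
        mask = GPMask(
            program_names=_read_strings(mg, "program_names"),
            gene_names=_read_strings(mg, "gene_names"),
            B=mg["B"][()],
            M=mg["M"][()],
            membership_mode=_read_strings(mg, "membership_mode"),
            orphan_genes=_read_strings(mg, "orphan_genes"),
        )
        return GPModel(
            spec=spec,
            mask=mask,
            params=params,
            condition_labels=_read_strings(f, "condition_labels"),
            trainable=trainable,
            new_unconstrained_idx=list(json.loads(f.attrs["new_unconstrained_idx"])),
        )
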