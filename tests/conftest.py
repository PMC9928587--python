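import sys
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from progmap.gene_sets import build_masks
from progmap.model import ModelSpec, GPModel
from progmap.simulate import (
    GroupEffect,
    PlantedQueryProgram,
    SimConfig,
    simulate,
    simulate_query,
)
from progmap.surgery import ExtensionSpec, extend_model, map_query
from progmap.training import TrainConfig, train_reference

SEED = 0


@pytest.fixture(scope="session")
def tiny_sim():
    """Small dataset for fast unit tests (240 cells x 60 genes, 3+2 programs)."""
    cfg = SimConfig(
        n_cells=240, n_genes=60, n_programs_active=3, n_programs_null=2,
        genes_per_program=8, n_conditions=2, seed=SEED,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def tiny_mask(tiny_sim):
    return build_masks(tiny_sim.gene_sets, tiny_sim.data.gene_names, min_genes=3, soft=True)


@pytest.fixture()
def tiny_model(tiny_sim, tiny_mask):
    spec = ModelSpec(
        n_genes=60, n_programs=tiny_mask.n_programs, n_conditions=2, hidden_sizes=(16, 16)
    )
    return GPModel.initialise(spec, tiny_mask, tiny_sim.data.condition_categories, seed=SEED)


@pytest.fixture(scope="session")
def reference_bundle():
    """The default synthetic study: 2000 x 500, 10 active + 10 null programs,
    2 batches, a +2.5 SD two-group shift in the first program; trained with
    the package defaults.  Shared by the integration and acceptance tests."""
    sim = simulate(SimConfig(group_effect=GroupEffect(), seed=SEED))
    mask = build_masks(sim.gene_sets, sim.data.gene_names, min_genes=5, soft=True)
    model, report = train_reference(sim.data, mask, cfg=TrainConfig(seed=SEED))
    return SimpleNamespace(sim=sim, mask=mask, model=model, report=report)


@pytest.fixture(scope="session")
def query_bundle(reference_bundle):
    """Query mapping on top of the session reference: one planted query-only
    perturbation signature on the genes no reference program uses."""
    rb = reference_bundle
    used = {g for genes in rb.sim.truth.program_genes.values() for g in genes}
    free = [i for i, g in enumerate(rb.sim.data.gene_names) if g not in used]
    query = simulate_query(
        rb.sim, n_cells=1500, conditions=("query0",),
        planted=PlantedQueryProgram(gene_indices=free), seed=100,
    )
    ext = ExtensionSpec(new_conditions=["query0"], n_new_unconstrained=10)
    pmodel = extend_model(rb.model, ext, seed=SEED)
    checksum_before = pmodel.frozen_checksum()
    mapped, report = map_query(
        pmodel, query.data, TrainConfig(seed=SEED, epochs=100, refine_epochs=50)
    )
    return SimpleNamespace(
        query=query, pmodel=pmodel, mapped=mapped, report=report,
        checksum_before=checksum_before, free_genes=free,
    )
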