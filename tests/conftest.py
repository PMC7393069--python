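"""Shared fixtures.

The expensive artifacts — a default-scale synthetic atlas pushed through the
whole pipeline, and a small atlas for unit tests — are built once per
session and shared.
"""

from __future__ import annotations

import time
from types import SimpleNamespace

import numpy as np
import pytest

from becatlas import pipeline, preprocess, synthetic


@pytest.fixture(scope="session")
def small_atlas():
    """A 1,200-cell atlas for unit-level planted-truth checks."""
    cfg = synthetic.AtlasConfig(n_cells=1200, seed=5)
    counts, truth, programs = synthetic.generate_atlas(cfg)
    return SimpleNamespace(cfg=cfg, counts=counts, truth=truth,
                           programs=programs)


@pytest.fixture(scope="session")
def small_norm(small_atlas):
    """Normalized, gene-filtered, decontaminated view of the small atlas."""
    norm = preprocess.normalize(small_atlas.counts)
    norm, _ = preprocess.filter_genes(norm, small_atlas.counts)
    sigs = synthetic.contaminant_signatures(small_atlas.programs)
    norm, _ = preprocess.remove_contaminants(norm, sigs, seed=5)
    truth = small_atlas.truth.loc[norm.cell_ids]
    return SimpleNamespace(norm=norm, truth=truth,
                           programs=small_atlas.programs)


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """One complete default-configuration pipeline run (5,000 cells).

    The wall time is recorded so the end-to-end budget can be asserted, and
    the in-memory state (truth tables, labels, trajectory, entropy, DE
    results) backs the planted-truth recovery tests.
    """
    cfg = pipeline.RunConfig(seed=7)
    state: dict = {}
    t0 = time.time()
    outdir = pipeline.run(cfg, tmp_path_factory.mktemp("full_run"),
                          state=state)
    elapsed = time.time() - t0
    truth = state["truth"].loc[state["norm"].cell_ids]
    return SimpleNamespace(config=cfg, state=state, outdir=outdir,
                           elapsed=elapsed, truth=truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
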