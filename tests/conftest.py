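from __future__ import annotations

import random

import pytest

from protoclust.core import HitRecord, edge_key
from protoclust.io import PipelineConfig
from protoclust.pipeline import run_all
from protoclust.simulate import SimConfig, generate


def random_edge_instance(
    rng: random.Random,
    n: int,
    edge_prob: float = 0.5,
    identity_range: tuple[float, float] = (30.0, 100.0),
    coverage_range: tuple[float, float] = (60.0, 100.0),
):
    """A random protein-id universe with random aggregated hits."""
    ids = [f"p{i:02d}" for i in range(n)]
    edges = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if rng.random() < edge_prob:
                ident = rng.uniform(*identity_range)
                cov_q = rng.uniform(*coverage_range)
                cov_s = rng.uniform(*coverage_range)
                edges[edge_key(a, b)] = HitRecord(a, b, ident, cov_q, cov_s)
    return ids, edges


@pytest.fixture(scope="session")
def sim():
    """The default synthetic pan-genome (the study conditions)."""
    return generate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(sim):
    """One full pipeline run on the default simulation, shared across tests."""
    return run_all(sim.dataset, PipelineConfig(exhaustive_filter_check=True))
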