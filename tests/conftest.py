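"""Shared fixtures: the standard synthetic study is simulated and analyzed
once per session and reused by every test that needs labeled results."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dmrkit import (
    SimConfig,
    assemble_sites,
    merge_strands,
    run_differential,
    simulate_meth_counts,
    simulate_truth,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TRUTH_SEED = 1
COUNTS_SEED = 11


@pytest.fixture(scope="session")
def standard_truth():
    return simulate_truth(SimConfig(), seed=TRUTH_SEED)


@pytest.fixture(scope="session")
def standard_counts(standard_truth):
    return simulate_meth_counts(standard_truth, seed=COUNTS_SEED)


@pytest.fixture(scope="session")
def standard_results(standard_truth, standard_counts):
    """Full differential-methylation chain on the standard fixture."""
    counts, design = standard_counts
    merged = {s: merge_strands(recs, s) for s, recs in counts.items()}
    sites = assemble_sites(merged, design)
    return run_differential(sites, control="wt", case="mut")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
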