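"""Shared fixtures.

The expensive fixtures (full-scale study batches, repeated default-seed
runs) are session-scoped so the acceptance tests can share one set of
simulator executions.
"""

from __future__ import annotations

import time

import numpy as np
import pytest

from caresim.abm.config import DemographyConfig
from caresim.abm.engine import batch_run, run_simulation
from caresim.abm.params import CareParams
from caresim.design import lptau_design


@pytest.fixture(scope="session")
def default_config():
    return DemographyConfig()


@pytest.fixture(scope="session")
def default_params():
    return CareParams()


@pytest.fixture(scope="session")
def small_config():
    """A fast configuration for unit tests of run-level behaviour."""
    return DemographyConfig(startYear=1860, endYear=1900, initialCouples=30)


@pytest.fixture(scope="session")
def default_runs_20(default_config, default_params):
    """Twenty default-parameter runs at seeds 0..19."""
    return [run_simulation(default_params, default_config, s) for s in range(20)]


@pytest.fixture(scope="session")
def study_batches(default_config):
    """The four full-scale study batches (200/400/800/1600 runs).

    Each batch takes a disjoint segment of the Sobol sequence and a
    disjoint block of per-run seeds, exactly as the pipeline generates
    them.  Returns (batches, wall_seconds) where batches maps size ->
    (design, run_table).
    """
    sizes = (200, 400, 800, 1600)
    batches = {}
    t0 = time.perf_counter()
    offset = 0
    for n in sizes:
        design = lptau_design(n, skip=1 + offset)
        runs = batch_run(design, default_config, offset)
        batches[n] = (design, runs)
        offset += n
    return batches, time.perf_counter() - t0
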