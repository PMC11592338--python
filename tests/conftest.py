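"""Shared fixtures: the default synthetic genome and its expensive derived
objects (loop table, balanced matrices, TAD calls) are built once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from regulohub.hic import ice_normalize, merge_replicates
from regulohub.loops import call_loops
from regulohub.synthetic import (
    CONDITIONS,
    SimulationConfig,
    build_truth,
    simulate_contacts,
)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_truth(default_config):
    return build_truth(default_config)


@pytest.fixture(scope="session")
def default_matrices(default_truth, default_config):
    return {
        (cond, rep): simulate_contacts(default_truth, cond, rep)
        for cond in CONDITIONS
        for rep in range(1, default_config.n_replicates_per_condition + 1)
    }


@pytest.fixture(scope="session")
def loop_table(default_matrices):
    return call_loops(default_matrices)


@pytest.fixture(scope="session")
def iced_gfp(default_matrices):
    merged = merge_replicates(
        [m for (c, _), m in default_matrices.items() if c == "GFP"]
    )
    return ice_normalize(merged)


@pytest.fixture(scope="session")
def tads_gfp(iced_gfp):
    from regulohub.domains import call_tads

    return call_tads(iced_gfp)


@pytest.fixture(scope="session")
def pipeline_report(tmp_path_factory):
    from regulohub.pipeline import RunConfig, run_all

    outdir = tmp_path_factory.mktemp("pipeline_run")
    report = run_all(RunConfig(), outdir)
    return report, outdir


def planted_loop_map(truth):
    return {(lp.bin_i, lp.bin_j): lp.category for lp in truth.loops}


def brute_force_overlap(a, b) -> bool:
    """Per-bp set intersection oracle for interval overlap."""
    if a.chrom != b.chrom:
        return False
    return bool(set(range(a.start, a.end)) & set(range(b.start, b.end)))
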