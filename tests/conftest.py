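"""Shared fixtures.

The heavyweight fixtures simulate libraries once per session and are shared
by the property and acceptance tests; problem sizes follow the toolkit's
default study conditions (200 molecules of ~8 kb at 300 mean copies).
"""

from __future__ import annotations

import pytest

from synthlr import (
    PipelineConfig,
    SimulationConfig,
    align_to_truth,
    run_pipeline,
    simulate_library,
)


def fragment_by_barcode(library):
    out = {}
    for truth, frag in zip(library.truths, library.fragments):
        out[truth.barcode_left] = frag
        out[truth.barcode_right] = frag
    return out


def truth_fragment_for(read, frag_by_bc):
    for bc in read.group_key.split("|"):
        frag = frag_by_bc.get(bc)
        if frag is not None:
            return frag
    return None


@pytest.fixture(scope="session")
def default_library():
    """Default study conditions: 200 molecules of ~8 kb from a 1 Mb reference."""
    return simulate_library(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_paired_run(default_library):
    cfg = PipelineConfig(simulate=default_library.config)
    return run_pipeline(cfg, library=default_library)


@pytest.fixture(scope="session")
def default_unpaired_run(default_library):
    cfg = PipelineConfig(simulate=default_library.config)
    return run_pipeline(cfg, library=default_library, skip_pairing=True)


@pytest.fixture(scope="session")
def default_truth_alignments(default_library, default_paired_run):
    """Ends-free truth alignments for synthetic reads of >= 1.5 kb."""
    frag_by_bc = fragment_by_barcode(default_library)
    results = []
    for read in default_paired_run.synthetic_reads:
        if len(read.sequence) < 1500:
            continue
        frag = truth_fragment_for(read, frag_by_bc)
        if frag is None:
            continue
        res = align_to_truth(read, frag)
        if res is not None:
            results.append(res)
    return results


@pytest.fixture(scope="session")
def small_library():
    """A light library for unit-level checks (6 molecules of ~4 kb)."""
    cfg = SimulationConfig(
        n_molecules=6,
        random_reference_length=60_000,
        fragment_mean=4000,
        fragment_sd=300,
        fragment_min=3500,
        fragment_max=4500,
        copies_per_molecule=120,
        seed=7,
    )
    return simulate_library(cfg)


@pytest.fixture(scope="session")
def small_run(small_library):
    cfg = PipelineConfig(simulate=small_library.config)
    return run_pipeline(cfg, library=small_library)


@pytest.fixture(scope="session")
def zero_error_library():
    """All substitution rates zero: payloads match truth exactly."""
    cfg = SimulationConfig(
        n_molecules=25,
        random_reference_length=300_000,
        copies_per_molecule=300,
        pcr_sub_rate=0.0,
        seq_sub_rate=0.0,
        low_tail_prob=0.0,
        seed=23,
    )
    return simulate_library(cfg)
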