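"""Shared fixtures: the packaged reference and small aligned libraries."""

from __future__ import annotations

from dataclasses import replace

import pytest

from trfseq import align, reference, simulate

TRNA = reference.TRNA_HIS_ID
MIRNA = reference.MIR4454_ID


@pytest.fixture(scope="session")
def ref_bundle():
    return reference.default_reference()


@pytest.fixture(scope="session")
def ref(ref_bundle):
    return ref_bundle[0]


@pytest.fixture(scope="session")
def trna_ann(ref_bundle):
    return ref_bundle[1][TRNA]


@pytest.fixture(scope="session")
def mirna_ann(ref_bundle):
    return ref_bundle[2][MIRNA]


def make_library(preset_name, n, seed, ref, **preset_changes):
    """Simulate + align one library; returns (primary records, truth table)."""
    preset = simulate.get_preset(preset_name, n_molecules=n, seed=seed)
    if preset_changes:
        preset = replace(preset, **preset_changes)
    reads, truth = simulate.simulate_reads(preset, ref)
    records, rejected = align.align_library(reads, ref)
    return records, truth, rejected


NOISE_FREE = dict(rt_model=simulate.RtModel(), seq_error_rate=0.0)


@pytest.fixture(scope="session")
def mock_lib(ref):
    return make_library("mock", 4000, 3, ref)


@pytest.fixture(scope="session")
def dicer_5p_lib(ref):
    return make_library("dicer_5p", 6000, 4, ref)


@pytest.fixture(scope="session")
def dicer_5pme2_lib(ref):
    return make_library("dicer_5pme2", 6000, 5, ref)


@pytest.fixture(scope="session")
def clean_mock_lib(ref):
    """Mock library with every noise layer switched off."""
    return make_library("mock", 300, 9, ref, **NOISE_FREE)
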