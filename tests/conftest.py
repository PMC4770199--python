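"""Shared fixtures: small seeded libraries exercised by several test modules."""

import numpy as np
import pytest

from drpseq.preprocess import AdapterScheme
from drpseq.simulate import (
    SimConfig,
    draw_abundances,
    make_transcriptome,
    render_reads,
    simulate_molecules,
)


@pytest.fixture(scope="session")
def scheme() -> AdapterScheme:
    return AdapterScheme()


@pytest.fixture(scope="session")
def small_library():
    """A small error-free library with 250-nt reads (mixed trim modes).

    250-nt reads keep the 120-nt core window out of reach of any chance
    partial Illumina-adapter suffix match, so molecule recovery is exact and
    the truth table is a valid oracle for deduplication and mapping.
    """
    cfg = SimConfig(
        n_genes=60,
        seed=42,
        input_picograms=600.0,
        capture_molecules_per_pg=2.0,
        pcr_cycles=4,
        per_cycle_efficiency=0.45,
        read_length_nt=250,
        fragment_min_bp=150,
        fragment_max_bp=400,
        error_rate=0.0,
    )
    tx = make_transcriptome(cfg)
    abund = draw_abundances(tx, cfg)
    molecules = simulate_molecules(tx, abund, cfg)
    reads, truth = render_reads(molecules, tx, cfg)
    return cfg, tx, abund, molecules, reads, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
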