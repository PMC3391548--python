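"""Shared fixtures: hand-built read sets and the seeded simulation grids
used by the acceptance tests."""

from __future__ import annotations

import pytest

from pyroqc import pipeline, simdata
from pyroqc.seqio import QualifiedRead, ReadSet


def make_read(
    read_id: str,
    bases: str,
    quals=None,
    q: int = 40,
    taxon=None,
    template_id=None,
) -> QualifiedRead:
    """A QualifiedRead with constant quality ``q`` unless ``quals`` given."""
    if quals is None:
        quals = (q,) * len(bases)
    return QualifiedRead(read_id, bases, tuple(quals), taxon, template_id)


def standard_noisy_config(seed: int = 20120405, **overrides) -> simdata.SimulationConfig:
    """The standard noisy simulation: 10 divergent templates, 500 reads,
    declining quality with isolated low-Q spikes, homopolymer indels and
    20% globally degraded reads."""
    params = dict(
        n_templates=10,
        template_length=140,
        n_reads=500,
        min_template_divergence=0.10,
        abundance_model="geometric",
        geometric_ratio=0.7,
        q_start=34.0,
        q_slope=0.02,
        q_noise_sd=0.5,
        q_spike_rate=0.004,
        q_spike_q=15.0,
        homopolymer_indel_rate=0.01,
        length_sd=10.0,
        frac_bad_reads=0.2,
        seed=seed,
    )
    params.update(overrides)
    return simdata.SimulationConfig(**params)


def error_free_config(seed: int = 20120405, **overrides) -> simdata.SimulationConfig:
    """The error-free limit of the standard configuration."""
    params = dict(
        q_start=40.0,
        q_slope=0.0,
        q_noise_sd=0.0,
        q_spike_rate=0.0,
        homopolymer_indel_rate=0.0,
        frac_bad_reads=0.0,
    )
    params.update(overrides)
    return standard_noisy_config(seed=seed, **params)


@pytest.fixture(scope="session")
def noisy_sim():
    """(read_set, ground_truth, templates) for the standard noisy config."""
    return simdata.simulate_community(standard_noisy_config())


@pytest.fixture(scope="session")
def noisy_grid(noisy_sim):
    """Full condition-grid manifest over the standard noisy simulation.

    The full-length baseline is not clustered here (it cannot share the
    trimmed distance matrix); the trimmed no-Q baseline is the unfiltered
    reference for the trend assertions.
    """
    read_set, _, _ = noisy_sim
    return pipeline.run_grid(read_set, cluster_full_length=False, quiet=True)


@pytest.fixture
def planted_fixture() -> tuple[ReadSet, dict]:
    """20 reads with non-overlapping planted defects: 5 short, 4 low-Q,
    2 N-containing, 1 primer-mutant; 8 clean survivors.

    The primer is ACGT; clean reads are 100 bases starting with it.
    Expected ledger: length 5, quality 4, ambiguous 2, primer 1.
    """
    primer = "ACGT"
    body = "ACGTACGTAC" * 10  # 100 bases, starts with the primer
    reads = []
    # 8 clean reads, length 100, all Q40
    for i in range(8):
        reads.append(make_read(f"clean{i}", body, q=40))
    # 5 planted short (length 50 << trim length)
    for i in range(5):
        reads.append(make_read(f"short{i}", body[:50], q=40))
    # 4 planted low quality: >15% of bases below any cutoff in the grid
    for i in range(4):
        quals = (10,) * 30 + (40,) * 70
        reads.append(make_read(f"lowq{i}", body, quals=quals))
    # 2 planted ambiguous
    for i in range(2):
        reads.append(make_read(f"ambig{i}", body[:40] + "N" + body[41:], q=40))
    # 1 planted primer mutant (first base broken)
    reads.append(make_read("primermut0", "T" + body[1:], q=40))
    expected = {
        "ledger": [("length", 5), ("quality", 4), ("ambiguous", 2), ("primer", 1)],
        "remaining": 8,
        "primer": primer,
    }
    return ReadSet(reads), expected
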