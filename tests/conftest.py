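import numpy as np
import pytest

from nanoits import (
    ErrorModel,
    MockSpec,
    PrimerPair,
    TrimRejection,
    generate_reference_set,
    simulate_reads,
    trim_and_orient,
)


@pytest.fixture(scope="session")
def mock_spec():
    """The default mock community: 16 taxa, one near pair at 1.5% divergence."""
    return MockSpec(seed=1)


@pytest.fixture(scope="session")
def mock_db(mock_spec):
    return generate_reference_set(mock_spec)


@pytest.fixture(scope="session")
def divergent_spec():
    """16 mutually divergent taxa (no sub-radius near pair)."""
    return MockSpec(n_taxa=16, near_pairs=(), seed=2)


@pytest.fixture(scope="session")
def divergent_db(divergent_spec):
    return generate_reference_set(divergent_spec)


@pytest.fixture(scope="session")
def primers():
    return PrimerPair()


def trim_all(reads, primers):
    out = []
    for r in reads:
        t = trim_and_orient(r, primers)
        if not isinstance(t, TrimRejection):
            out.append(t)
    return out


@pytest.fixture(scope="session")
def clean_reads(mock_db, mock_spec, primers):
    """600 essentially error-free reads from the default mock, trimmed."""
    reads, _ = simulate_reads(
        mock_db, mock_spec, 600, [40], model=ErrorModel(qual_spread=0),
        seed=7, inject_errors=False,
    )
    return trim_all(reads, primers)


@pytest.fixture(scope="session")
def noisy_reads_q20(mock_db, mock_spec, primers):
    """800 reads at target Q20 with the default error model, trimmed."""
    reads, truth = simulate_reads(mock_db, mock_spec, 800, [20], seed=11)
    return trim_all(reads, primers), truth
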