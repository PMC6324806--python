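import numpy as np
import pytest

from scissile import (
    CleavageEvent,
    Peptide,
    builtin_table,
    default_registry,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def table():
    return builtin_table()


def random_peptides(n, lengths, seed, id_prefix="pep"):
    """Plain-numpy peptide generator, independent of the synthetic module."""
    rng = np.random.default_rng(seed)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    peptides = []
    for i in range(n):
        L = int(rng.integers(lengths[0], lengths[1] + 1))
        blocks = tuple(rng.choice(alphabet, size=L))
        peptides.append(Peptide(id=f"{id_prefix}-{i}", blocks=blocks))
    return peptides


def random_events(peptides, rate, seed, protease_id="prot"):
    """Independent Bernoulli cleavage of every bond, for oracle tests."""
    rng = np.random.default_rng(seed)
    events = []
    for p in peptides:
        for b in range(p.n_bonds):
            if rng.random() < rate:
                events.append(CleavageEvent(p.id, b, protease_id))
    return events
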