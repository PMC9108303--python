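"""Shared fixtures and builders for the troutmig test suite."""

from __future__ import annotations

import numpy as np
import pytest

from troutmig.demography import FRESHWATER, RESIDENT, Population
from troutmig.genetics import MALE, N_LOCI


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_population(n: int, *, genomes: np.ndarray | None = None, **overrides) -> Population:
    """Build a population of ``n`` hand-placed trout with sensible defaults.

    Any Population column can be overridden with an array-like of length n.
    """
    fields = {
        "id": np.arange(n, dtype=np.int64),
        "sex": np.full(n, MALE, dtype=np.int8),
        "age_weeks": np.full(n, 104, dtype=np.int32),
        "habitat": np.full(n, FRESHWATER, dtype=np.int8),
        "tactic": np.full(n, RESIDENT, dtype=np.int8),
        "threshold": np.zeros(n),
        "condition": np.zeros(n),
        "quality": np.full(n, 230.0),
        "base_quality": np.full(n, 230.0),
        "parasitised": np.zeros(n, dtype=bool),
        "sneaking": np.zeros(n, dtype=bool),
        "x": np.zeros(n, dtype=np.int16),
        "y": np.zeros(n, dtype=np.int16),
        "weeks_at_sea": np.zeros(n, dtype=np.int32),
        "times_at_sea": np.zeros(n, dtype=np.int32),
    }
    for key, value in overrides.items():
        if key not in fields:
            raise KeyError(key)
        fields[key] = np.asarray(value)
    if genomes is None:
        genomes = np.zeros((n, N_LOCI, 2), dtype=np.uint8)
    return Population(fields, genomes)
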