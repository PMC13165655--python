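"""Shared fixtures: small synthetic cohorts and preprocessed splits.

Everything is generated programmatically at test time; sizes are kept small
enough for quick unit runs, with the heavier trained-model protocol living
in its own module-scoped fixture in test_acceptance.py.
"""

from __future__ import annotations

import numpy as np
import pytest

from edgebp.cohort import CohortSpec, generate_cohort
from edgebp.preprocess import assemble_splits, preprocess_records


@pytest.fixture(scope="session")
def small_cohort():
    """20 two-minute records with default noise settings."""
    spec = CohortSpec(n_records=20, duration_s=120.0, seed=7)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    spec, records = small_cohort
    return preprocess_records(records, min_samples=int(spec.duration_s * 125))


@pytest.fixture(scope="session")
def small_split(small_windows):
    return assemble_splits(small_windows, split_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
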