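import numpy as np
import pytest

from markorder.simulate import generate_subject_fixture
from markorder.stats import count_transitions, pool_stats


@pytest.fixture(scope="session")
def pooled_order1_fixture():
    """Three short trials from a mildly asymmetric first-order chain,
    pooled at order 1 — the canonical small dataset for evidence tests."""
    trials = generate_subject_fixture(
        1, [0.7, 0.4], n_trials=3, length_range=(20, 30), seed=42,
        burn_in=2000,
    )
    stats = pool_stats([count_transitions(s, 1) for s in trials])
    return trials, stats


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
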