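"""Shared fixtures: a small training bank and a bundle trained on it.

The small bank (560 clips) keeps model-dependent tests fast while
remaining separable; the full default bank is exercised only by the
acceptance test for the cross-validation criterion.
"""

from __future__ import annotations

import numpy as np
import pytest

from courtbeat.features import feature_matrix
from courtbeat.models import train_bundle
from courtbeat.synthcourt import BankSpec, gen_sample_bank

SMALL_BANK_SPEC = BankSpec(n_noise=200, n_rebound=180, n_impact=180, seed=7)


@pytest.fixture(scope="session")
def small_bank():
    clips, labels = gen_sample_bank(SMALL_BANK_SPEC)
    return clips, np.asarray(labels)


@pytest.fixture(scope="session")
def small_features(small_bank):
    clips, labels = small_bank
    X, names = feature_matrix(clips, extended=True)
    return X, names, labels


@pytest.fixture(scope="session")
def trained_bundle(small_features):
    X, _, labels = small_features
    return train_bundle(X, labels, seed=7)
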