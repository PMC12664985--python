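"""Shared fixtures: tiny trained models and synthetic corpora.

The ``tiny_model`` fixture trains a small causal model once per session
on a perfectly separable two-class corpus (disjoint residue alphabets,
Q/A/R vs G/S/L) so interpretability and classification tests can probe
a genuinely trained network without repeating the cost.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from plmscreen import (
    ClassProfile,
    LabeledDataset,
    ModelConfig,
    TrainingConfig,
    generate_proteome,
    train_model,
)

TAG_MAP = {"algal": "0", "bacterial": "1"}


@pytest.fixture(scope="session")
def tiny_profiles() -> tuple[ClassProfile, ClassProfile]:
    pa = ClassProfile("algal", {"Q": 1 / 3, "A": 1 / 3, "R": 1 / 3},
                      (), (20, 20))
    pb = ClassProfile("bacterial", {"G": 1 / 3, "S": 1 / 3, "L": 1 / 3},
                      (), (20, 20))
    return pa, pb


@pytest.fixture(scope="session")
def tiny_corpus(tiny_profiles):
    pa, pb = tiny_profiles
    ra = generate_proteome(pa, 180, seed=1)
    rb = generate_proteome(pb, 180, seed=2)
    train = LabeledDataset.from_items(
        [(r.sequence, r.true_class) for r in ra[:150] + rb[:150]], "train")
    hold = LabeledDataset.from_items(
        [(r.sequence, r.true_class) for r in ra[150:] + rb[150:]], "eval")
    return train, hold


@pytest.fixture(scope="session")
def tiny_model(tiny_corpus):
    train, hold = tiny_corpus
    model, _ = train_model(
        train, hold, TAG_MAP,
        arch=ModelConfig(n_layers=2, d_model=32, n_heads=2, context_length=32),
        cfg=TrainingConfig(batch_size=32, learning_rate=2e-3, max_steps=500,
                           warmup_steps=50, eval_interval=100, pad_to=20,
                           seed=5),
    )
    return model


@pytest.fixture(scope="session")
def tiny_holdout(tiny_corpus):
    return tiny_corpus[1]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
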