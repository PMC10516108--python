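"""Shared fixtures: toy corpus, preprocessed corpus, tiny trained model.

The expensive fixtures (pretrained model, descriptor projection) are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from genalign.chemspace import (
    compute_descriptors,
    fast_descriptor_provider,
    fit_projection,
    project,
)
from genalign.corpus import preprocess
from genalign.generator import (
    GeneratorConfig,
    TrainSchedule,
    build_model,
    pretrain,
)
from genalign.synthetic import make_corpus


@pytest.fixture(scope="session")
def toy_corpus() -> list[str]:
    return make_corpus(300, seed=1)


@pytest.fixture(scope="session")
def prep(toy_corpus):
    return preprocess(toy_corpus, min_count=2, coverage=0.995, seed=0)


@pytest.fixture(scope="session")
def tiny_schedule() -> TrainSchedule:
    return TrainSchedule(batch_size=16, epochs=8, peak_lr=6e-4, final_lr=6e-5)


@pytest.fixture(scope="session")
def tiny_model(prep, tiny_schedule):
    """A briefly-pretrained tiny model (enough structure to sample from)."""
    config = GeneratorConfig.tiny(prep.encoded.max_len + 2)
    model = build_model(config, prep.vocabulary, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pretrain(model, prep.train, tiny_schedule, seed=0, validation=prep.validation)
    return model


@pytest.fixture(scope="session")
def descriptor_provider():
    return fast_descriptor_provider()


@pytest.fixture(scope="session")
def corpus_projection(prep, descriptor_provider):
    matrix = compute_descriptors(prep.corpus, provider=descriptor_provider)
    model = fit_projection(matrix, n_components=10)
    return model, matrix


@pytest.fixture(scope="session")
def corpus_coords(corpus_projection):
    model, matrix = corpus_projection
    return project(model, matrix)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
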