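"""Shared fixtures: tiny hand-built corpora and a small end-to-end
synthetic experiment reused by pipeline, evaluation and audit tests."""

from __future__ import annotations

import pytest

from portalfusion import (
    Corpus,
    EncoderSpec,
    FusionConfig,
    LabelSchema,
    Message,
    RebalanceSpec,
    TrainConfig,
    make_fold_plan,
    run_experiment,
)
from portalfusion.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def schema() -> LabelSchema:
    return LabelSchema()


@pytest.fixture()
def tiny_corpus(schema) -> Corpus:
    msgs = [
        Message("m1", "headache and rash since monday", "A"),
        Message("m2", "need a refill of my tablets", "P"),
        Message("m3", "question about billing and insurance", "L"),
        Message("m4", "just an update, all stable", "U"),
        Message("m5", "the swelling got worse", "A"),
        Message("m6", "reschedule my appointment please", "L"),
    ]
    return Corpus(schema, msgs)


@pytest.fixture(scope="session")
def small_dataset():
    """Synthetic corpus + aligned complementary-encoder embeddings."""
    config = SyntheticConfig(n=300, seed=11)
    corpus, embeddings = generate_dataset(config)
    specs = [
        EncoderSpec(name=name, category=cat, dim=config.dim,
                    backend="precomputed")
        for name, cat in zip(sorted(embeddings), ("generic", "domain", "source"))
    ]
    return config, corpus, embeddings, specs


@pytest.fixture(scope="session")
def small_experiment(small_dataset):
    """One full repeated-CV run (k=5, r=2) on the small synthetic set."""
    _, corpus, embeddings, specs = small_dataset
    plan = make_fold_plan(corpus, n_folds=5, n_repeats=2, seed=11)
    result = run_experiment(
        corpus,
        specs,
        FusionConfig(strategy="cnn", training=TrainConfig(lr=0.05, epochs=80)),
        RebalanceSpec("oversample"),
        plan,
        precomputed=embeddings,
        hyper=TrainConfig(epochs=150),
    )
    return corpus, plan, result
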