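"""Sentence encoders and fine-tuned baseline classifiers.

A *baseline model* is one sentence encoder plus a softmax
classification head.  The encoder contract is uniform across backends:

* ``mock`` — a deterministic token-hash encoder (lowercase, strip
  punctuation, whitespace-tokenize; each token maps through a fixed
  seeded hash to a unit-norm vector; the message embedding is the mean
  over token vectors).  It needs no downloads, is stable across
  processes and platforms, and is the primary offline test double.
* ``precomputed`` — row lookup in an existing :class:`EmbeddingSet`
  (e.g. one produced by the synthetic generator or exported from a
  transformer run elsewhere).
* anything else is treated as a transformer checkpoint identifier and
  requires a transformer runtime to be importable.

With a frozen (mock/precomputed) encoder, "fine-tuning" reduces to
fitting the head on the frozen embeddings, which completes in seconds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._optim import LinearSoftmaxHead, TrainConfig
from .corpus import Corpus, LabelSchema, Message
from .rebalance import RebalanceSpec, inverse_frequency_weights, oversample

logger = logging.getLogger(__name__)

__all__ = [
    "EncoderSpec",
    "EmbeddingSet",
    "FittedClassifier",
    "PredictionSet",
    "MockEncoder",
    "encode",
    "fine_tune",
    "predict",
]

_CATEGORIES = ("generic", "domain", "source", "mock")

# Strip the same punctuation everywhere so token hashing is reproducible.
_PUNCT = r"""!"#$%&'()*+,-./:;<=>?@[\]^_`{|}~"""
_PUNCT_TABLE = str.maketrans("", "", _PUNCT)


@dataclass(frozen=True)
class EncoderSpec:
    """Description of one sentence encoder."""

    name: str
    category: str = "mock"
    dim: int = 64
    max_tokens: int = 256
    backend: str = "mock"

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("dim must be positive")
        if self.category not in _CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not in {_CATEGORIES}"
            )


@dataclass
class EmbeddingSet:
    """An n x dim matrix of message embeddings aligned to message ids."""

    encoder_name: str
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {len(self.ids)} ids"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding matrix contains non-finite values")
        self._row_of = {i: r for r, i in enumerate(self.ids)}
        if len(self._row_of) != len(self.ids):
            raise ValueError("duplicate ids in EmbeddingSet")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def row(self, msg_id: str) -> np.ndarray:
        try:
            return self.matrix[self._row_of[msg_id]]
        except KeyError:
            raise KeyError(
                f"encoder {self.encoder_name!r} has no embedding for id {msg_id!r}"
            ) from None

    def subset(self, ids: Sequence[str]) -> "EmbeddingSet":
        rows = np.stack([self.row(i) for i in ids]) if ids else \
            np.empty((0, self.dim))
        return EmbeddingSet(self.encoder_name, tuple(ids), rows)

    def save(self, stem: str | Path) -> None:
        """Persist as <stem>.npy plus a JSON sidecar <stem>.json."""
        stem = Path(stem)
        np.save(stem.with_suffix(".npy"), self.matrix)
        sidecar = {"encoder_name": self.encoder_name, "ids": list(self.ids),
                   "dim": self.dim}
        stem.with_suffix(".json").write_text(json.dumps(sidecar), encoding="utf-8")

    @classmethod
    def load(cls, stem: str | Path) -> "EmbeddingSet":
        stem = Path(stem)
        sidecar = json.loads(stem.with_suffix(".json").read_text(encoding="utf-8"))
        matrix = np.load(stem.with_suffix(".npy"))
        return cls(sidecar["encoder_name"], tuple(sidecar["ids"]), matrix)


class MockEncoder:
    """Deterministic token-hash sentence encoder.

    Tokens are hashed (BLAKE2b, salted with the encoder name so
    distinct mock encoders produce distinct feature spaces) to seed a
    fixed Gaussian unit vector; a message embeds as the mean of its
    token vectors, and an empty token list embeds as the zero vector.
    No randomized hashing is involved, so output is stable across
    processes and platforms.
    """

    def __init__(self, name: str, dim: int, max_tokens: int = 256):
        self.name = name
        self.dim = dim
        self.max_tokens = max_tokens
        self._cache: dict[str, np.ndarray] = {}

    @staticmethod
    def tokenize(text: str) -> list[str]:
        return text.lower().translate(_PUNCT_TABLE).split()

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.name}|{token}".encode("utf-8"), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "big"))
            vec = rng.standard_normal(self.dim)
            vec /= np.linalg.norm(vec)
            self._cache[token] = vec
        return vec

    def encode_text(self, text: str) -> np.ndarray:
        tokens = self.tokenize(text)
        if len(tokens) > self.max_tokens:
            logger.warning(
                "encoder %s: truncating message from %d to %d tokens",
                self.name, len(tokens), self.max_tokens,
            )
            tokens = tokens[: self.max_tokens]
        if not tokens:
            return np.zeros(self.dim)
        return np.mean([self._token_vector(t) for t in tokens], axis=0)


def encode(
    spec: EncoderSpec,
    messages: Sequence[Message],
    precomputed: EmbeddingSet | None = None,
) -> EmbeddingSet:
    """Embed messages with the backend named by ``spec``.

    One output row per message, dimension ``spec.dim``; deterministic
    given the spec (and, for precomputed backends, the stored matrix).
    Messages longer than ``spec.max_tokens`` are truncated with a
    logged warning.
    """
    if len(messages) == 0:
        raise ValueError("messages must be non-empty")
    ids = tuple(m.id for m in messages)
    if spec.backend == "precomputed" or precomputed is not None:
        if precomputed is None:
            raise ValueError(
                f"encoder {spec.name!r} declares a precomputed backend but no "
                "EmbeddingSet was supplied"
            )
        rows = np.stack([precomputed.row(i) for i in ids])
        return EmbeddingSet(spec.name, ids, rows)
    if spec.backend == "mock":
        enc = MockEncoder(spec.name, spec.dim, spec.max_tokens)
        rows = np.stack([enc.encode_text(m.text) for m in messages])
        return EmbeddingSet(spec.name, ids, rows)
    # Checkpoint identifier: needs a transformer runtime.
    try:  # pragma: no cover - exercised only where transformers is installed
        import torch  # noqa: F401
        import transformers  # noqa: F401
    except ImportError as exc:
        raise RuntimeError(
            f"encoder backend {spec.backend!r} (checkpoint for {spec.name!r}) "
            "requires the 'torch' and 'transformers' packages, which are not "
            "importable; use the 'mock' or 'precomputed' backends instead"
        ) from exc
    raise NotImplementedError(  # pragma: no cover
        f"transformer checkpoint loading for {spec.backend!r} is not wired up"
    )


@dataclass
class PredictionSet:
    """Per-model predicted label plus class-probability vector per message.

    ``probs`` columns follow schema order; each row sums to 1 and the
    label is the schema-order tie-broken argmax.  ``source`` optionally
    records the provenance of each prediction (consensus vs fusion).
    """

    model_name: str
    schema: LabelSchema
    ids: tuple[str, ...]
    probs: np.ndarray
    source: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.ids), len(self.schema)):
            raise ValueError(
                f"probs shape {self.probs.shape} does not match "
                f"({len(self.ids)}, {len(self.schema)})"
            )
        sums = self.probs.sum(axis=1)
        if len(self.ids) and not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1 within 1e-6")
        if self.source is not None and len(self.source) != len(self.ids):
            raise ValueError("source must align with ids")

    @property
    def labels(self) -> tuple[str, ...]:
        # np.argmax returns the first maximal index; columns are in
        # schema (alphabetical) order, so ties break alphabetically.
        idx = np.argmax(self.probs, axis=1)
        return tuple(self.schema.labels[i] for i in idx)

    def label_of(self, msg_id: str) -> str:
        return self.labels[self.ids.index(msg_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": list(self.ids), "label": list(self.labels)})
        for j, lab in enumerate(self.schema):
            df[f"p_{lab}"] = self.probs[:, j]
        if self.source is not None:
            df["source"] = list(self.source)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, schema: LabelSchema | None = None,
        model_name: str | None = None,
    ) -> "PredictionSet":
        df = pd.read_csv(path, dtype={"id": str})
        prob_cols = [c for c in df.columns if c.startswith("p_")]
        schema = schema or LabelSchema(tuple(c[2:] for c in prob_cols))
        probs = df[[f"p_{lab}" for lab in schema]].to_numpy(dtype=float)
        source = tuple(df["source"]) if "source" in df.columns else None
        return cls(model_name or Path(path).stem, schema, tuple(df["id"]),
                   probs, source)


@dataclass
class FittedClassifier:
    """A frozen encoder plus a trained softmax head."""

    spec: EncoderSpec
    head: LinearSoftmaxHead
    schema: LabelSchema
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.head.W.shape[0] != len(self.schema):
            raise ValueError("head output dimension must equal schema size")


def fine_tune(
    spec: EncoderSpec,
    train: Corpus,
    rebalance: RebalanceSpec | None = None,
    hyper: TrainConfig | None = None,
    seed: int = 0,
    embeddings: EmbeddingSet | None = None,
) -> FittedClassifier:
    """Fit a baseline classifier on a labeled training corpus.

    With a frozen backend (mock or precomputed) the encoder itself is
    untouched and only the linear softmax head is trained, using the
    requested rebalancing strategy.  Deterministic given ``seed``.

    ``embeddings`` may supply precomputed rows covering the training
    ids (mandatory for precomputed backends, an optimization for
    others).
    """
    rebalance = rebalance or RebalanceSpec()
    labels = train.labels()
    counts = {c: labels.count(c) for c in train.schema}
    absent = [c for c, n in counts.items() if n == 0]
    if absent:
        raise ValueError(f"classes absent from training corpus: {absent}")
    if len(set(labels)) < 2:
        raise ValueError("training corpus must contain at least 2 classes")

    emb = encode(spec, train.messages, precomputed=embeddings)
    ids = list(emb.ids)
    label_of = {m.id: m.label for m in train}

    gamma = 0.0
    alpha_of: dict[str, float] | None = None
    if rebalance.strategy == "oversample":
        ids = oversample(ids, labels, seed=seed)
    elif rebalance.strategy == "class_weight":
        alpha_of = rebalance.class_weights(counts)
    elif rebalance.strategy == "focal":
        gamma = rebalance.gamma
        alpha_of = rebalance.class_weights(counts)

    X = np.stack([emb.row(i) for i in ids])
    y = np.array([train.schema.index(label_of[i]) for i in ids])
    alpha = (
        None if alpha_of is None
        else np.array([alpha_of[label_of[i]] for i in ids])
    )

    hyper = hyper or TrainConfig()
    head = LinearSoftmaxHead(emb.dim, len(train.schema), seed=seed)
    trace = head.fit(
        X, y, gamma=gamma, alpha=alpha,
        config=TrainConfig(hyper.lr, hyper.epochs, hyper.batch_size, seed),
    )
    meta = {
        "seed": seed,
        "epochs": hyper.epochs,
        "rebalance": rebalance.strategy,
        "final_loss": trace[-1] if trace else None,
        "train_ids": tuple(ids),
    }
    return FittedClassifier(spec, head, train.schema, meta)


def predict(
    model: FittedClassifier,
    messages: Sequence[Message],
    embeddings: EmbeddingSet | None = None,
) -> PredictionSet:
    """Predict labels and class probabilities for messages, in order."""
    emb = encode(model.spec, messages, precomputed=embeddings)
    probs = model.head.predict_proba(emb.matrix)
    return PredictionSet(model.spec.name, model.schema, emb.ids, probs)
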