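"""Disagreement-routed fusion of multiple encoder embeddings.

The central idea: after fitting one baseline classifier per encoder,
messages on which all baselines agree are trusted and take the
consensus label; messages on which they disagree are routed to a
*fusion head* trained (on the disagreement subset of the training
split, with gold labels) to map the stack of per-encoder embeddings to
class probabilities.  Three fusion strategies are provided:

* ``average``   — column-wise mean over the K embeddings, then a fully
  connected softmax layer;
* ``attention`` — additive attention (``score_k = v' tanh(W e_k)``,
  softmax over encoders) produces a weighted mean, then dense+softmax;
* ``cnn``       — the K x d stack is treated as a single-channel 2-D
  grid: valid-mode convolutions of several filter heights, ReLU,
  global max-pooling, concatenation, dropout, dense+softmax
  (a TextCNN-style architecture over the encoder axis).

All heads are plain numpy with analytic gradients and Adam, so
training is fast, dependency-free and bit-reproducible given a seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._optim import Adam, TrainConfig, loss_and_grad_logits, softmax
from .corpus import Corpus, LabelSchema
from .encoders import EmbeddingSet, PredictionSet
from .rebalance import RebalanceSpec, oversample

logger = logging.getLogger(__name__)

__all__ = [
    "DisagreementSplit",
    "FusionTrainingSet",
    "FusionConfig",
    "FittedFusion",
    "split_by_agreement",
    "build_fusion_training_set",
    "AverageFusionHead",
    "AttentionFusionHead",
    "CNNFusionHead",
    "fuse_average",
    "fuse_attention",
    "fuse_cnn",
    "train_fusion",
    "predict_fusion",
    "combine_predictions",
]


# ---------------------------------------------------------------------------
# Routing


@dataclass(frozen=True)
class DisagreementSplit:
    """Partition of message ids by baseline agreement.

    ``agreed`` holds (id, consensus label) pairs for messages on which
    every baseline predicted the same label; ``disagreed`` holds the
    remaining ids.  ``order`` preserves the original id order so the
    combined prediction set can be emitted in input order.
    """

    agreed: tuple[tuple[str, str], ...]
    disagreed: tuple[str, ...]
    order: tuple[str, ...]

    @property
    def agreed_ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.agreed)

    @property
    def consensus(self) -> dict[str, str]:
        return dict(self.agreed)

    def __post_init__(self) -> None:
        union = set(self.agreed_ids) | set(self.disagreed)
        if union != set(self.order) or len(self.agreed) + len(self.disagreed) != len(
            self.order
        ):
            raise ValueError("agreed and disagreed must partition the id universe")


def split_by_agreement(preds: Sequence[PredictionSet]) -> DisagreementSplit:
    """Split ids into baseline-agreed (with consensus label) and disagreed.

    Requires at least two prediction sets over identical id sets; an id
    is agreed iff all predicted labels coincide.
    """
    if len(preds) < 2:
        raise ValueError("need at least 2 prediction sets to compare")
    base = set(preds[0].ids)
    for p in preds[1:]:
        diff = base.symmetric_difference(p.ids)
        if diff:
            raise ValueError(
                f"prediction sets cover different ids; symmetric difference: "
                f"{sorted(diff)}"
            )
    labels = [dict(zip(p.ids, p.labels)) for p in preds]
    agreed: list[tuple[str, str]] = []
    disagreed: list[str] = []
    for i in preds[0].ids:
        votes = {lab[i] for lab in labels}
        if len(votes) == 1:
            agreed.append((i, votes.pop()))
        else:
            disagreed.append(i)
    return DisagreementSplit(tuple(agreed), tuple(disagreed), tuple(preds[0].ids))


# ---------------------------------------------------------------------------
# Fusion training set


@dataclass
class FusionTrainingSet:
    """Stacked per-encoder embeddings for the disagreement subset.

    ``stacks`` has shape (n, K, d): for each disagreed message a K x d
    matrix whose rows follow ``encoder_order`` (ascending by encoder
    name, recorded so CNN filters see a reproducible row layout).
    """

    ids: tuple[str, ...]
    stacks: np.ndarray
    labels: tuple[str, ...]
    encoder_order: tuple[str, ...]
    projections: Mapping[str, np.ndarray | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stacks = np.asarray(self.stacks, dtype=float)
        if len(self.ids) and not np.all(np.isfinite(self.stacks)):
            raise ValueError("stacks contain non-finite values")
        if self.stacks.ndim != 3 or self.stacks.shape[0] != len(self.ids):
            raise ValueError("stacks must be (n, K, d) aligned to ids")


def _projection_matrix(encoder_name: str, dim: int, common_dim: int) -> np.ndarray:
    """Fixed seeded Gaussian projection dim -> common_dim for one encoder."""
    digest = hashlib.blake2b(
        f"projection|{encoder_name}".encode(), digest_size=8
    ).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "big"))
    return rng.standard_normal((dim, common_dim)) / np.sqrt(dim)


def build_fusion_training_set(
    split: DisagreementSplit,
    embeddings: Sequence[EmbeddingSet],
    truth: Corpus,
    common_dim: int | None = None,
) -> FusionTrainingSet:
    """Assemble K x common_dim stacks for the disagreed, gold-labeled ids.

    Encoders are stacked in ascending name order regardless of input
    order.  An encoder whose dimension differs from ``common_dim`` is
    mapped through a fixed per-encoder projection (recorded in the
    result); matching dimensions pass through identically.  An empty
    disagreement set yields an empty training set with a logged warning
    so the caller can fall back to consensus-only predictions.
    """
    if len(embeddings) < 2:
        raise ValueError("fusion needs at least 2 encoders")
    emb_sorted = sorted(embeddings, key=lambda e: e.encoder_name)
    order = tuple(e.encoder_name for e in emb_sorted)
    if common_dim is None:
        common_dim = emb_sorted[0].dim

    projections: dict[str, np.ndarray | None] = {}
    for e in emb_sorted:
        projections[e.encoder_name] = (
            None if e.dim == common_dim
            else _projection_matrix(e.encoder_name, e.dim, common_dim)
        )

    if not split.disagreed:
        logger.warning(
            "empty disagreement set: baselines agree on every training message; "
            "fusion cannot be trained and the pipeline will fall back to "
            "consensus labels everywhere"
        )
        return FusionTrainingSet(
            (), np.empty((0, len(order), common_dim)), (), order, projections
        )

    label_of = {m.id: m.label for m in truth}
    stacks = np.empty((len(split.disagreed), len(order), common_dim))
    labels: list[str] = []
    for n, i in enumerate(split.disagreed):
        if label_of.get(i) is None:
            raise ValueError(f"disagreed id {i!r} is not labeled in the truth corpus")
        for k, e in enumerate(emb_sorted):
            row = e.row(i)  # raises naming (encoder, id) when missing
            proj = projections[e.encoder_name]
            stacks[n, k] = row if proj is None else row @ proj
        labels.append(label_of[i])
    return FusionTrainingSet(split.disagreed, stacks, tuple(labels), order, projections)


# ---------------------------------------------------------------------------
# Fusion heads


@dataclass(frozen=True)
class FusionConfig:
    """Architecture and training settings for one fusion head."""

    strategy: str = "cnn"
    common_dim: int = 768
    filter_heights: tuple[int, ...] = (2, 3)
    filter_width: int = 5
    n_filters: int = 64
    dropout: float = 0.1
    attention_hidden: int = 64
    training: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.strategy not in ("average", "attention", "cnn"):
            raise ValueError(f"unknown fusion strategy {self.strategy!r}")
        if self.common_dim <= 0:
            raise ValueError("common_dim must be positive")


class AverageFusionHead:
    """Column-wise mean over encoders, then a dense softmax layer."""

    def __init__(self, d: int, n_classes: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.W = rng.normal(0.0, 0.01, size=(n_classes, d))
        self.b = np.zeros(n_classes)

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def forward_batch(self, X: np.ndarray, training: bool = False,
                      rng: np.random.Generator | None = None):
        F = X.mean(axis=1)
        return F @ self.W.T + self.b, {"F": F}

    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        return {"W": dlogits.T @ cache["F"], "b": dlogits.sum(axis=0)}

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self.forward_batch(X)
        return softmax(logits, axis=1)


class AttentionFusionHead:
    """Additive attention over the encoder axis, then dense softmax.

    score_k = v' tanh(Wa e_k); weights = softmax over k; the fused
    vector is the attention-weighted mean of the encoder embeddings.
    """

    def __init__(self, d: int, n_classes: int, hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.Wa = rng.normal(0.0, 1.0 / np.sqrt(d), size=(hidden, d))
        self.va = rng.normal(0.0, 1.0 / np.sqrt(hidden), size=hidden)
        self.Wo = rng.normal(0.0, 0.01, size=(n_classes, d))
        self.bo = np.zeros(n_classes)

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"Wa": self.Wa, "va": self.va, "Wo": self.Wo, "bo": self.bo}

    def attention_weights(self, X: np.ndarray) -> np.ndarray:
        T = np.tanh(X @ self.Wa.T)          # (n, K, hidden)
        S = T @ self.va                      # (n, K)
        return softmax(S, axis=1)

    def forward_batch(self, X: np.ndarray, training: bool = False,
                      rng: np.random.Generator | None = None):
        T = np.tanh(X @ self.Wa.T)
        S = T @ self.va
        A = softmax(S, axis=1)
        F = (A[:, :, None] * X).sum(axis=1)
        logits = F @ self.Wo.T + self.bo
        return logits, {"X": X, "T": T, "A": A, "F": F}

    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        X, T, A, F = cache["X"], cache["T"], cache["A"], cache["F"]
        dWo = dlogits.T @ F
        dbo = dlogits.sum(axis=0)
        dF = dlogits @ self.Wo                          # (n, d)
        dA = (dF[:, None, :] * X).sum(axis=2)           # (n, K)
        dS = A * (dA - (A * dA).sum(axis=1, keepdims=True))
        dva = (dS[:, :, None] * T).sum(axis=(0, 1))
        dT = dS[:, :, None] * self.va                   # (n, K, hidden)
        dpre = dT * (1.0 - T**2)
        dWa = np.einsum("nkh,nkd->hd", dpre, X)
        return {"Wa": dWa, "va": dva, "Wo": dWo, "bo": dbo}

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self.forward_batch(X)
        return softmax(logits, axis=1)


class CNNFusionHead:
    """TextCNN-style 2-D convolution over the K x d embedding stack.

    For each filter height h (h <= K) and width w: valid-mode
    convolution, ReLU, global max-pool; pooled features from all filter
    sizes are concatenated, passed through dropout (training only) and
    a dense softmax layer.
    """

    def __init__(self, d: int, n_classes: int, n_encoders: int,
                 filter_heights: Sequence[int] = (2, 3), filter_width: int = 5,
                 n_filters: int = 64, dropout: float = 0.1, seed: int = 0):
        heights = tuple(h for h in filter_heights)
        for h in heights:
            if h > n_encoders:
                raise ValueError(
                    f"filter height {h} exceeds the number of encoders "
                    f"{n_encoders}"
                )
        if filter_width > d:
            raise ValueError(f"filter width {filter_width} exceeds embedding dim {d}")
        self.heights = heights
        self.width = filter_width
        self.n_filters = n_filters
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        self.filters = {
            h: rng.normal(0.0, np.sqrt(2.0 / (h * filter_width)),
                          size=(n_filters, h, filter_width))
            for h in heights
        }
        self.biases = {h: np.zeros(n_filters) for h in heights}
        n_feat = n_filters * len(heights)
        self.Wo = rng.normal(0.0, 0.01, size=(n_classes, n_feat))
        self.bo = np.zeros(n_classes)

    @property
    def params(self) -> dict[str, np.ndarray]:
        p: dict[str, np.ndarray] = {"Wo": self.Wo, "bo": self.bo}
        for h in self.heights:
            p[f"filt{h}"] = self.filters[h]
            p[f"bias{h}"] = self.biases[h]
        return p

    def pooled_features(self, X: np.ndarray) -> np.ndarray:
        """Concatenated global-max-pooled ReLU convolution features."""
        feats, _ = self._conv_forward(X)
        return feats

    def _conv_forward(self, X: np.ndarray):
        n = X.shape[0]
        feats = []
        caches = {}
        for h in self.heights:
            win = sliding_window_view(X, (h, self.width), axis=(1, 2))
            conv = np.einsum("nijhw,fhw->nfij", win, self.filters[h])
            conv += self.biases[h][None, :, None, None]
            relu = np.maximum(conv, 0.0)
            flat = relu.reshape(n, self.n_filters, -1)
            arg = flat.argmax(axis=2)
            pooled = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]
            feats.append(pooled)
            caches[h] = (win.reshape(n, -1, h, self.width), arg, pooled)
        return np.concatenate(feats, axis=1), caches

    def forward_batch(self, X: np.ndarray, training: bool = False,
                      rng: np.random.Generator | None = None):
        feat, caches = self._conv_forward(X)
        mask = None
        if training and self.dropout > 0.0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            mask = (rng.random(feat.shape) >= self.dropout) / (1.0 - self.dropout)
            feat = feat * mask
        logits = feat @ self.Wo.T + self.bo
        return logits, {"feat": feat, "caches": caches, "mask": mask}

    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        feat, caches, mask = cache["feat"], cache["caches"], cache["mask"]
        grads = {"Wo": dlogits.T @ feat, "bo": dlogits.sum(axis=0)}
        dfeat = dlogits @ self.Wo
        if mask is not None:
            dfeat = dfeat * mask
        n = dfeat.shape[0]
        for j, h in enumerate(self.heights):
            win_flat, arg, pooled = caches[h]
            dpool = dfeat[:, j * self.n_filters : (j + 1) * self.n_filters]
            # Gradient flows only through the argmax window, and only
            # where the ReLU output at the max was strictly positive.
            g = dpool * (pooled > 0.0)
            gathered = win_flat[np.arange(n)[:, None], arg]   # (n, nf, h, w)
            grads[f"filt{h}"] = np.einsum("nf,nfhw->fhw", g, gathered)
            grads[f"bias{h}"] = g.sum(axis=0)
        return grads

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self.forward_batch(X)
        return softmax(logits, axis=1)


def fuse_average(stack: np.ndarray, head: AverageFusionHead) -> np.ndarray:
    """Class probabilities for one K x d stack via the average strategy."""
    return head.predict_proba(stack[None])[0]


def fuse_attention(
    stack: np.ndarray, head: AttentionFusionHead
) -> tuple[np.ndarray, np.ndarray]:
    """(class probabilities, attention weights over the K encoders)."""
    probs = head.predict_proba(stack[None])[0]
    weights = head.attention_weights(stack[None])[0]
    return probs, weights


def fuse_cnn(stack: np.ndarray, head: CNNFusionHead) -> np.ndarray:
    """Class probabilities for one K x d stack via the CNN strategy."""
    return head.predict_proba(stack[None])[0]


# ---------------------------------------------------------------------------
# Training and inference


@dataclass
class FittedFusion:
    """A trained fusion head plus everything needed to replay it."""

    config: FusionConfig
    head: AverageFusionHead | AttentionFusionHead | CNNFusionHead
    schema: LabelSchema
    encoder_order: tuple[str, ...]
    projections: Mapping[str, np.ndarray | None]
    final_loss: float | None = None


def _make_head(config: FusionConfig, d: int, n_classes: int, n_encoders: int):
    seed = config.training.seed
    if config.strategy == "average":
        return AverageFusionHead(d, n_classes, seed=seed)
    if config.strategy == "attention":
        return AttentionFusionHead(d, n_classes, hidden=config.attention_hidden,
                                   seed=seed)
    heights = tuple(h for h in config.filter_heights if h <= n_encoders) or (
        n_encoders,
    )
    width = min(config.filter_width, d)
    return CNNFusionHead(d, n_classes, n_encoders, filter_heights=heights,
                         filter_width=width, n_filters=config.n_filters,
                         dropout=config.dropout, seed=seed)


def train_fusion(
    config: FusionConfig,
    train_set: FusionTrainingSet,
    rebalance: RebalanceSpec | None = None,
    schema: LabelSchema | None = None,
) -> FittedFusion:
    """Train a fusion head on the disagreement training set.

    Uses the same loss machinery as baseline fine-tuning (optionally
    focal / class-weighted / oversampled) with full-batch Adam;
    deterministic given ``config.training.seed``.
    """
    if len(train_set.ids) == 0:
        raise ValueError(
            "fusion training set is empty (baselines agreed everywhere); "
            "use the consensus-only fallback path instead of training fusion"
        )
    rebalance = rebalance or RebalanceSpec()
    schema = schema or LabelSchema(tuple(sorted(set(train_set.labels))))
    if len(set(train_set.labels)) < 2:
        raise ValueError("fusion training set must contain at least 2 classes")

    ids = list(train_set.ids)
    label_of = dict(zip(train_set.ids, train_set.labels))
    counts = {c: train_set.labels.count(c) for c in set(train_set.labels)}
    seed = config.training.seed

    gamma = 0.0
    alpha_of: dict[str, float] | None = None
    if rebalance.strategy == "oversample":
        ids = oversample(ids, list(train_set.labels), seed=seed)
    elif rebalance.strategy == "class_weight":
        alpha_of = rebalance.class_weights(counts)
    elif rebalance.strategy == "focal":
        gamma = rebalance.gamma
        alpha_of = rebalance.class_weights(counts)

    row_of = {i: r for r, i in enumerate(train_set.ids)}
    X = train_set.stacks[[row_of[i] for i in ids]]
    y = np.array([schema.index(label_of[i]) for i in ids])
    alpha = (
        None if alpha_of is None
        else np.array([alpha_of[label_of[i]] for i in ids])
    )

    n, n_enc, d = X.shape
    head = _make_head(config, d, len(schema), n_enc)
    opt = Adam(head.params, lr=config.training.lr)
    rng = np.random.default_rng(seed)
    bs = config.training.batch_size or n
    final_loss = None
    for _ in range(config.training.epochs):
        order = rng.permutation(n) if bs < n else np.arange(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            logits, cache = head.forward_batch(X[idx], training=True, rng=rng)
            loss, dlogits = loss_and_grad_logits(
                logits, y[idx], gamma, None if alpha is None else alpha[idx]
            )
            opt.step(head.backward(cache, dlogits))
            epoch_loss += loss * len(idx)
        final_loss = epoch_loss / n
    return FittedFusion(config, head, schema, train_set.encoder_order,
                        train_set.projections, final_loss)


def predict_fusion(
    fitted: FittedFusion,
    embeddings: Sequence[EmbeddingSet],
    ids: Sequence[str],
) -> PredictionSet:
    """Fusion-head predictions for ``ids`` from per-encoder embeddings."""
    by_name = {e.encoder_name: e for e in embeddings}
    missing = [n for n in fitted.encoder_order if n not in by_name]
    if missing:
        raise ValueError(f"missing embeddings for encoders: {missing}")
    d = (
        fitted.head.W.shape[1] if isinstance(fitted.head, AverageFusionHead)
        else fitted.head.Wo.shape[1] if isinstance(fitted.head, AttentionFusionHead)
        else None
    )
    # Rebuild stacks in the recorded encoder order with the recorded
    # projections, mirroring build_fusion_training_set exactly.
    first = by_name[fitted.encoder_order[0]]
    common_dim = first.dim
    for name in fitted.encoder_order:
        proj = fitted.projections.get(name)
        if proj is not None:
            common_dim = proj.shape[1]
            break
    stacks = np.empty((len(ids), len(fitted.encoder_order), common_dim))
    for n, i in enumerate(ids):
        for k, name in enumerate(fitted.encoder_order):
            row = by_name[name].row(i)
            proj = fitted.projections.get(name)
            stacks[n, k] = row if proj is None else row @ proj
    probs = (
        fitted.head.predict_proba(stacks) if len(ids)
        else np.empty((0, len(fitted.schema)))
    )
    return PredictionSet("fusion", fitted.schema, tuple(ids), probs,
                         source=tuple("fusion" for _ in ids))


def combine_predictions(
    split: DisagreementSplit,
    fused: PredictionSet,
) -> PredictionSet:
    """Merge consensus labels with fusion predictions into a full set.

    Agreed ids carry probability 1 on their consensus label with
    provenance ``consensus``; disagreed ids carry the fusion head's
    probabilities with provenance ``fusion``.  Output follows the
    original id order and covers every id exactly once.
    """
    if set(fused.ids) != set(split.disagreed):
        diff = set(fused.ids).symmetric_difference(split.disagreed)
        raise ValueError(
            f"fused predictions must cover exactly the disagreed ids; "
            f"mismatch on {sorted(diff)}"
        )
    schema = fused.schema
    consensus = split.consensus
    fused_row = {i: fused.probs[r] for r, i in enumerate(fused.ids)}
    probs = np.zeros((len(split.order), len(schema)))
    source = []
    for n, i in enumerate(split.order):
        if i in consensus:
            probs[n, schema.index(consensus[i])] = 1.0
            source.append("consensus")
        else:
            probs[n] = fused_row[i]
            source.append("fusion")
    return PredictionSet("routed_fusion", schema, split.order, probs,
                         source=tuple(source))
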