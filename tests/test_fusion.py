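"""Disagreement routing, fusion training sets, and the three fusion heads."""

import numpy as np
import pytest

from portalfusion import (
    AttentionFusionHead,
    AverageFusionHead,
    CNNFusionHead,
    Corpus,
    EmbeddingSet,
    FusionConfig,
    LabelSchema,
    Message,
    PredictionSet,
    RebalanceSpec,
    TrainConfig,
    build_fusion_training_set,
    combine_predictions,
    fuse_attention,
    fuse_average,
    fuse_cnn,
    predict_fusion,
    split_by_agreement,
    train_fusion,
)
from portalfusion._optim import loss_and_grad_logits, softmax


def pset(name, ids, labels, schema):
    probs = np.zeros((len(ids), len(schema)))
    for n, lab in enumerate(labels):
        probs[n, schema.index(lab)] = 1.0
    return PredictionSet(name, schema, tuple(ids), probs)


class TestSplitByAgreement:
    def test_unanimous_vs_disagreed(self, schema):
        ids = ["x", "y", "z"]
        p1 = pset("m1", ids, ["A", "A", "L"], schema)
        p2 = pset("m2", ids, ["A", "A", "P"], schema)
        p3 = pset("m3", ids, ["A", "L", "U"], schema)
        split = split_by_agreement([p1, p2, p3])
        assert split.agreed == (("x", "A"),)
        assert set(split.disagreed) == {"y", "z"}
        assert split.order == ("x", "y", "z")

    def test_all_unanimous_gives_empty_disagreed(self, schema):
        p1 = pset("m1", ["a", "b"], ["A", "U"], schema)
        p2 = pset("m2", ["a", "b"], ["A", "U"], schema)
        split = split_by_agreement([p1, p2])
        assert split.disagreed == ()
        assert dict(split.agreed) == {"a": "A", "b": "U"}

    def test_mismatched_ids_error_lists_difference(self, schema):
        p1 = pset("m1", ["a", "b"], ["A", "U"], schema)
        p2 = pset("m2", ["a", "c"], ["A", "U"], schema)
        with pytest.raises(ValueError, match=r"\['b', 'c'\]"):
            split_by_agreement([p1, p2])

    def test_needs_two_sets(self, schema):
        with pytest.raises(ValueError):
            split_by_agreement([pset("m", ["a"], ["A"], schema)])


def make_embeddings(names, ids, dim, seed=0):
    rng = np.random.default_rng(seed)
    return [EmbeddingSet(n, tuple(ids), rng.normal(size=(len(ids), dim)))
            for n in names]


class TestBuildFusionTrainingSet:
    def setup_method(self):
        self.schema = LabelSchema()
        self.truth = Corpus(self.schema, [Message(i, "t", lab) for i, lab in
                                          zip("abc", ["A", "L", "P"])])

    def test_shape_contract(self):
        split = split_by_agreement([
            pset("m1", list("abc"), ["A", "A", "P"], self.schema),
            pset("m2", list("abc"), ["A", "L", "U"], self.schema),
        ])
        embs = make_embeddings(["e1", "e2"], list("abc"), dim=4)
        ts = build_fusion_training_set(split, embs, self.truth)
        assert ts.stacks.shape == (len(split.disagreed), 2, 4)
        assert ts.labels == tuple(self.truth[i].label for i in ts.ids)

    def test_empty_disagreement_warns(self, caplog):
        split = split_by_agreement([
            pset("m1", list("ab"), ["A", "L"], self.schema),
            pset("m2", list("ab"), ["A", "L"], self.schema),
        ])
        embs = make_embeddings(["e1", "e2"], list("ab"), dim=4)
        with caplog.at_level("WARNING"):
            ts = build_fusion_training_set(split, embs, self.truth)
        assert len(ts.ids) == 0 and ts.stacks.shape == (0, 2, 4)
        assert "fall back" in caplog.text or "consensus" in caplog.text

    def test_encoder_order_is_name_sorted_regardless_of_input(self):
        split = split_by_agreement([
            pset("m1", list("abc"), ["A", "A", "P"], self.schema),
            pset("m2", list("abc"), ["L", "A", "P"], self.schema),
        ])
        embs = make_embeddings(["zeta", "alpha"], list("abc"), dim=3)
        ts1 = build_fusion_training_set(split, embs, self.truth)
        ts2 = build_fusion_training_set(split, embs[::-1], self.truth)
        assert ts1.encoder_order == ts2.encoder_order == ("alpha", "zeta")
        np.testing.assert_array_equal(ts1.stacks, ts2.stacks)

    def test_dimension_mismatch_uses_recorded_projection(self):
        split = split_by_agreement([
            pset("m1", list("abc"), ["A", "A", "P"], self.schema),
            pset("m2", list("abc"), ["L", "A", "P"], self.schema),
        ])
        e_small = make_embeddings(["small"], list("abc"), dim=4, seed=1)[0]
        e_big = make_embeddings(["big"], list("abc"), dim=6, seed=2)[0]
        ts = build_fusion_training_set(split, [e_small, e_big], self.truth,
                                       common_dim=4)
        assert ts.stacks.shape[2] == 4
        assert ts.projections["small"] is None
        proj = ts.projections["big"]
        assert proj.shape == (6, 4)
        np.testing.assert_allclose(ts.stacks[0, 0], e_big.row(ts.ids[0]) @ proj)

    def test_missing_embedding_row_names_encoder_and_id(self):
        split = split_by_agreement([
            pset("m1", list("abc"), ["A", "A", "P"], self.schema),
            pset("m2", list("abc"), ["L", "A", "U"], self.schema),
        ])
        embs = make_embeddings(["e1"], list("abc"), dim=4)
        embs += make_embeddings(["e2"], list("ab"), dim=4)  # missing "c"
        with pytest.raises(KeyError, match="e2.*'c'"):
            build_fusion_training_set(split, embs, self.truth)


class TestFuseAverage:
    def test_identical_rows_fuse_to_that_row(self):
        head = AverageFusionHead(d=3, n_classes=4, seed=0)
        row = np.array([1.0, -2.0, 0.5])
        stack = np.tile(row, (3, 1))
        expected = softmax(head.W @ row + head.b)
        np.testing.assert_allclose(fuse_average(stack, head), expected)

    def test_opposite_rows_cancel_to_uniform_with_zero_bias(self):
        head = AverageFusionHead(d=3, n_classes=4, seed=0)
        r = np.array([2.0, 1.0, -1.0])
        probs = fuse_average(np.stack([r, -r]), head)
        np.testing.assert_allclose(probs, np.full(4, 0.25), atol=1e-12)

    def test_zero_weights_give_uniform(self):
        head = AverageFusionHead(d=5, n_classes=4, seed=0)
        head.W[:] = 0.0
        probs = fuse_average(np.random.default_rng(0).normal(size=(3, 5)), head)
        np.testing.assert_allclose(probs, np.full(4, 0.25))


class TestFuseAttention:
    def test_identical_rows_give_uniform_weights(self):
        head = AttentionFusionHead(d=4, n_classes=4, hidden=6, seed=1)
        stack = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (5, 1))
        _, weights = fuse_attention(stack, head)
        np.testing.assert_allclose(weights, np.full(5, 0.2), atol=1e-12)

    def test_weights_sum_to_one(self):
        head = AttentionFusionHead(d=8, n_classes=4, hidden=6, seed=2)
        rng = np.random.default_rng(3)
        for _ in range(10):
            _, w = fuse_attention(rng.normal(size=(4, 8)), head)
            assert np.isclose(w.sum(), 1.0, atol=1e-6)

    def test_hand_computed_softmax_on_2x2_stack(self):
        head = AttentionFusionHead(d=2, n_classes=4, hidden=2, seed=0)
        head.Wa[:] = np.array([[1.0, 0.0], [0.0, 1.0]])
        head.va[:] = np.array([1.0, -1.0])
        stack = np.array([[0.5, -0.5], [1.0, 1.0]])
        # scores: v . tanh(Wa e_k) = tanh(e_k1) - tanh(e_k2)
        s = np.array([np.tanh(0.5) - np.tanh(-0.5), np.tanh(1.0) - np.tanh(1.0)])
        expected = np.exp(s) / np.exp(s).sum()
        _, w = fuse_attention(stack, head)
        np.testing.assert_allclose(w, expected, atol=1e-12)


def brute_force_conv(stack, filt, bias):
    """Dense loop oracle for one valid-mode 2-D convolution filter."""
    K, d = stack.shape
    h, w = filt.shape
    out = np.empty((K - h + 1, d - w + 1))
    for i in range(K - h + 1):
        for j in range(d - w + 1):
            out[i, j] = np.sum(stack[i:i + h, j:j + w] * filt) + bias
    return out


class TestFuseCNN:
    def test_zero_stack_zero_params_give_uniform(self):
        head = CNNFusionHead(d=6, n_classes=4, n_encoders=3,
                             filter_heights=(2,), filter_width=3,
                             n_filters=2, seed=0)
        head.Wo[:] = 0.0
        probs = fuse_cnn(np.zeros((3, 6)), head)
        np.testing.assert_allclose(probs, np.full(4, 0.25))

    def test_pooled_feature_matches_brute_force_oracle(self):
        head = CNNFusionHead(d=3, n_classes=4, n_encoders=2,
                             filter_heights=(2,), filter_width=2,
                             n_filters=1, dropout=0.0, seed=0)
        filt = np.array([[1.0, -1.0], [0.5, 2.0]])
        head.filters[2][0] = filt
        head.biases[2][0] = 0.25
        stack = np.array([[1.0, 2.0, -1.0], [0.0, -0.5, 3.0]])
        expected = max(0.0, brute_force_conv(stack, filt, 0.25).max())
        pooled = head.pooled_features(stack[None])[0, 0]
        assert pooled == pytest.approx(expected, abs=1e-12)

    def test_filter_height_exceeding_encoders_rejected(self):
        with pytest.raises(ValueError, match="height"):
            CNNFusionHead(d=8, n_classes=4, n_encoders=2, filter_heights=(3,))

    def test_dropout_inactive_at_inference(self):
        head = CNNFusionHead(d=8, n_classes=4, n_encoders=3, dropout=0.9,
                             filter_width=3, n_filters=4, seed=1)
        stack = np.random.default_rng(0).normal(size=(3, 8))
        p1 = fuse_cnn(stack, head)
        head.dropout = 0.0
        p2 = fuse_cnn(stack, head)
        np.testing.assert_array_equal(p1, p2)


def numerical_grad(head, X, y, param, eps=1e-6):
    """Central-difference gradient of the mean CE loss w.r.t. one array."""
    g = np.zeros_like(param)
    it = np.nditer(param, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = param[idx]
        param[idx] = orig + eps
        lp, _ = loss_and_grad_logits(head.forward_batch(X)[0], y)
        param[idx] = orig - eps
        lm, _ = loss_and_grad_logits(head.forward_batch(X)[0], y)
        param[idx] = orig
        g[idx] = (lp - lm) / (2 * eps)
        it.iternext()
    return g


@pytest.mark.parametrize("make_head", [
    lambda: AverageFusionHead(d=5, n_classes=3, seed=4),
    lambda: AttentionFusionHead(d=5, n_classes=3, hidden=4, seed=4),
    lambda: CNNFusionHead(d=5, n_classes=3, n_encoders=3, filter_heights=(2,),
                          filter_width=3, n_filters=2, dropout=0.0, seed=4),
], ids=["average", "attention", "cnn"])
def test_analytic_gradients_match_numerical(make_head):
    """The hand-derived backward passes agree with central differences."""
    head = make_head()
    rng = np.random.default_rng(7)
    X = rng.normal(size=(6, 3, 5))
    y = rng.integers(0, 3, size=6)
    logits, cache = head.forward_batch(X)
    _, dlogits = loss_and_grad_logits(logits, y)
    grads = head.backward(cache, dlogits)
    for name, param in head.params.items():
        num = numerical_grad(head, X, y, param)
        np.testing.assert_allclose(grads[name], num, atol=1e-6,
                                   err_msg=f"param {name}")


def separable_training_set(n=120, d=8, K=3, seed=0):
    rng = np.random.default_rng(seed)
    schema = LabelSchema()
    labels = [schema.labels[i % 4] for i in range(n)]
    stacks = rng.normal(0.0, 0.05, size=(n, K, d))
    for i, lab in enumerate(labels):
        stacks[i, :, schema.index(lab)] += 3.0
    from portalfusion.fusion import FusionTrainingSet

    ids = tuple(f"m{i}" for i in range(n))
    return FusionTrainingSet(ids, stacks, tuple(labels), tuple(f"e{k}" for k in range(K)))


class TestTrainFusion:
    @pytest.mark.parametrize("strategy", ["average", "attention", "cnn"])
    def test_separable_stacks_high_training_accuracy(self, strategy):
        ts = separable_training_set()
        cfg = FusionConfig(strategy=strategy, filter_width=3,
                           training=TrainConfig(lr=0.02, epochs=300))
        fitted = train_fusion(cfg, ts, RebalanceSpec("none"))
        probs = fitted.head.predict_proba(ts.stacks)
        pred = [fitted.schema.labels[i] for i in probs.argmax(axis=1)]
        acc = np.mean([p == t for p, t in zip(pred, ts.labels)])
        assert acc >= 0.95

    def test_same_seed_identical_parameters(self):
        ts = separable_training_set()
        cfg = FusionConfig(strategy="cnn", filter_width=3,
                           training=TrainConfig(epochs=40, seed=5))
        f1 = train_fusion(cfg, ts, RebalanceSpec("focal"))
        f2 = train_fusion(cfg, ts, RebalanceSpec("focal"))
        for k in f1.head.params:
            np.testing.assert_array_equal(f1.head.params[k], f2.head.params[k])

    def test_empty_training_set_instructs_fallback(self):
        from portalfusion.fusion import FusionTrainingSet

        ts = FusionTrainingSet((), np.empty((0, 2, 4)), (), ("e1", "e2"))
        with pytest.raises(ValueError, match="fallback"):
            train_fusion(FusionConfig(strategy="average"), ts)

    def test_single_class_rejected(self):
        from portalfusion.fusion import FusionTrainingSet

        ts = FusionTrainingSet(("a", "b"), np.zeros((2, 2, 4)), ("A", "A"),
                               ("e1", "e2"))
        with pytest.raises(ValueError, match="2 classes"):
            train_fusion(FusionConfig(strategy="average"), ts,
                         schema=LabelSchema())


class TestCombinePredictions:
    def test_bookkeeping_and_provenance(self, schema):
        split = split_by_agreement([
            pset("m1", list("abc"), ["A", "L", "P"], schema),
            pset("m2", list("abc"), ["A", "L", "U"], schema),
        ])
        assert split.disagreed == ("c",)
        fused = PredictionSet("f", schema, ("c",),
                              np.array([[0.1, 0.2, 0.6, 0.1]]))
        final = combine_predictions(split, fused)
        assert final.ids == ("a", "b", "c")
        assert final.labels == ("A", "L", "P")
        assert final.source == ("consensus", "consensus", "fusion")
        np.testing.assert_allclose(final.probs[0], [1, 0, 0, 0])

    def test_every_label_from_exactly_one_source(self, schema):
        rng = np.random.default_rng(0)
        ids = [f"m{i}" for i in range(30)]
        la = [rng.choice(list("ALPU")) for _ in ids]
        lb = [rng.choice(list("ALPU")) for _ in ids]
        split = split_by_agreement([pset("m1", ids, la, schema),
                                    pset("m2", ids, lb, schema)])
        probs = rng.dirichlet(np.ones(4), size=len(split.disagreed))
        fused = PredictionSet("f", schema, split.disagreed, probs)
        final = combine_predictions(split, fused)
        consensus_ids = set(split.agreed_ids)
        for i, src in zip(final.ids, final.source):
            assert (src == "consensus") == (i in consensus_ids)
            assert (src == "fusion") == (i in set(split.disagreed))

    def test_empty_disagreed_gives_consensus_only(self, schema):
        split = split_by_agreement([pset("m1", ["a"], ["U"], schema),
                                    pset("m2", ["a"], ["U"], schema)])
        fused = PredictionSet("f", schema, (), np.empty((0, 4)))
        final = combine_predictions(split, fused)
        assert final.labels == ("U",) and final.source == ("consensus",)

    def test_empty_agreed_gives_fusion_only(self, schema):
        split = split_by_agreement([pset("m1", ["a"], ["U"], schema),
                                    pset("m2", ["a"], ["A"], schema)])
        fused = PredictionSet("f", schema, ("a",), np.array([[0.7, 0.1, 0.1, 0.1]]))
        final = combine_predictions(split, fused)
        assert final.labels == ("A",) and final.source == ("fusion",)

    def test_coverage_mismatch_rejected(self, schema):
        split = split_by_agreement([pset("m1", list("ab"), ["A", "L"], schema),
                                    pset("m2", list("ab"), ["A", "P"], schema)])
        wrong = PredictionSet("f", schema, ("a",), np.array([[1.0, 0, 0, 0]]))
        with pytest.raises(ValueError, match="disagreed"):
            combine_predictions(split, wrong)


def test_predict_fusion_replays_projection_and_order(schema):
    """predict_fusion rebuilds stacks exactly as the training-set builder."""
    truth = Corpus(schema, [Message(i, "t", lab) for i, lab in
                            zip("abcd", ["A", "L", "P", "U"])])
    split = split_by_agreement([
        pset("m1", list("abcd"), ["A", "A", "P", "U"], schema),
        pset("m2", list("abcd"), ["L", "A", "L", "A"], schema),
    ])
    embs = make_embeddings(["e1", "e2"], list("abcd"), dim=4, seed=9)
    ts = build_fusion_training_set(split, embs, truth)
    cfg = FusionConfig(strategy="average", training=TrainConfig(epochs=30))
    fitted = train_fusion(cfg, ts, schema=schema)
    out = predict_fusion(fitted, embs, ts.ids)
    direct = fitted.head.predict_proba(ts.stacks)
    np.testing.assert_allclose(out.probs, direct)
    assert out.source == tuple("fusion" for _ in ts.ids)
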