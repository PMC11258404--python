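"""Metrics, repeated-CV aggregation, model selection, bucket analysis.

Scores are accuracy plus per-class and macro-averaged precision /
recall / F1 (macro = unweighted mean over all schema classes, so rare
classes count as much as the dominant one).  Run-level scores from the
k folds x r repeats are aggregated as mean, sample SD and a t-based
95% confidence interval.  The disagreement-bucket analysis groups test
messages by how many distinct labels the three baselines predicted
(buckets named 0, 2 and 3) and compares per-model accuracy inside each
bucket.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support

from ._optim import TrainConfig
from .corpus import Corpus, FoldPlan, LabelSchema
from .encoders import (
    EmbeddingSet,
    EncoderSpec,
    PredictionSet,
    encode,
    fine_tune,
    predict,
)
from .ensemble import ensemble_predict
from .fusion import (
    FusionConfig,
    build_fusion_training_set,
    combine_predictions,
    predict_fusion,
    split_by_agreement,
    train_fusion,
)
from .rebalance import RebalanceSpec

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "AggregateReport",
    "BucketReport",
    "ExperimentResult",
    "compute_metrics",
    "aggregate_runs",
    "bucket_by_distinct_labels",
    "select_best_per_category",
    "run_experiment",
    "SingleSplitResult",
    "routed_fusion_single_split",
    "benchmark_complementary_fusion",
]

METRICS = ("accuracy", "macro_precision", "macro_recall", "macro_f1")


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy plus per-class and macro precision/recall/F1."""

    accuracy: float
    per_class: Mapping[str, tuple[float, float, float]]  # label -> (P, R, F1)
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }


def compute_metrics(
    truth: Sequence[str], preds: Sequence[str], schema: LabelSchema
) -> MetricsReport:
    """Confusion-matrix metrics over aligned truth/prediction sequences.

    Classes with a zero denominator (never predicted, or absent from
    the truth) score 0 for the affected metric, with a logged warning;
    macro averages run over ALL schema classes regardless.
    """
    if len(truth) != len(preds):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(preds)} preds")
    if len(truth) == 0:
        raise ValueError("cannot score an empty evaluation set")
    labels = list(schema.labels)
    p, r, f1, support = precision_recall_fscore_support(
        truth, preds, labels=labels, zero_division=0
    )
    predicted = set(preds)
    degenerate = [
        lab for lab, s in zip(labels, support) if s == 0 or lab not in predicted
    ]
    if degenerate:
        logger.warning(
            "zero-denominator classes scored 0 in precision/recall: %s", degenerate
        )
    accuracy = float(np.mean(np.asarray(truth) == np.asarray(preds)))
    per_class = {
        lab: (float(p[i]), float(r[i]), float(f1[i])) for i, lab in enumerate(labels)
    }
    return MetricsReport(
        accuracy=accuracy,
        per_class=per_class,
        macro_precision=float(np.mean(p)),
        macro_recall=float(np.mean(r)),
        macro_f1=float(np.mean(f1)),
        n=len(truth),
    )


@dataclass(frozen=True)
class AggregateStats:
    mean: float
    sd: float
    ci_lo: float
    ci_hi: float
    n_runs: int


def aggregate_runs(
    scores: Sequence[float], confidence: float = 0.95, normal: bool = False
) -> AggregateStats:
    """Mean, sample SD (n-1) and confidence interval over run scores.

    The interval is ``mean +/- t_{(1+c)/2, n-1} * SD / sqrt(n)`` by
    default; ``normal=True`` swaps the t quantile for the normal one.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n < 2:
        raise ValueError("need at least 2 run scores to aggregate")
    mean = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1))
    q = (1.0 + confidence) / 2.0
    crit = float(stats.norm.ppf(q)) if normal else float(stats.t.ppf(q, n - 1))
    half = crit * sd / np.sqrt(n)
    return AggregateStats(mean, sd, mean - half, mean + half, n)


@dataclass
class AggregateReport:
    """Per-metric aggregate statistics with run-level scores retained."""

    model: str
    stats: dict[str, AggregateStats]
    run_scores: pd.DataFrame  # columns: repeat, fold, metric, value

    def mean(self, metric: str) -> float:
        return self.stats[metric].mean


def bucket_by_distinct_labels(
    preds: Sequence[PredictionSet],
) -> dict[str, int]:
    """Map each id to its disagreement bucket: 0, 2 or 3.

    The bucket is the number of *distinct* labels among the three
    baseline predictions, using the convention that unanimity is
    bucket 0 (not 1).  Defined for exactly three baselines.
    """
    if len(preds) != 3:
        raise ValueError(f"bucket scheme is defined for 3 baselines, got {len(preds)}")
    base = set(preds[0].ids)
    for p in preds[1:]:
        if set(p.ids) != base:
            raise ValueError("prediction sets must cover identical ids")
    maps = [dict(zip(p.ids, p.labels)) for p in preds]
    out: dict[str, int] = {}
    for i in preds[0].ids:
        distinct = len({m[i] for m in maps})
        out[i] = 0 if distinct == 1 else distinct
    return out


@dataclass
class BucketReport:
    """Counts and per-model accuracy inside each disagreement bucket."""

    counts: dict[int, int]
    correct: dict[tuple[str, int], int]  # (model, bucket) -> n correct

    def accuracy(self, model: str, bucket: int) -> float:
        n = self.counts.get(bucket, 0)
        return self.correct.get((model, bucket), 0) / n if n else float("nan")

    def models(self) -> list[str]:
        return sorted({m for m, _ in self.correct})

    def overall_accuracy(self, model: str) -> float:
        total = sum(self.counts.values())
        hits = sum(self.correct.get((model, b), 0) for b in self.counts)
        return hits / total if total else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in sorted(self.counts):
            for m in self.models():
                rows.append(
                    {"bucket": b, "n": self.counts[b], "model": m,
                     "accuracy": self.accuracy(m, b)}
                )
        return pd.DataFrame(rows)


def select_best_per_category(
    aggregates: Mapping[str, AggregateReport],
    categories: Mapping[str, str],
) -> dict[str, str]:
    """Top model per encoder category by mean macro-F1 (accuracy breaks ties)."""
    by_cat: dict[str, list[str]] = {}
    for model, cat in categories.items():
        by_cat.setdefault(cat, []).append(model)
    out: dict[str, str] = {}
    for cat, models in by_cat.items():
        if not models:
            raise ValueError(f"category {cat!r} is empty")
        out[cat] = max(
            sorted(models),
            key=lambda m: (
                round(aggregates[m].mean("macro_f1"), 12),
                round(aggregates[m].mean("accuracy"), 12),
            ),
        )
    return out


@dataclass
class AuditRecord:
    """Id-level audit of one (repeat, fold) run for leakage checks."""

    repeat: int
    fold: int
    test_ids: frozenset[str]
    baseline_train_ids: frozenset[str]
    fusion_train_ids: frozenset[str]


@dataclass
class ExperimentResult:
    run_scores: pd.DataFrame  # model, repeat, fold, metric, value
    aggregates: dict[str, AggregateReport]
    bucket_report: BucketReport | None
    audit: list[AuditRecord] = field(default_factory=list)

    def aggregated_frame(self) -> pd.DataFrame:
        rows = []
        for model, rep in sorted(self.aggregates.items()):
            for metric, s in rep.stats.items():
                rows.append(
                    {"model": model, "metric": metric, "mean": s.mean,
                     "sd": s.sd, "ci_lo": s.ci_lo, "ci_hi": s.ci_hi}
                )
        return pd.DataFrame(rows)


def _derived_seed(base: int, repeat: int, fold: int, salt: int = 0) -> int:
    return (base * 9973 + repeat * 1009 + fold * 101 + salt * 7) % (2**31 - 1)


def run_experiment(
    corpus: Corpus,
    encoder_specs: Sequence[EncoderSpec],
    fusion_config: FusionConfig,
    rebalance: RebalanceSpec | None = None,
    fold_plan: FoldPlan | None = None,
    precomputed: Mapping[str, EmbeddingSet] | None = None,
    hyper: TrainConfig | None = None,
    with_ensemble: bool = True,
) -> ExperimentResult:
    """The full repeated-CV pipeline over a labeled corpus.

    For every (repeat, fold): fine-tune one baseline per encoder on the
    training split, split both splits by baseline agreement, train the
    fusion head on the training split's disagreement subset (gold
    labels), route the test split (consensus for agreed ids, fusion for
    disagreed), and score every model on the untouched test fold.
    Scores are aggregated over all runs; with exactly three baselines a
    pooled disagreement-bucket report is also produced.

    If a training split yields no usable disagreement set (baselines
    agree everywhere, or the disagreed messages span a single class)
    the fusion path for that fold degrades to the majority vote of the
    baselines, with a prominent log message.
    """
    from .corpus import make_fold_plan  # local import avoids cycle at module load

    rebalance = rebalance or RebalanceSpec()
    fold_plan = fold_plan or make_fold_plan(corpus)
    precomputed = dict(precomputed or {})
    base_seed = fold_plan.seed

    # Frozen encoders: embed the whole corpus once per encoder.
    full_emb: dict[str, EmbeddingSet] = {}
    for spec in encoder_specs:
        full_emb[spec.name] = (
            precomputed[spec.name]
            if spec.name in precomputed
            else encode(spec, corpus.messages)
        )

    rows: list[dict] = []
    audit: list[AuditRecord] = []
    do_buckets = len(encoder_specs) == 3
    bucket_counts: dict[int, int] = {}
    bucket_correct: dict[tuple[str, int], int] = {}
    truth_of = {m.id: m.label for m in corpus}

    for r in range(fold_plan.n_repeats):
        for fold in range(fold_plan.n_folds):
            train_ids, test_ids = fold_plan.train_test_ids(r, fold)
            train_corpus = corpus.subset(train_ids)
            test_msgs = corpus.subset(test_ids).messages

            baselines = {}
            train_preds, test_preds = [], []
            train_ids_used: set[str] = set()
            for j, spec in enumerate(encoder_specs):
                seed = _derived_seed(base_seed, r, fold, salt=j + 1)
                model = fine_tune(
                    spec, train_corpus, rebalance, hyper, seed=seed,
                    embeddings=full_emb[spec.name],
                )
                baselines[spec.name] = model
                train_ids_used.update(model.metadata["train_ids"])
                train_preds.append(
                    predict(model, train_corpus.messages,
                            embeddings=full_emb[spec.name])
                )
                test_preds.append(
                    predict(model, test_msgs, embeddings=full_emb[spec.name])
                )

            train_split = split_by_agreement(train_preds)
            test_split = split_by_agreement(test_preds)
            emb_list = [full_emb[s.name] for s in encoder_specs]

            fusion_train_ids: frozenset[str] = frozenset()
            fused_test: PredictionSet | None = None
            train_set = build_fusion_training_set(
                train_split, emb_list, train_corpus
            )
            if len(train_set.ids) >= 2 and len(set(train_set.labels)) >= 2:
                cfg = replace_training_seed(
                    fusion_config, _derived_seed(base_seed, r, fold, salt=0)
                )
                fitted = train_fusion(cfg, train_set, rebalance,
                                      schema=corpus.schema)
                fusion_train_ids = frozenset(train_set.ids)
                fused_test = predict_fusion(fitted, emb_list, test_split.disagreed)
            else:
                logger.warning(
                    "repeat %d fold %d: unusable fusion training set "
                    "(%d disagreed ids); falling back to majority vote for "
                    "disagreed test messages", r, fold, len(train_set.ids),
                )
                if test_split.disagreed:
                    mv = ensemble_predict(test_preds, name="fusion_fallback")
                    keep = [mv.ids.index(i) for i in test_split.disagreed]
                    fused_test = PredictionSet(
                        "fusion_fallback", corpus.schema, test_split.disagreed,
                        mv.probs[keep],
                    )
                else:
                    fused_test = PredictionSet(
                        "fusion_fallback", corpus.schema, (),
                        np.empty((0, len(corpus.schema))),
                    )
            final = combine_predictions(test_split, fused_test)

            scored: dict[str, PredictionSet] = {
                p.model_name: p for p in test_preds
            }
            scored["fusion"] = final
            if with_ensemble and len(test_preds) >= 2:
                scored["majority_vote"] = ensemble_predict(test_preds)

            truth = [truth_of[i] for i in test_ids]
            for name, pset in scored.items():
                lab_of = dict(zip(pset.ids, pset.labels))
                preds_aligned = [lab_of[i] for i in test_ids]
                rep = compute_metrics(truth, preds_aligned, corpus.schema)
                for metric, value in rep.as_dict().items():
                    rows.append(
                        {"model": name, "repeat": r, "fold": fold,
                         "metric": metric, "value": value}
                    )

            if do_buckets:
                buckets = bucket_by_distinct_labels(test_preds)
                for i, b in buckets.items():
                    bucket_counts[b] = bucket_counts.get(b, 0) + 1
                for name, pset in scored.items():
                    lab_of = dict(zip(pset.ids, pset.labels))
                    for i, b in buckets.items():
                        if lab_of[i] == truth_of[i]:
                            key = (name, b)
                            bucket_correct[key] = bucket_correct.get(key, 0) + 1

            audit.append(
                AuditRecord(
                    repeat=r, fold=fold, test_ids=frozenset(test_ids),
                    baseline_train_ids=frozenset(train_ids_used),
                    fusion_train_ids=fusion_train_ids,
                )
            )

    run_scores = pd.DataFrame(rows)
    aggregates: dict[str, AggregateReport] = {}
    for model, grp in run_scores.groupby("model"):
        stats_by_metric = {
            metric: aggregate_runs(sub["value"].to_numpy())
            for metric, sub in grp.groupby("metric")
        }
        aggregates[model] = AggregateReport(model, stats_by_metric,
                                            grp.reset_index(drop=True))
    bucket_report = (
        BucketReport(bucket_counts, bucket_correct) if do_buckets else None
    )
    return ExperimentResult(run_scores, aggregates, bucket_report, audit)


def replace_training_seed(config: FusionConfig, seed: int) -> FusionConfig:
    """Copy of a fusion config with the training seed swapped."""
    from dataclasses import replace

    return replace(config, training=TrainConfig(
        config.training.lr, config.training.epochs,
        config.training.batch_size, seed,
    ))


@dataclass
class SingleSplitResult:
    """Routed-fusion pipeline scored on one held-out split."""

    fusion: MetricsReport
    baselines: dict[str, MetricsReport]
    best_baseline: str
    bucket_gains: dict[int, float]  # fusion acc minus best-baseline acc
    bucket_counts: dict[int, int]
    disagreement_rate_train: float
    disagreement_rate_test: float
    final: PredictionSet

    @property
    def macro_f1_gain(self) -> float:
        return self.fusion.macro_f1 - self.baselines[self.best_baseline].macro_f1


def routed_fusion_single_split(
    corpus: Corpus,
    encoder_specs: Sequence[EncoderSpec],
    fusion_config: FusionConfig,
    rebalance: RebalanceSpec | None = None,
    precomputed: Mapping[str, EmbeddingSet] | None = None,
    hyper: TrainConfig | None = None,
    seed: int = 0,
    train_frac: float = 0.7,
) -> SingleSplitResult:
    """Train and score the routed-fusion pipeline on one random split.

    A lighter-weight companion to :func:`run_experiment` for benchmark
    comparisons: one shuffled train/test split (seeded), baselines
    fine-tuned on the training side, fusion trained on the training
    side's disagreement subset, everything scored on the held-out side.
    Bucket gains compare the routed pipeline's accuracy with the best
    single baseline's (by test macro-F1) inside each disagreement
    bucket; with other than three encoders buckets are skipped.
    """
    rebalance = rebalance or RebalanceSpec()
    precomputed = dict(precomputed or {})
    full_emb = {
        spec.name: precomputed.get(spec.name) or encode(spec, corpus.messages)
        for spec in encoder_specs
    }
    rng = np.random.default_rng(seed)
    ids = np.array(corpus.ids)
    rng.shuffle(ids)
    n_train = int(train_frac * len(ids))
    train_corpus = corpus.subset(ids[:n_train].tolist())
    test_corpus = corpus.subset(ids[n_train:].tolist())

    train_preds, test_preds = [], []
    for j, spec in enumerate(encoder_specs):
        model = fine_tune(spec, train_corpus, rebalance, hyper,
                          seed=_derived_seed(seed, 0, 0, salt=j + 1),
                          embeddings=full_emb[spec.name])
        train_preds.append(predict(model, train_corpus.messages,
                                   embeddings=full_emb[spec.name]))
        test_preds.append(predict(model, test_corpus.messages,
                                  embeddings=full_emb[spec.name]))

    train_split = split_by_agreement(train_preds)
    test_split = split_by_agreement(test_preds)
    emb_list = [full_emb[s.name] for s in encoder_specs]
    train_set = build_fusion_training_set(train_split, emb_list, train_corpus)
    if len(train_set.ids) >= 2 and len(set(train_set.labels)) >= 2:
        cfg = replace_training_seed(fusion_config, _derived_seed(seed, 0, 0))
        fitted = train_fusion(cfg, train_set, rebalance, schema=corpus.schema)
        fused = predict_fusion(fitted, emb_list, test_split.disagreed)
    else:
        logger.warning("single split: unusable fusion training set; "
                       "falling back to majority vote")
        mv = ensemble_predict(test_preds, name="fusion_fallback")
        keep = [mv.ids.index(i) for i in test_split.disagreed]
        fused = PredictionSet("fusion_fallback", corpus.schema,
                              test_split.disagreed, mv.probs[keep])
    final = combine_predictions(test_split, fused)

    truth_of = {m.id: m.label for m in test_corpus}
    truth = [truth_of[i] for i in final.ids]
    fusion_rep = compute_metrics(truth, list(final.labels), corpus.schema)
    baseline_reps = {}
    for p in test_preds:
        lab_of = dict(zip(p.ids, p.labels))
        baseline_reps[p.model_name] = compute_metrics(
            truth, [lab_of[i] for i in final.ids], corpus.schema
        )
    best = max(sorted(baseline_reps),
               key=lambda m: baseline_reps[m].macro_f1)

    bucket_gains: dict[int, float] = {}
    bucket_counts: dict[int, int] = {}
    if len(encoder_specs) == 3:
        buckets = bucket_by_distinct_labels(test_preds)
        final_lab = dict(zip(final.ids, final.labels))
        best_pred = next(p for p in test_preds if p.model_name == best)
        best_lab = dict(zip(best_pred.ids, best_pred.labels))
        for b in (0, 2, 3):
            ids_b = [i for i, v in buckets.items() if v == b]
            bucket_counts[b] = len(ids_b)
            if ids_b:
                acc_f = float(np.mean([final_lab[i] == truth_of[i] for i in ids_b]))
                acc_b = float(np.mean([best_lab[i] == truth_of[i] for i in ids_b]))
                bucket_gains[b] = acc_f - acc_b
    return SingleSplitResult(
        fusion=fusion_rep,
        baselines=baseline_reps,
        best_baseline=best,
        bucket_gains=bucket_gains,
        bucket_counts=bucket_counts,
        disagreement_rate_train=len(train_split.disagreed) / max(len(train_corpus), 1),
        disagreement_rate_test=len(test_split.disagreed) / max(len(test_corpus), 1),
        final=final,
    )


def benchmark_complementary_fusion(
    seed: int, n: int = 2000, strategy: str = "cnn"
) -> SingleSplitResult:
    """The standard synthetic benchmark of the routed-fusion pipeline.

    Three complementary encoders (one strong on A and U, one on P, one
    on L) at signal-to-noise 3, a 70/30 split, class-weight rebalancing
    and a CNN fusion head — the regime in which routing disagreeing
    messages to a fusion head should beat every single baseline,
    concentrated in the disagreement buckets.
    """
    from .synthetic import SyntheticConfig, generate_dataset

    config = SyntheticConfig(n=n, seed=seed)
    corpus, embeddings = generate_dataset(config)
    specs = [
        EncoderSpec(name=name, category=cat, dim=config.dim,
                    backend="precomputed")
        for name, cat in zip(sorted(embeddings), ("generic", "domain", "source"))
    ]
    return routed_fusion_single_split(
        corpus,
        specs,
        FusionConfig(strategy=strategy,
                     training=TrainConfig(lr=0.05, epochs=150)),
        RebalanceSpec("class_weight"),
        precomputed=embeddings,
        hyper=TrainConfig(epochs=300),
        seed=seed,
    )
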