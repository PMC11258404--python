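"""Labeled message corpora: data model, I/O, class statistics, fold planning.

A corpus is the unit every split and metric in this package is defined
over: a list of uniquely-identified short free-text messages, each
optionally carrying a single primary-concern label from a fixed schema.
The default schema is the four-class A / L / P / U scheme (active
symptoms, logistics, prescriptions, other/updates); the schema's
ascending lexicographic order doubles as the tie-break order used by
majority voting and argmax prediction throughout the package.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LabelSchema",
    "Message",
    "Corpus",
    "FoldPlan",
    "load_corpus",
    "write_corpus",
    "class_distribution",
    "make_fold_plan",
]

DEFAULT_LABELS = ("A", "L", "P", "U")


@dataclass(frozen=True)
class LabelSchema:
    """Ordered set of class labels.

    Labels are stored in ascending lexicographic order; that order IS
    the tie-break order (alphabetical-first) used by voting and argmax.
    """

    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        if not labels:
            raise ValueError("schema must contain at least one label")
        if len(set(labels)) != len(labels):
            raise ValueError(f"schema labels must be unique, got {labels!r}")
        object.__setattr__(self, "labels", tuple(sorted(labels)))

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValueError(f"label {label!r} not in schema {self.labels!r}") from None


@dataclass(frozen=True)
class Message:
    id: str
    text: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("message id must be non-empty")


@dataclass
class Corpus:
    """A list of messages with unique ids under a shared label schema."""

    schema: LabelSchema
    messages: list[Message] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.messages:
            if m.id in seen:
                raise ValueError(f"duplicate message id {m.id!r}")
            seen.add(m.id)
            if m.label is not None and m.label not in self.schema:
                raise ValueError(
                    f"message {m.id!r} has label {m.label!r} not in schema "
                    f"{self.schema.labels!r}"
                )

    def __len__(self) -> int:
        return len(self.messages)

    def __iter__(self):
        return iter(self.messages)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.messages]

    def labels(self) -> list[str]:
        """Labels of all messages; raises if any message is unlabeled."""
        missing = [m.id for m in self.messages if m.label is None]
        if missing:
            raise ValueError(f"unlabeled messages present: {missing}")
        return [m.label for m in self.messages]  # type: ignore[misc]

    def subset(self, ids: Iterable[str]) -> "Corpus":
        """Messages with the given ids, in the corpus's original order."""
        wanted = set(ids)
        unknown = wanted - set(self.ids)
        if unknown:
            raise KeyError(f"ids not in corpus: {sorted(unknown)}")
        return Corpus(self.schema, [m for m in self.messages if m.id in wanted])

    def __getitem__(self, msg_id: str) -> Message:
        for m in self.messages:
            if m.id == msg_id:
                return m
        raise KeyError(msg_id)


def load_corpus(
    path: str | Path,
    format: str | None = None,
    schema: LabelSchema | None = None,
) -> Corpus:
    """Read a corpus from JSONL (canonical) or CSV.

    JSONL records carry keys ``id``, ``text`` and optionally ``label``;
    CSV files carry a header row ``id,text,label`` (RFC-4180 quoting,
    UTF-8).  Record order is preserved.  Duplicate ids and labels
    outside the schema are hard errors naming the offender.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format {format!r}")
    schema = schema or LabelSchema()

    messages: list[Message] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                if "id" not in rec or "text" not in rec:
                    raise ValueError(f"{path}:{lineno}: record needs 'id' and 'text'")
                messages.append(
                    Message(str(rec["id"]), str(rec["text"]), rec.get("label"))
                )
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for rec in reader:
                if rec.get("id") is None or rec.get("text") is None:
                    raise ValueError(f"{path}: CSV needs 'id' and 'text' columns")
                label = rec.get("label") or None
                messages.append(Message(rec["id"], rec["text"], label))
    return Corpus(schema, messages)


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus as JSONL or CSV (inverse of :func:`load_corpus`)."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for m in corpus:
                rec = {"id": m.id, "text": m.text}
                if m.label is not None:
                    rec["label"] = m.label
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "text", "label"])
            for m in corpus:
                writer.writerow([m.id, m.text, m.label or ""])
    else:
        raise ValueError(f"unknown corpus format {format!r}")


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1") ** ndigits, ROUND_HALF_UP))


def class_distribution(corpus: Corpus) -> dict[str, tuple[int, float]]:
    """Per-label (count, percent) with percents rounded half-up to 1 decimal.

    Percents are 100*count/total; e.g. 991 of 2239 reports as 44.3.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    unlabeled = [m.id for m in corpus if m.label is None]
    if unlabeled:
        raise ValueError(f"unlabeled messages present: {unlabeled}")
    total = len(corpus)
    out: dict[str, tuple[int, float]] = {}
    for label in corpus.schema:
        count = sum(1 for m in corpus if m.label == label)
        out[label] = (count, _round_half_up(100.0 * count / total))
    return out


@dataclass(frozen=True)
class FoldPlan:
    """Repeated stratified k-fold assignment: (repeat, id) -> fold index."""

    n_folds: int
    n_repeats: int
    seed: int
    assignment: tuple[Mapping[str, int], ...]  # one mapping per repeat

    def fold_ids(self, repeat: int, fold: int) -> list[str]:
        return [i for i, f in self.assignment[repeat].items() if f == fold]

    def train_test_ids(self, repeat: int, fold: int) -> tuple[list[str], list[str]]:
        train = [i for i, f in self.assignment[repeat].items() if f != fold]
        test = [i for i, f in self.assignment[repeat].items() if f == fold]
        return train, test

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "assignment": [dict(a) for a in self.assignment],
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            payload["n_folds"],
            payload["n_repeats"],
            payload["seed"],
            tuple(payload["assignment"]),
        )


def make_fold_plan(
    corpus: Corpus,
    n_folds: int = 10,
    n_repeats: int = 3,
    seed: int = 0,
) -> FoldPlan:
    """Plan repeated stratified k-fold cross-validation.

    Per repeat ``r`` (seeded ``seed + r``), each class's ids are
    shuffled and dealt round-robin into folds through a single running
    cursor, so per-class fold counts differ by at most one AND overall
    fold sizes differ by at most one.  Same inputs give an identical
    plan.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    labels = corpus.labels()
    by_class: dict[str, list[str]] = {c: [] for c in corpus.schema}
    for m, lab in zip(corpus.messages, labels):
        by_class[lab].append(m.id)
    for c in corpus.schema:
        if 0 < len(by_class[c]) < n_folds:
            raise ValueError(
                f"class {c!r} has only {len(by_class[c])} members; "
                f"needs at least n_folds={n_folds}"
            )

    assignment: list[dict[str, int]] = []
    for r in range(n_repeats):
        rng = np.random.default_rng(seed + r)
        fold_of: dict[str, int] = {}
        cursor = 0
        for c in corpus.schema:  # fixed class order keeps the deal deterministic
            ids = list(by_class[c])
            rng.shuffle(ids)
            for i in ids:
                fold_of[i] = cursor % n_folds
                cursor += 1
        assignment.append(fold_of)
    return FoldPlan(n_folds, n_repeats, seed, tuple(assignment))
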