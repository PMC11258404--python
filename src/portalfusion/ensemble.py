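"""Majority-vote ensembles with alphabetical tie-breaking.

The voting rule: the plurality label wins; when several labels tie for
the top count, the tied label that comes first in the schema's
(alphabetical) order is chosen.  For three all-distinct votes under the
default schema this is the alphabetical-first rule (A, L, P, U).
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np

from .corpus import LabelSchema
from .encoders import PredictionSet

__all__ = ["majority_vote", "ensemble_predict"]


def majority_vote(labels: Sequence[str], schema: LabelSchema) -> str:
    """Plurality label; ties broken by schema (alphabetical) order."""
    if len(labels) < 2:
        raise ValueError("majority vote needs at least 2 votes")
    bad = [lab for lab in labels if lab not in schema]
    if bad:
        raise ValueError(f"labels outside schema: {bad}")
    counts = Counter(labels)
    top = max(counts.values())
    tied = [lab for lab, n in counts.items() if n == top]
    return min(tied, key=schema.index)


def ensemble_predict(members: Sequence[PredictionSet],
                     name: str = "majority_vote") -> PredictionSet:
    """Per-id majority vote over member predictions.

    The ensemble's probability vector is the vote share per label, so
    the schema-order argmax of the shares reproduces the tie-broken
    vote exactly.
    """
    if len(members) < 2:
        raise ValueError("ensemble needs at least 2 members")
    schema = members[0].schema
    base = set(members[0].ids)
    for m in members[1:]:
        diff = base.symmetric_difference(m.ids)
        if diff:
            raise ValueError(
                f"member prediction sets cover different ids: {sorted(diff)}"
            )
    label_maps = [dict(zip(m.ids, m.labels)) for m in members]
    ids = members[0].ids
    k = len(members)
    probs = np.zeros((len(ids), len(schema)))
    for n, i in enumerate(ids):
        for lab_map in label_maps:
            probs[n, schema.index(lab_map[i])] += 1.0 / k
    return PredictionSet(name, schema, ids, probs)
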