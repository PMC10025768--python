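"""Evaluation of annotation results.

All target-private cell types collapse to a single "unknown" class before
scoring.  Reported metrics: total accuracy over all cells; accuracy on cells
whose (collapsed) truth is a known type; accuracy on truly unknown cells;
and the H-score, the harmonic mean of the known and unknown accuracies
(0 when either side is 0, and None when the truth contains no unknown cells,
in which case a harmonic mean is undefined).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

UNKNOWN_LABEL = "unknown"


@dataclass
class EvalReport:
    total_accuracy: float
    known_accuracy: Optional[float]
    unknown_accuracy: Optional[float]
    h_score: Optional[float]
    per_class_accuracy: Dict[str, float]
    confusion: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "total_accuracy": self.total_accuracy,
            "known_accuracy": self.known_accuracy,
            "unknown_accuracy": self.unknown_accuracy,
            "h_score": self.h_score,
            "per_class_accuracy": self.per_class_accuracy,
        }


def collapse_private(truth: Sequence[str], known_set: Set[str]) -> List[str]:
    """Map every truth label outside the known set to 'unknown'."""
    known_set = set(known_set)
    return [t if t in known_set else UNKNOWN_LABEL for t in truth]


def evaluate(pred: Sequence[str], truth: Sequence[str], known_set: Set[str]) -> EvalReport:
    """Score predictions against (collapsed) truth labels by exact match."""
    if len(pred) != len(truth):
        raise ValueError("prediction and truth label lists differ in length")
    pred = list(pred)
    ctruth = collapse_private(truth, known_set)
    hits = np.array([p == t for p, t in zip(pred, ctruth)], dtype=float)
    total = float(hits.mean())

    is_unknown = np.array([t == UNKNOWN_LABEL for t in ctruth])
    known_acc = float(hits[~is_unknown].mean()) if (~is_unknown).any() else None
    unknown_acc = float(hits[is_unknown].mean()) if is_unknown.any() else None
    if unknown_acc is None:
        h = None
    else:
        ka = known_acc if known_acc is not None else 0.0
        h = 0.0 if ka + unknown_acc == 0 else 2.0 * ka * unknown_acc / (ka + unknown_acc)

    per_class = {}
    for cls in sorted(set(ctruth)):
        mask = np.array([t == cls for t in ctruth])
        per_class[cls] = float(hits[mask].mean())

    confusion = pd.crosstab(
        pd.Series(ctruth, name="truth"), pd.Series(pred, name="predicted")
    )
    return EvalReport(
        total_accuracy=total,
        known_accuracy=known_acc,
        unknown_accuracy=unknown_acc,
        h_score=h,
        per_class_accuracy=per_class,
        confusion=confusion,
    )
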