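"""Chart-review validation: dev/test sampling, dual-review adjudication, and
classification metrics against the adjudicated gold standard.

The protocol mirrors standard phenotyping validation: sample notes, split
into a development set (for rule refinement) and a held-out test set, have
two reviewers label each note independently, resolve disagreements by a
third review, then score the detector once on the test set.

Rounding to printed precision uses half-up (0.845 -> 0.85), computed in
exact integer arithmetic so borderline ratios are never misrounded.
Metrics with a zero denominator are reported as None, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .detector import MASH_POSITIVE, NoteLabel

POSITIVE = "positive"
NEGATIVE = "negative"
PENDING = "pending"


@dataclass(frozen=True)
class LabeledNote:
    note_id: str
    reviewer_a: str
    reviewer_b: str
    adjudicated: str = PENDING


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ValidationMetrics:
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    f1: float | None
    ppv: float | None
    n: int


def round_ratio_half_up(num: int, den: int, scale: int) -> int:
    """Half-up rounding of ``scale * num / den`` in exact integer arithmetic."""
    if den <= 0:
        raise ValueError("denominator must be positive")
    return (2 * scale * num + den) // (2 * den)


def sample_split(
    note_ids: Sequence[str],
    n_total: int = 300,
    n_dev: int = 150,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Uniformly sample ``n_total`` notes without replacement and split them
    into disjoint dev/test sets; reproducible given the seed."""
    ids = list(note_ids)
    if not 0 <= n_dev <= n_total:
        raise ValueError("need 0 <= n_dev <= n_total")
    if len(ids) < n_total:
        raise ValueError(
            f"corpus has {len(ids)} notes but {n_total} were requested"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=n_total, replace=False)
    sampled = [ids[i] for i in chosen]
    return {"dev": sampled[:n_dev], "test": sampled[n_dev:]}


def adjudicate(
    labels: Iterable[LabeledNote],
    third_review: Mapping[str, str] | None = None,
) -> list[LabeledNote]:
    """Resolve dual-review labels: agreements stand, disagreements take the
    third review.  Raises if any disagreement lacks a third-review label."""
    third_review = third_review or {}
    out: list[LabeledNote] = []
    uncovered: list[str] = []
    for lab in labels:
        if lab.reviewer_a == lab.reviewer_b:
            out.append(replace(lab, adjudicated=lab.reviewer_a))
        elif lab.note_id in third_review:
            out.append(replace(lab, adjudicated=third_review[lab.note_id]))
        else:
            uncovered.append(lab.note_id)
    if uncovered:
        raise ValueError(
            "disagreements without a third review: " + ", ".join(sorted(uncovered))
        )
    return out


def _as_binary(label: str) -> bool:
    return label in (POSITIVE, MASH_POSITIVE)


def metrics_from_matrix(cm: ConfusionMatrix) -> ValidationMetrics:
    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return ValidationMetrics(
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        accuracy=ratio(cm.tp + cm.tn, cm.n),
        f1=ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
        ppv=ratio(cm.tp, cm.tp + cm.fp),
        n=cm.n,
    )


def evaluate(
    predictions: Iterable[NoteLabel] | Mapping[str, str],
    gold: Sequence[LabeledNote],
) -> tuple[ConfusionMatrix, ValidationMetrics]:
    """Score predictions against adjudicated gold labels (positive = MASH).

    ``predictions`` may be detector output (NoteLabel records) or a plain
    note_id -> label mapping.  Every gold note must have a prediction and be
    adjudicated.
    """
    if isinstance(predictions, Mapping):
        pred_map = dict(predictions)
    else:
        pred_map = {p.note_id: p.label for p in predictions}

    tp = fp = fn = tn = 0
    missing = [g.note_id for g in gold if g.note_id not in pred_map]
    if missing:
        raise ValueError("missing predictions for: " + ", ".join(sorted(missing)))
    for g in gold:
        if g.adjudicated == PENDING:
            raise ValueError(f"gold label for {g.note_id} is not adjudicated")
        truth = _as_binary(g.adjudicated)
        pred = _as_binary(pred_map[g.note_id])
        if truth and pred:
            tp += 1
        elif truth:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
    return cm, metrics_from_matrix(cm)


def consistent_matrices(
    n: int,
    sensitivity_pct: int,
    specificity_pct: int,
    accuracy_pct: int,
) -> list[ConfusionMatrix]:
    """All integer 2x2 matrices of size ``n`` whose sensitivity, specificity
    and accuracy round (half-up) to the given integer percents.

    Exhaustive enumeration over tp/fn/fp with tn determined; used as an
    independent oracle when only rounded printed metrics are available.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    out: list[ConfusionMatrix] = []
    for pos in range(n + 1):  # pos = tp + fn
        neg = n - pos  # fp + tn
        if pos == 0 or neg == 0:
            continue  # sensitivity or specificity undefined
        for tp in range(pos + 1):
            if round_ratio_half_up(tp, pos, 100) != sensitivity_pct:
                continue
            for fp in range(neg + 1):
                tn = neg - fp
                if round_ratio_half_up(tn, neg, 100) != specificity_pct:
                    continue
                if round_ratio_half_up(tp + tn, n, 100) != accuracy_pct:
                    continue
                out.append(ConfusionMatrix(tp=tp, fp=fp, fn=pos - tp, tn=tn))
    return out
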