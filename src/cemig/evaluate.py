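"""Sequence-level classification metrics for discovered motifs.

A discovered PWM induces a per-sequence score: the best log-odds match
over all offsets and both strands against the Markov background's
mononucleotide frequencies.  Thresholding those scores classifies
sequences as motif-bearing (positive) or background (negative), and the
quality of that classification is summarised by precision, specificity,
accuracy and the area under the precision-recall curve (AUPRC) — the
PR curve being the informative one under the class imbalance typical of
open-chromatin scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score

from .background import BackgroundModel
from .paths import MotifResult
from .sequences import SequenceSet, reverse_complement

BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_PWM_FLOOR = 1e-4


@dataclass
class LabeledScores:
    """Per-sequence labels, scores, and thresholded predictions."""

    labels: np.ndarray  # bool
    scores: np.ndarray  # float
    predictions: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        self.scores = np.asarray(self.scores, dtype=float)
        self.predictions = np.asarray(self.predictions, dtype=bool)
        if not (len(self.labels) == len(self.scores) == len(self.predictions)):
            raise ValueError("labels, scores and predictions must be equal length")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


@dataclass
class ClassificationMetrics:
    precision: float
    specificity: float
    acc: float
    auprc: float
    precision_defined: bool = True


def scan_best_score(
    seqs: SequenceSet, motif: MotifResult, model: BackgroundModel
) -> np.ndarray:
    """Best log-odds PWM match per sequence, over both strands and offsets.

    The window score is sum_j log(pwm[b_j, j] / M1(b_j)) with PWM entries
    floored at a small positive value; windows containing N are skipped.
    A sequence with no scoreable window (shorter than the PWM, or all N)
    receives the floor score L * log(floor / max(M1)), below any real match.
    """
    L = motif.length
    logodds = np.log(np.maximum(motif.pwm, _PWM_FLOOR)) - np.log(model.M1)[:, None]
    floor_score = float(L * (math.log(_PWM_FLOOR) - math.log(float(model.M1.max()))))
    out = np.empty(seqs.n)
    for i, (_, seq) in enumerate(seqs):
        best = floor_score
        for s in (seq, reverse_complement(seq)):
            for off in range(len(s) - L + 1):
                window = s[off : off + L]
                if "N" in window:
                    continue
                score = sum(
                    logodds[BASE_INDEX[b], j] for j, b in enumerate(window)
                )
                if score > best:
                    best = score
        out[i] = best
    return out


def acc_optimal_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score threshold (predict positive at score >= threshold) maximising
    accuracy; the smallest maximiser is returned for determinism."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    candidates = np.concatenate(([-np.inf], np.unique(scores)))
    best_thr, best_acc = -np.inf, -1.0
    for thr in candidates:
        acc = float(np.mean((scores >= thr) == labels))
        if acc > best_acc:
            best_acc, best_thr = acc, float(thr)
    return best_thr


def classification_metrics(ls: LabeledScores) -> ClassificationMetrics:
    """Precision, specificity, accuracy and AUPRC of labelled scores.

    Precision = TP / (TP + FP), reported as 0 with a flag when nothing is
    predicted positive; specificity = TN / (TN + FP); ACC = (TP + TN) / N.
    AUPRC uses interpolation-free step summation over all thresholds and
    requires both classes to be present.
    """
    y, yhat = ls.labels, ls.predictions
    tp = int(np.sum(y & yhat))
    fp = int(np.sum(~y & yhat))
    tn = int(np.sum(~y & ~yhat))
    n = len(y)
    precision_defined = (tp + fp) > 0
    precision = tp / (tp + fp) if precision_defined else 0.0
    specificity = tn / (tn + fp) if (tn + fp) > 0 else 1.0
    acc = (tp + tn) / n
    if y.all() or not y.any():
        raise ValueError("AUPRC requires both positive and negative sequences")
    auprc = float(average_precision_score(y, ls.scores))
    return ClassificationMetrics(
        precision=precision,
        specificity=specificity,
        acc=acc,
        auprc=auprc,
        precision_defined=precision_defined,
    )
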