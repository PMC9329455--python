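"""Evaluation battery: thresholded selection, confusion metrics, ROC,
McNemar comparisons and the model-selection grid.

Category selection mirrors the probability-threshold protocol: a class is
selected only if its output probability exceeds the threshold (default
0.17, just above six-class chance 1/6 = 16.66%); otherwise the case is
*missed*.  Missed cases are counted separately and excluded from the
one-vs-rest confusion counts, but remain in the denominator of overall
accuracy.

Percentages are reported rounded half-up to one decimal, matching how
confusion-matrix metrics are conventionally tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from scipy.stats import chi2

from . import training

DEFAULT_THRESHOLD = 0.17
MISSED = "missed"

#: Upper 5% point of chi-square with 1 df: pairwise McNemar below this is
#: treated as "no reliable difference" by the model-selection rule.
CHI2_CRIT_5PCT = 3.841


def round_half_up_percent(numerator: int, denominator: int) -> float:
    """Exact percent ratio rounded half-up to one decimal; NaN if 0/0."""
    if denominator == 0:
        return float("nan")
    value = Decimal(100 * int(numerator)) / Decimal(int(denominator))
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassDecision:
    """Thresholded category selection for one probability vector."""

    probabilities: np.ndarray
    selected: int | str
    threshold: float

    @property
    def missed(self) -> bool:
        return self.selected == MISSED


def select_category(probabilities: Sequence[float],
                    threshold: float = DEFAULT_THRESHOLD) -> ClassDecision:
    """Select the argmax class if its probability exceeds the threshold.

    Ties are broken toward the lowest class index; if no probability
    exceeds the threshold the decision is ``missed``.  Classes are
    1-based.
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.ndim != 1 or np.any(probs < -1e-12) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must be a 1-D vector summing to 1")
    best = int(np.argmax(probs))  # argmax takes the first (lowest) index on ties
    if probs[best] > threshold:
        return ClassDecision(probs, best + 1, threshold)
    return ClassDecision(probs, MISSED, threshold)


def decide_batch(probabilities: np.ndarray,
                 threshold: float = DEFAULT_THRESHOLD) -> list[ClassDecision]:
    """Apply :func:`select_category` to each probability row."""
    return [select_category(row, threshold) for row in np.asarray(probabilities)]


def count_missed(decisions: Iterable[ClassDecision]) -> int:
    """Number of decisions for which no class cleared the threshold."""
    return sum(1 for d in decisions if d.missed)


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest tp/fp/fn/tn per class (arrays of length n_classes)."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.tp.size

    @property
    def n_cases(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


def confusion_counts(true_labels: Sequence[int],
                     predicted_labels: Sequence[int],
                     n_classes: int) -> ConfusionCounts:
    """Per-class one-vs-rest counts from aligned 1-based label sequences.

    Missed decisions must be excluded by the caller before counting
    (``count_missed`` reports them separately).
    """
    truth = np.asarray(true_labels)
    pred = np.asarray(predicted_labels)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValueError("label sequences must be 1-D and of equal length")
    for name, arr in (("true", truth), ("predicted", pred)):
        if arr.size and (arr.min() < 1 or arr.max() > n_classes):
            raise ValueError(f"{name} labels must lie in 1..{n_classes}")
    tp = np.zeros(n_classes, dtype=int)
    fp = np.zeros(n_classes, dtype=int)
    fn = np.zeros(n_classes, dtype=int)
    tn = np.zeros(n_classes, dtype=int)
    for k in range(1, n_classes + 1):
        tp[k - 1] = int(np.sum((truth == k) & (pred == k)))
        fp[k - 1] = int(np.sum((truth != k) & (pred == k)))
        fn[k - 1] = int(np.sum((truth == k) & (pred != k)))
        tn[k - 1] = int(np.sum((truth != k) & (pred != k)))
    return ConfusionCounts(tp, fp, fn, tn)


def metrics_from_counts(counts: ConfusionCounts) -> pd.DataFrame:
    """Per-class precision, TPR, FPR and accuracy in percent (1 decimal).

    precision = tp/(tp+fp); TPR = tp/(tp+fn); FPR = fp/(fp+tn);
    accuracy = (tp+tn)/(tp+fp+fn+tn).  Zero denominators yield NaN.
    """
    rows = []
    for k in range(counts.n_classes):
        tp, fp = int(counts.tp[k]), int(counts.fp[k])
        fn, tn = int(counts.fn[k]), int(counts.tn[k])
        rows.append({
            "class": k + 1,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "precision_pct": round_half_up_percent(tp, tp + fp),
            "tpr_pct": round_half_up_percent(tp, tp + fn),
            "fpr_pct": round_half_up_percent(fp, fp + tn),
            "accuracy_pct": round_half_up_percent(tp + tn, tp + fp + fn + tn),
        })
    return pd.DataFrame(rows)


def roc_points(scores: Sequence[float],
               truth: Sequence[bool]) -> list[tuple[float, float]]:
    """One-vs-rest ROC curve: (FPR, TPR) pairs over all score thresholds.

    The decision rule at threshold ``s`` predicts positive when
    ``score >= s``; sweeping over the distinct scores (descending) plus
    the endpoints (0,0) and (1,1) yields a curve with non-decreasing FPR.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and truth must be 1-D and of equal length")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative case")
    points = [(0.0, 0.0)]
    for s in np.sort(np.unique(scores))[::-1]:
        predicted = scores >= s
        tpr = float(np.sum(predicted & truth)) / n_pos
        fpr = float(np.sum(predicted & ~truth)) / n_neg
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    # drop consecutive duplicates while preserving order
    deduped = [points[0]]
    for pt in points[1:]:
        if pt != deduped[-1]:
            deduped.append(pt)
    return deduped


def mcnemar_statistic(discordant_b: int, discordant_c: int) -> float:
    """McNemar chi-square (b - c)^2 / (b + c), no continuity correction."""
    if discordant_b < 0 or discordant_c < 0:
        raise ValueError("discordant counts must be non-negative")
    if discordant_b + discordant_c == 0:
        raise ValueError("statistic undefined with no discordant pairs")
    return (discordant_b - discordant_c) ** 2 / (discordant_b + discordant_c)


def mcnemar_pvalue(statistic: float) -> float:
    """Upper-tail chi-square p-value (df = 1) for the McNemar statistic."""
    return float(chi2.sf(statistic, df=1))


def discordant_counts(correct_a: Sequence[bool],
                      correct_b: Sequence[bool]) -> tuple[int, int]:
    """Discordant pair counts from two aligned correctness sequences.

    Returns (b, c) with b = cases classifier A got right and B got
    wrong, c = the reverse.
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("correctness sequences must align")
    return int(np.sum(a & ~b)), int(np.sum(~a & b))


# -- model-selection grid --------------------------------------------------

def evaluate_decisions(decisions: Sequence[ClassDecision],
                       true_labels: Sequence[int]) -> dict:
    """Overall accuracy plus confusion counts for one decision set.

    Accuracy counts a case as correct only if it was selected (not
    missed) and matches the true class; missed cases stay in the
    denominator.
    """
    truth = np.asarray(true_labels)
    kept = [(d.selected, t) for d, t in zip(decisions, truth) if not d.missed]
    n_correct = sum(1 for sel, t in kept if sel == t)
    n_classes = int(truth.max())
    counts = confusion_counts([t for _, t in kept], [s for s, _ in kept],
                              n_classes)
    return {
        "accuracy_pct": round_half_up_percent(n_correct, truth.size),
        "n_missed": count_missed(decisions),
        "counts": counts,
        "correct": np.array([(not d.missed) and d.selected == t
                             for d, t in zip(decisions, truth)]),
    }


def model_selection_grid(inputs: np.ndarray,
                         labels: Sequence[int],
                         new_datasets: Sequence[np.ndarray] = (),
                         algorithms: Sequence[str] = ("scg", "rprop"),
                         consecutive: Sequence[int] = (100, 150, 200),
                         base_config: training.TrainConfig | None = None,
                         threshold: float = DEFAULT_THRESHOLD,
                         ) -> pd.DataFrame:
    """Train the algorithm x validation-trials grid and rank the networks.

    One network is trained per (algorithm, consecutive-correct) cell; each
    row reports the overall thresholded accuracy on the full dataset and
    the missed-trial counts on each new (unlabeled) dataset.  The
    best-network flag goes to the highest-accuracy row, except that rows
    whose pairwise McNemar statistic against it stays below the 5%
    critical value (3.841) are treated as ties and the tie with the
    fewest total missed trials on new data wins.
    """
    from .classify import train_classifier  # local import avoids a cycle

    base = base_config or training.TrainConfig()
    rows = []
    correctness = []
    for algorithm in algorithms:
        for n_consecutive in consecutive:
            config = replace(base, algorithm=algorithm,
                             consecutive_correct=n_consecutive)
            model, history, _ = train_classifier(inputs, labels, config)
            decisions = decide_batch(model.predict_proba(inputs), threshold)
            report = evaluate_decisions(decisions, labels)
            row = {
                "network": f"{algorithm}-{n_consecutive}",
                "algorithm": algorithm,
                "validation_trials": n_consecutive,
                "accuracy_pct": report["accuracy_pct"],
                "stop_reason": history.stop_reason,
                "epochs": history.n_epochs,
            }
            for j, X_new in enumerate(new_datasets, start=1):
                new_decisions = decide_batch(model.predict_proba(X_new),
                                             threshold)
                row[f"missed_new{j}"] = count_missed(new_decisions)
            rows.append(row)
            correctness.append(report["correct"])
    grid = pd.DataFrame(rows)

    missed_cols = [c for c in grid.columns if c.startswith("missed_new")]
    total_missed = (grid[missed_cols].sum(axis=1) if missed_cols
                    else pd.Series(0, index=grid.index))
    best = int(grid["accuracy_pct"].idxmax())
    tied = []
    for i in range(len(grid)):
        if i == best:
            tied.append(i)
            continue
        b, c = discordant_counts(correctness[best], correctness[i])
        if b + c == 0 or mcnemar_statistic(b, c) < CHI2_CRIT_5PCT:
            tied.append(i)
    winner = min(tied, key=lambda i: (total_missed[i],
                                      -grid.loc[i, "accuracy_pct"]))
    grid["selected"] = [i == winner for i in range(len(grid))]
    return grid
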