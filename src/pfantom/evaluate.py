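"""Per-compartment evaluation: confusion counts, sensitivity/specificity
and threshold-swept ROC curves, one-vs-rest against GO-derived truth.

Ground truth is multi-label (a protein may genuinely reside in several
compartments), so each compartment is evaluated as its own binary problem:
for compartment c, a protein counts as a true positive when c is both
called and true, regardless of what else is called or true.  Proteins the
predictor abstains on for lack of domain data (status no_pfam / no_data)
are excluded from the denominators by default and reported as coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .predictor import CompartmentScores, PredictionCall, call_localization

#: Statuses for which the predictor had usable domain data.
COVERED_STATUSES = frozenset({"predicted", "tie", "below_threshold"})


@dataclass(frozen=True)
class ConfusionCounts:
    compartment_name: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


class Metrics(NamedTuple):
    """Sensitivity/specificity pair; None marks a zero-denominator ratio."""

    sensitivity: float | None
    specificity: float | None


@dataclass
class PerformanceReport:
    """Per-compartment sensitivity/specificity for one predictor."""

    predictor_label: str
    per_compartment: dict[str, Metrics]
    counts: dict[str, ConfusionCounts]
    n_evaluated: int
    n_uncovered: int = 0

    def to_rows(self) -> list[dict]:
        rows = []
        for comp, m in self.per_compartment.items():
            c = self.counts[comp]
            rows.append(
                {
                    "compartment": comp,
                    "sensitivity": "NA" if m.sensitivity is None else round(m.sensitivity, 4),
                    "specificity": "NA" if m.specificity is None else round(m.specificity, 4),
                    "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                    "predictor": self.predictor_label,
                }
            )
        return rows


@dataclass
class RocCurve:
    """One compartment's ROC sweep: (threshold, TPR, FPR) points plus AUC."""

    compartment_name: str
    points: list[tuple[float, float, float]] = field(default_factory=list)
    auc: float = float("nan")

    def __post_init__(self) -> None:
        ts = [t for t, _, _ in self.points]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("thresholds must be strictly increasing")
        for series in ([p[1] for p in self.points], [p[2] for p in self.points]):
            if any(b > a + 1e-12 for a, b in zip(series, series[1:])):
                raise ValueError("TPR/FPR must be non-increasing in threshold")


def _select_covered(
    calls: Sequence[PredictionCall],
    truth: Mapping[str, set[str]],
    include_uncovered: bool,
) -> tuple[list[PredictionCall], int]:
    missing = [c.protein_id for c in calls if c.protein_id not in truth]
    if missing:
        raise ValueError(
            "proteins missing from truth table: " + ", ".join(sorted(missing)[:10])
        )
    if include_uncovered:
        return list(calls), 0
    covered = [c for c in calls if c.status in COVERED_STATUSES]
    return covered, len(calls) - len(covered)


def confusion_counts(
    calls: Sequence[PredictionCall],
    truth: Mapping[str, set[str]],
    compartment: str,
    *,
    include_uncovered: bool = False,
) -> ConfusionCounts:
    """One-vs-rest confusion table for a single compartment.

    Tie calls contribute every called compartment; with
    ``include_uncovered`` proteins the predictor abstained on count as
    all-negative calls.
    """
    evaluated, _ = _select_covered(calls, truth, include_uncovered)
    tp = fp = tn = fn = 0
    for call in evaluated:
        predicted = compartment in call.called
        actual = compartment in truth[call.protein_id]
        if predicted and actual:
            tp += 1
        elif predicted:
            fp += 1
        elif actual:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(compartment, tp, fp, tn, fn)


def performance_metrics(counts: ConfusionCounts) -> Metrics:
    """sensitivity = tp/(tp+fn), specificity = tn/(tn+fp); None when undefined."""
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    return Metrics(sens, spec)


def performance_report(
    calls: Sequence[PredictionCall],
    truth: Mapping[str, set[str]],
    compartments: Sequence[str],
    *,
    predictor_label: str = "pfantom",
    include_uncovered: bool = False,
) -> PerformanceReport:
    """Sensitivity/specificity for every compartment, plus coverage."""
    evaluated, n_uncovered = _select_covered(calls, truth, include_uncovered)
    counts = {
        c: confusion_counts(evaluated, truth, c, include_uncovered=True)
        for c in compartments
    }
    metrics = {c: performance_metrics(k) for c, k in counts.items()}
    return PerformanceReport(
        predictor_label=predictor_label,
        per_compartment=metrics,
        counts=counts,
        n_evaluated=len(evaluated),
        n_uncovered=n_uncovered,
    )


def roc_sweep(
    scored: Sequence[CompartmentScores],
    truth: Mapping[str, set[str]],
    compartment: str,
    step: float = 0.01,
) -> RocCurve:
    """Sweep the calling threshold and trace the one-vs-rest ROC curve.

    At threshold t a protein is called ``compartment`` iff its score there
    is >= t and the compartment is among the (tied) argmax scores.  The AUC
    summary applies the trapezoid rule to the (FPR, TPR) points closed with
    the (0,0) and (1,1) endpoints.
    """
    if not 0.0 < step <= 1.0:
        raise ValueError("step must lie in (0, 1]")
    scorable = [s for s in scored if s.domains_used]
    missing = [s.protein_id for s in scorable if s.protein_id not in truth]
    if missing:
        raise ValueError(
            "proteins missing from truth table: " + ", ".join(sorted(missing)[:10])
        )
    actual = np.array([compartment in truth[s.protein_id] for s in scorable])
    score_c = np.array([s.scores.get(compartment, 0.0) for s in scorable])
    is_top = np.array(
        [
            bool(s.scores)
            and s.scores.get(compartment, 0.0) >= max(s.scores.values()) - 1e-12
            for s in scorable
        ]
    )
    n_pos = int(actual.sum())
    n_neg = len(scorable) - n_pos

    points = []
    n_steps = int(round(1.0 / step))
    for i in range(n_steps + 1):
        t = min(1.0, i * step)
        called = is_top & (score_c >= t)
        tp = int((called & actual).sum())
        fp = int((called & ~actual).sum())
        tpr = tp / n_pos if n_pos else 0.0
        fpr = fp / n_neg if n_neg else 0.0
        points.append((t, tpr, fpr))
        if t >= 1.0:
            break

    xs = np.array([p[2] for p in points] + [0.0, 1.0])
    ys = np.array([p[1] for p in points] + [0.0, 1.0])
    order = np.lexsort((ys, xs))
    auc = float(np.trapezoid(ys[order], xs[order]))
    return RocCurve(compartment, points, auc)


def evaluate_at_thresholds(
    scored: Sequence[CompartmentScores],
    truth: Mapping[str, set[str]],
    compartments: Sequence[str],
    step: float = 0.01,
) -> dict[str, RocCurve]:
    """ROC curves for every compartment of interest."""
    return {c: roc_sweep(scored, truth, c, step) for c in compartments}
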