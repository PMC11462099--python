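"""Two-task evaluation against gold labels.

Task ``info_presence``: positive = any severity information documented.
Task ``severity``: restricted to records whose GOLD label is documented,
with moderate-to-severe as the positive class and mild as the negative
class; a gold-documented record the pipeline left undocumented counts on
the negative side.  Metrics follow the usual count identities and are
displayed with half-up rounding to 2 decimals (full precision kept
internally); reported values that disagree with the counts they
accompany are flagged, never silently echoed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional

from .resolve import PatientSeverity

TASKS = ("info_presence", "severity")
METRICS = ("accuracy", "sensitivity", "specificity", "f1")


class AlignmentError(ValueError):
    """Prediction and gold files do not cover the same record identifiers."""


@dataclass(frozen=True)
class GoldLabel:
    """Manually assigned record-level label."""

    record_id: str
    has_severity_info: bool
    severity: Optional[str] = None  # mild | moderate_severe | None

    def __post_init__(self):
        if self.has_severity_info and self.severity not in (
            "mild",
            "moderate_severe",
        ):
            raise ValueError(
                f"documented gold record {self.record_id!r} needs a severity"
            )


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int
    task: str = "info_presence"

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def build_confusion(
    pred: Iterable[PatientSeverity],
    gold: Iterable[GoldLabel],
    task: str,
) -> ConfusionMatrix:
    """Tally one of the two binary tasks over aligned records."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    pred_by_id: Dict[str, PatientSeverity] = {p.patient_id: p for p in pred}
    gold_by_id: Dict[str, GoldLabel] = {g.record_id: g for g in gold}
    missing = sorted(set(pred_by_id) - set(gold_by_id))
    if missing:
        raise AlignmentError(f"predictions without gold labels: {missing}")
    extra = sorted(set(gold_by_id) - set(pred_by_id))
    if extra:
        raise AlignmentError(f"gold labels without predictions: {extra}")

    tp = fp = fn = tn = 0
    for rid in gold_by_id:
        g, p = gold_by_id[rid], pred_by_id[rid]
        if task == "info_presence":
            gpos, ppos = g.has_severity_info, p.has_severity_info
        else:
            if not g.has_severity_info:
                continue
            gpos = g.severity == "moderate_severe"
            ppos = p.severity == "moderate_severe"
        if gpos and ppos:
            tp += 1
        elif gpos:
            fn += 1
        elif ppos:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn, task=task)


def _ratio(num: int, den: int) -> Optional[Fraction]:
    if den == 0:
        return None
    return Fraction(num, den)


def round_half_up(value: Fraction, ndigits: int = 2) -> float:
    """Decimal half-up rounding of an exact ratio (reporting style)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(
        (Decimal(value.numerator) / Decimal(value.denominator)).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


def _is_borderline(value: Fraction, ndigits: int = 2) -> bool:
    scaled = value * 10**ndigits
    return scaled - int(scaled) == Fraction(1, 2)


@dataclass(frozen=True)
class MetricsReport:
    """Exact metrics of one confusion matrix plus display rounding."""

    cm: ConfusionMatrix
    accuracy: Optional[Fraction]
    sensitivity: Optional[Fraction]
    specificity: Optional[Fraction]
    f1: Optional[Fraction]

    def rounded(self, ndigits: int = 2) -> Dict[str, Optional[float]]:
        return {
            m: (None if v is None else round_half_up(v, ndigits))
            for m, v in self._items()
        }

    def borderline(self, ndigits: int = 2) -> List[str]:
        """Metrics whose exact value sits exactly on a rounding boundary."""
        return [
            m
            for m, v in self._items()
            if v is not None and _is_borderline(v, ndigits)
        ]

    def _items(self):
        return zip(
            METRICS, (self.accuracy, self.sensitivity, self.specificity, self.f1)
        )

    def to_dict(self) -> dict:
        return {
            "task": self.cm.task,
            "counts": {
                "tp": self.cm.tp,
                "fp": self.cm.fp,
                "fn": self.cm.fn,
                "tn": self.cm.tn,
            },
            "metrics": {
                m: (None if v is None else float(v)) for m, v in self._items()
            },
            "metrics_rounded": self.rounded(),
            "borderline": self.borderline(),
        }


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, sensitivity, specificity and F1 from the four counts.

    A metric whose denominator is zero is reported as ``None``
    (undefined), never as 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return MetricsReport(
        cm=cm,
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        f1=_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
    )


def compare_with_reported(
    cm: ConfusionMatrix, reported: Mapping[str, float], ndigits: int = 2
) -> List[dict]:
    """Recompute metrics from counts and flag disagreements with a report.

    Returns one entry per metric whose half-up rounded recomputation
    differs from the reported value — used to surface internally
    inconsistent published tables instead of echoing them.
    """
    rep = compute_metrics(cm)
    rounded = rep.rounded(ndigits)
    flags = []
    for metric, value in reported.items():
        if metric not in METRICS:
            raise KeyError(metric)
        computed = rounded[metric]
        if computed is None or abs(computed - float(value)) > 10**-ndigits / 2:
            flags.append(
                {"metric": metric, "computed": computed, "reported": float(value)}
            )
    return flags
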