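"""Scoring of segmentations and CNV calls against simulated truth.

Three views of accuracy:

* **Breakpoint distance** — for every true breakpoint, the distance (in
  windows) to the nearest predicted breakpoint, and symmetrically for every
  prediction; a histogram of prediction distances summarizes localization.
* **Breakpoint ROC** — the decoder emits hard calls, so operating points are
  generated by sweeping the jump-probability parameter (eta for the
  homogeneous model, theta for the heterogeneous one).  At each sweep value,
  TPR is the fraction of true breakpoints matched within a window tolerance
  and FPR is the number of unmatched predictions divided by the number of
  eligible negative positions (windows not within tolerance of any true
  breakpoint).  The curve is anchored at (0,0) and (1,1) and integrated by
  the trapezoid rule, so a segmenter that never predicts scores exactly 0.5
  (the chance diagonal).
* **Interval precision/recall** — a call is a true positive if it overlaps a
  truth interval by at least one base (optionally also requiring the copy
  direction to match); precision = TP calls / all calls, recall = found
  truths / all truths, F = harmonic mean.  Metrics are stratified into the
  Small (< 20 kb), Medium (20-100 kb) and Large (>= 100 kb) event classes.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .profiles import CNVCall, CopyState, GenomicProfile, Segmentation
from .simulate import TruthSet

__all__ = [
    "SizeClass",
    "BreakpointDistances",
    "breakpoint_distances",
    "breakpoint_distance_histogram",
    "ROCResult",
    "roc_auc",
    "ClassMetrics",
    "PrecisionRecallReport",
    "precision_recall",
    "classify_size",
    "EvaluationReport",
]

DEFAULT_SIZE_CLASSES = (20_000, 100_000)
DEFAULT_TOLERANCE_WINDOWS = 2


class SizeClass(enum.Enum):
    SMALL = "SMALL"
    MEDIUM = "MEDIUM"
    LARGE = "LARGE"


def classify_size(length_bp: int, boundaries: Sequence[int] = DEFAULT_SIZE_CLASSES) -> SizeClass:
    """Small below the first boundary, Large at or above the second."""
    small_max, medium_max = boundaries
    if length_bp < small_max:
        return SizeClass.SMALL
    if length_bp < medium_max:
        return SizeClass.MEDIUM
    return SizeClass.LARGE


@dataclass
class BreakpointDistances:
    """Nearest-neighbor window distances, both directions; inf marks a miss."""

    truth_to_pred: np.ndarray
    pred_to_truth: np.ndarray


def _nearest(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    if len(src) == 0:
        return np.zeros(0)
    if len(dst) == 0:
        return np.full(len(src), np.inf)
    return np.min(np.abs(src[:, None] - dst[None, :]), axis=1).astype(float)


def breakpoint_distances(
    predicted: Sequence[int], truth: TruthSet | Sequence[int]
) -> BreakpointDistances:
    """Distances (in windows) between predicted and true breakpoints.

    ``truth`` may be a :class:`~slmcnv.simulate.TruthSet` or a bare breakpoint
    index list.
    """
    true_b = np.asarray(truth.breakpoints if isinstance(truth, TruthSet) else truth, float)
    pred = np.asarray(list(predicted), float)
    return BreakpointDistances(_nearest(true_b, pred), _nearest(pred, true_b))


def breakpoint_distance_histogram(
    pred_to_truth: np.ndarray, max_distance: int | None = None
) -> np.ndarray:
    """Fraction of predicted breakpoints at each window distance from truth.

    Distances above ``max_distance`` (or infinite) accumulate in the last
    bin.  Fractions sum to 1 when any breakpoint was predicted; an empty
    prediction set returns an empty histogram.
    """
    d = np.asarray(pred_to_truth, float)
    if len(d) == 0:
        return np.zeros(0)
    finite = d[np.isfinite(d)]
    if max_distance is None:
        max_distance = int(finite.max()) if len(finite) else 0
    clipped = np.minimum(d, max_distance + 1).astype(int)
    counts = np.bincount(clipped, minlength=max_distance + 2)
    return counts / counts.sum()


@dataclass
class ROCResult:
    """Swept operating points (fpr, tpr, sweep value) and the trapezoid AUC."""

    points: list[tuple[float, float, float]]
    auc: float


def roc_auc(
    profiles: Iterable[tuple[GenomicProfile, TruthSet]],
    segmenter: Callable[[GenomicProfile, float], Segmentation],
    sweep: Sequence[float],
    tolerance_windows: int = DEFAULT_TOLERANCE_WINDOWS,
) -> ROCResult:
    """Breakpoint ROC over a sweep of the segmenter's sensitivity parameter.

    ``segmenter(profile, sweep_value)`` must return a :class:`Segmentation`.
    Counts are pooled over all profiles at each sweep value.
    """
    if len(sweep) < 2:
        raise ValueError("sweep needs at least 2 parameter values")
    profiles = list(profiles)
    points = []
    for v in sweep:
        hits = total_true = fps = negatives = 0
        for profile, truth in profiles:
            seg = segmenter(profile, v)
            pred = np.asarray(seg.breakpoints, float)
            true_b = np.asarray(truth.breakpoints, float)
            d_t = _nearest(true_b, pred)
            d_p = _nearest(pred, true_b)
            total_true += len(true_b)
            hits += int(np.sum(d_t <= tolerance_windows))
            fps += int(np.sum(d_p > tolerance_windows))
            n = len(profile)
            positions = np.arange(n, dtype=float)
            near_true = _nearest(positions, true_b) <= tolerance_windows
            negatives += int(n - near_true.sum())
        tpr = hits / total_true if total_true else 0.0
        fpr = fps / negatives if negatives else 0.0
        points.append((fpr, tpr, float(v)))

    unique_ops = {(round(f, 15), round(t, 15)) for f, t, _ in points}
    if len(unique_ops) == 1:
        warnings.warn("degenerate sweep: all operating points identical; "
                      "AUC computed from the anchors", stacklevel=2)
    # sort points by (fpr, tpr) and integrate with (0,0) and (1,1) anchors
    ordered = sorted((f, t) for f, t, _ in points)
    curve = [(0.0, 0.0)] + ordered + [(1.0, 1.0)]
    fx = np.array([p[0] for p in curve])
    fy = np.array([p[1] for p in curve])
    auc = float(np.trapezoid(fy, fx))
    return ROCResult(points, auc)


@dataclass
class ClassMetrics:
    """Counts for one size class.

    ``tp``/``fp`` count calls (correct vs spurious); ``found``/``fn`` count
    truth intervals (detected vs missed), mirroring the asymmetric
    definitions of precision (over calls) and recall (over the reference).
    """

    tp: int = 0
    fp: int = 0
    found: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def recall(self) -> float:
        return self.found / (self.found + self.fn) if (self.found + self.fn) else float("nan")

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        if np.isnan(p) or np.isnan(r) or (p + r) == 0:
            return 0.0
        return 2.0 * p * r / (p + r)


@dataclass
class PrecisionRecallReport:
    per_class: dict[SizeClass, ClassMetrics]
    overall: ClassMetrics


def _overlaps(a: CNVCall, b: CNVCall) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def precision_recall(
    calls: Sequence[CNVCall],
    reference: Sequence[CNVCall],
    size_classes: Sequence[int] = DEFAULT_SIZE_CLASSES,
    require_direction: bool = True,
) -> PrecisionRecallReport:
    """Any-overlap precision/recall of CNV calls against a truth set.

    A call is TP if it overlaps >= 1 bp of any truth interval (and, with
    ``require_direction``, shares its copy direction); a truth interval
    counts as found if >= 1 call overlaps it.  Recall strata follow the
    truth interval length; TP calls inherit the class of the truth they hit,
    FP calls are classified by their own length.  With an empty reference,
    recall is NaN and a warning is emitted.
    """
    if not reference:
        warnings.warn("empty reference set: recall undefined (NaN)", stacklevel=2)

    def match(c: CNVCall, t: CNVCall) -> bool:
        return _overlaps(c, t) and (not require_direction or c.copy_state is t.copy_state)

    per_class = {sc: ClassMetrics() for sc in SizeClass}
    overall = ClassMetrics()
    for c in calls:
        hit = next((t for t in reference if match(c, t)), None)
        if hit is not None:
            overall.tp += 1
            per_class[classify_size(hit.length, size_classes)].tp += 1
        else:
            overall.fp += 1
            per_class[classify_size(c.length, size_classes)].fp += 1
    for t in reference:
        cm = per_class[classify_size(t.length, size_classes)]
        if any(match(c, t) for c in calls):
            overall.found += 1
            cm.found += 1
        else:
            overall.fn += 1
            cm.fn += 1
    return PrecisionRecallReport(per_class, overall)


@dataclass
class EvaluationReport:
    """Aggregate of the three scoring views for one benchmark run."""

    auc: float | None = None
    breakpoint_distance_histogram: np.ndarray | None = None
    precision_recall: PrecisionRecallReport | None = None
    extras: dict = field(default_factory=dict)
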