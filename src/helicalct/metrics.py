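"""Segmentation overlap (Dice) and diagnostic-performance metrics.

The Dice similarity coefficient between a gold-standard pixel set M and a
candidate segmentation N is ``2|M ∩ N| / (|M| + |N|)``: 0 for disjoint
masks, 1 for identical ones.  The empty-vs-empty case (0/0) is defined as 1
here — two empty segmentations agree perfectly.

The diagnostic rates follow the clinical-evaluation formula sheet this
package targets, including its unconventional missed-diagnosis and
misdiagnosis denominators (both divided by true negatives + false
positives).  Pass ``conventional=True`` to additionally report the textbook
miss rate fn/(fn+tp) and false-positive rate fp/(fp+tn).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .errors import ValidationError
from .phantom import BinaryMask, VoxelVolume

__all__ = [
    "ConfusionCounts",
    "DiagnosticReport",
    "dice",
    "threshold_segment",
    "confusion_from_labels",
    "diagnostic_report",
    "chi_square_2x2",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class DiagnosticReport:
    """Diagnostic rates; an entry is None when its denominator is zero, and
    ``undefined`` lists which.

    All standard rates lie in [0, 1].  The as-printed ``missed_rate``
    (fn over tn + fp) is not a true proportion — it exceeds 1 when
    fn > tn + fp; it is reported exactly as defined, unclamped.
    """

    detection_rate: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    coincidence_rate: Optional[float]
    missed_rate: Optional[float]
    misdiagnosis_rate: Optional[float]
    conventional_missed_rate: Optional[float] = None
    conventional_misdiagnosis_rate: Optional[float] = None
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "undefined"}
        d["undefined"] = list(self.undefined)
        return d


def dice(m: BinaryMask | np.ndarray, n: BinaryMask | np.ndarray) -> float:
    """Dice similarity 2|M∩N|/(|M|+|N|); both-empty defined as 1."""
    a = m.values if isinstance(m, BinaryMask) else np.asarray(m, dtype=bool)
    b = n.values if isinstance(n, BinaryMask) else np.asarray(n, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def threshold_segment(volume: VoxelVolume | np.ndarray, threshold: float) -> BinaryMask:
    """Binary mask of voxels with value >= threshold."""
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    if isinstance(volume, VoxelVolume):
        return BinaryMask(volume.values >= threshold, volume.spacing, volume.origin)
    arr = np.asarray(volume)
    return BinaryMask(arr >= threshold, (1.0,) * arr.ndim, (0.0,) * arr.ndim)


def confusion_from_labels(truth: Sequence[bool], predicted: Sequence[bool]) -> ConfusionCounts:
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    if t.shape != p.shape:
        raise ValidationError("truth and predicted must have equal length")
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def _rate(num: int, den: int, name: str, undefined: list[str]) -> Optional[float]:
    if den == 0:
        undefined.append(name)
        return None
    return num / den


def diagnostic_report(c: ConfusionCounts, conventional: bool = False) -> DiagnosticReport:
    """All diagnostic rates from a 2x2 confusion table.

    detection_rate = predicted positives / total (detected cases over all
    subjects); missed and misdiagnosis rates use the as-printed
    (tn + fp) denominator by default.
    """
    if c.total == 0:
        raise ValidationError("confusion counts are all zero")
    und: list[str] = []
    neg = c.tn + c.fp
    rep = DiagnosticReport(
        detection_rate=_rate(c.tp + c.fp, c.total, "detection_rate", und),
        sensitivity=_rate(c.tp, c.tp + c.fn, "sensitivity", und),
        specificity=_rate(c.tn, neg, "specificity", und),
        ppv=_rate(c.tp, c.tp + c.fp, "ppv", und),
        npv=_rate(c.tn, c.tn + c.fn, "npv", und),
        coincidence_rate=_rate(c.tp + c.tn, c.total, "coincidence_rate", und),
        missed_rate=_rate(c.fn, neg, "missed_rate", und),
        misdiagnosis_rate=_rate(c.fp, neg, "misdiagnosis_rate", und),
    )
    if conventional:
        rep.conventional_missed_rate = _rate(c.fn, c.fn + c.tp, "conventional_missed_rate", und)
        rep.conventional_misdiagnosis_rate = _rate(c.fp, c.fp + c.tn, "conventional_misdiagnosis_rate", und)
    rep.undefined = und
    return rep


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test (1 df) on a 2x2 contingency table.

    ``table`` is [[a, b], [c, d]] of non-negative counts; optional Yates
    continuity correction.  Returns (statistic, p_value).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(t < 0):
        raise ValidationError("counts must be non-negative")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValidationError("degenerate table: a row or column total is zero")
    expected = np.outer(row, col) / n
    diff = np.abs(t - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    p = float(_chi2_dist.sf(stat, df=1))
    return stat, p
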