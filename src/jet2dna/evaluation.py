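"""Prediction scoring (six standard metrics) and paired method comparison.

Predictions and reference interfaces are compared as residue sets over an
evaluation universe (surface residues by default, since binding is a surface
phenomenon; all residues optionally). Metrics are reported x100 -- [0, 100]
for Sens/PPV/Spe/Acc/F1 and [-100, 100] for MCC. A metric whose denominator
is zero is reported as ``None`` (undefined), never silently 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "paired_comparison",
    "best_combination",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    sens: Optional[float]
    ppv: Optional[float]
    spe: Optional[float]
    acc: Optional[float]
    f1: Optional[float]
    mcc: Optional[float]

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "Sens": self.sens, "PPV": self.ppv, "Spe": self.spe,
            "Acc": self.acc, "F1": self.f1, "MCC": self.mcc,
        }


def confusion(
    prediction: Set, reference: Set, universe: Set
) -> ConfusionCounts:
    """2x2 counts of predicted vs reference membership over the universe."""
    if not universe:
        raise ValueError("evaluation universe is empty")
    prediction, reference, universe = set(prediction), set(reference), set(universe)
    if not prediction <= universe:
        raise ValueError("prediction must be a subset of the universe")
    if not reference <= universe:
        raise ValueError("reference must be a subset of the universe")
    tp = len(prediction & reference)
    fp = len(prediction - reference)
    fn = len(reference - prediction)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Sens, PPV, Spe, Acc, F1 and MCC from the counts, scaled x100."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn

    def ratio(num: float, den: float) -> Optional[float]:
        return 100.0 * num / den if den else None

    sens = ratio(tp, tp + fn)
    ppv = ratio(tp, tp + fp)
    spe = ratio(tn, tn + fp)
    acc = ratio(tp + tn, c.total)
    f1 = None
    if sens is not None and ppv is not None and (sens + ppv) > 0:
        f1 = 2.0 * sens * ppv / (sens + ppv)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 100.0 * (tp * tn - fp * fn) / math.sqrt(mcc_den) if mcc_den else None
    return MetricsReport(sens=sens, ppv=ppv, spe=spe, acc=acc, f1=f1, mcc=mcc)


def paired_comparison(
    values_a: Sequence[float], values_b: Sequence[float], alpha: float = 0.05
) -> Dict[str, object]:
    """Compare two paired per-protein metric vectors.

    Normality of the paired differences is assessed with the Anderson-Darling
    test (5% level): normal differences go to the paired t-test, otherwise the
    Wilcoxon signed-rank test. Significant iff p < 0.05.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    diffs = a - b
    if np.allclose(diffs, 0.0):
        return {"test": "no difference", "statistic": None, "p_value": None,
                "significant": False}

    ad = stats.anderson(diffs, dist="norm", method="interpolate")
    normal = ad.pvalue > 0.05
    if normal:
        stat, p = stats.ttest_rel(a, b)
        name = "paired t-test"
    else:
        stat, p = stats.wilcoxon(a, b)
        name = "Wilcoxon signed-rank"
    return {"test": name, "statistic": float(stat), "p_value": float(p),
            "significant": bool(p < alpha)}


def best_combination(
    predictions_by_scheme: Dict[str, Set],
    reference: Set,
    universe: Set,
) -> Tuple[Tuple[str, ...], MetricsReport]:
    """Max-F1 patch combination across schemes (per-protein evaluation mode).

    Every non-empty subset of the scheme predictions is unioned and scored;
    the subset with the highest F1 wins (ties: fewer schemes, then name).
    """
    names = sorted(predictions_by_scheme)
    best: Tuple[Tuple[str, ...], MetricsReport] = ((), metrics(
        confusion(set(), reference, universe)))
    best_f1 = -1.0
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            union: Set = set()
            for name in combo:
                union |= predictions_by_scheme[name]
            report = metrics(confusion(union & universe, reference, universe))
            f1 = report.f1 if report.f1 is not None else -1.0
            if f1 > best_f1:
                best_f1 = f1
                best = (combo, report)
    return best
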