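"""Discrimination and classification assessment of a favourability surface.

AUC is computed by the rank-sum (Mann-Whitney) formulation — the fraction
of presence/absence pairs ordered correctly, ties counting one half — with
a two-sided p-value from the tie-corrected normal approximation to the
Mann-Whitney statistic. Classification measures are taken at the
environmental-neutrality threshold F = 0.5: a cell is counted favourable
iff F is strictly greater than 0.5.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats


def roc_auc(scores, presence) -> tuple[float, float]:
    """(AUC, two-sided p) for scores against a binary presence vector.

    AUC is invariant under any strictly increasing transform of the scores,
    so probability and favourability surfaces of the same model score
    identically.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(presence)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(s)
    R1 = float(ranks[y == 1].sum())
    U = R1 - n1 * (n1 + 1) / 2.0
    auc = U / (n1 * n0)
    n = n1 + n0
    _, counts = np.unique(s, return_counts=True)
    tie_term = float(((counts ** 3) - counts).sum())
    var = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all scores identical
        return auc, 1.0
    z = (U - n1 * n0 / 2.0) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(auc), float(min(p, 1.0))


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int


def confusion_at_threshold(F, presence, threshold: float = 0.5) -> ConfusionCounts:
    """Counts at the favourability cut: favourable iff F > threshold (strict,
    so F exactly at the threshold counts as not favourable)."""
    F = np.asarray(F, dtype=float)
    y = np.asarray(presence).astype(bool)
    fav = F > threshold
    return ConfusionCounts(
        tp=int((fav & y).sum()), fp=int((fav & ~y).sum()),
        tn=int((~fav & ~y).sum()), fn=int((~fav & y).sum()))


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


@dataclass
class EvaluationReport:
    """AUC with significance plus threshold classification measures.

    sensitivity — presence cells classified favourable, among presences;
    specificity — absence cells classified unfavourable, among absences;
    OPR — absence cells among the favourable area (over-prediction);
    UPR — presence cells among the unfavourable area (under-prediction).
    Undefined ratios (empty denominator) are NaN, never zero.
    """

    auc: float
    auc_p: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    opr: float
    upr: float

    def to_json(self, **kw) -> str:
        return json.dumps(asdict(self), sort_keys=True, **kw)


def classification_measures(c: ConfusionCounts) -> dict[str, float]:
    if min(c.tp, c.fp, c.tn, c.fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    return {
        "sensitivity": _ratio(c.tp, c.tp + c.fn),
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "opr": _ratio(c.fp, c.tp + c.fp),
        "upr": _ratio(c.fn, c.tn + c.fn),
    }


def evaluate(F, presence, threshold: float = 0.5) -> EvaluationReport:
    auc, p = roc_auc(F, presence)
    c = confusion_at_threshold(F, presence, threshold)
    m = classification_measures(c)
    return EvaluationReport(auc=auc, auc_p=p, tp=c.tp, fp=c.fp, tn=c.tn,
                            fn=c.fn, **m)
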