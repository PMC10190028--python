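"""Predictor screening: Spearman collinearity filter, then BH-FDR admission.

Two-stage reduction of the candidate pool before stepwise modelling:

1. multicollinearity — for each pair of candidates whose Spearman rank
   correlation exceeds a threshold (default |r| > 0.8) only the member with
   the higher individual predictive power is retained;
2. type-I control — of the survivors, only variables whose univariate Rao
   score test clears the Benjamini-Hochberg false-discovery-rate procedure
   at q (default 0.05) are admitted to modelling.

"Individual predictive power" defaults to the univariate Rao score
statistic (consistent with the stepwise entry criterion); a univariate-AUC
alternative is exposed through ``power=``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalogue import CATALOGUE_ORDER


def spearman_matrix(table: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Spearman correlations: product-moment correlation of mid-ranks.

    Ties get average ranks. A constant column has undefined correlations,
    reported as NaN (the collinearity filter treats NaN as 0).
    """
    X = table[list(variables)].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows for a rank correlation")
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    sd = ranks.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(ranks, rowvar=False)
    C[sd == 0, :] = np.nan
    C[:, sd == 0] = np.nan
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=list(variables), columns=list(variables))


def rao_score_test(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Score test for adding one variable to the intercept-only logistic model.

    Under the null the fitted probability is the prevalence p-bar everywhere;
    the efficient score is U = sum x_i (y_i - p_bar) with variance
    V = p_bar (1 - p_bar) sum (x_i - x_bar)^2, and U^2/V is chi-square with
    one degree of freedom. A constant x makes the test undefined: p = 1 by
    convention (flagged as statistic NaN).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.min() == y.max():
        raise ValueError("presence must contain both classes")
    pbar = y.mean()
    U = float(x @ (y - pbar))
    V = float(pbar * (1.0 - pbar) * ((x - x.mean()) ** 2).sum())
    if V <= 0.0:
        return float("nan"), 1.0
    stat = U * U / V
    return stat, float(stats.chi2.sf(stat, df=1))


def univariate_auc(y: np.ndarray, x: np.ndarray) -> float:
    """Rank-sum AUC of a single covariate as a score (orientation-free: max of
    the variable and its negation)."""
    from .evaluation import roc_auc
    a, _ = roc_auc(x, y)
    return max(a, 1.0 - a)


def collinearity_filter(corr: pd.DataFrame, power: dict[str, float],
                        threshold: float = 0.8,
                        ) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy pairwise filter: retain the stronger member of each |r|>threshold pair.

    Offending pairs are processed in descending |r|; a pair acts only if both
    members are still alive. Ties on |r| and on predictive power break by
    catalogue order (earlier-listed wins), so the result is deterministic and
    independent of input ordering. Returns (retained, drop log), the log as
    (dropped, retained partner, r) triples.
    """
    cand = list(corr.index)
    # catalogue order first; names outside the catalogue rank after it,
    # alphabetically, so the tie-break never depends on input ordering
    extra = sorted(c for c in cand if c not in CATALOGUE_ORDER)
    order = {c: CATALOGUE_ORDER.get(
        c, len(CATALOGUE_ORDER) + (extra.index(c) if c in extra else 0))
        for c in cand}
    pairs = []
    for i, a in enumerate(cand):
        for b in cand[i + 1:]:
            r = corr.loc[a, b]
            r = 0.0 if pd.isna(r) else float(r)
            if abs(r) > threshold:
                a_, b_ = sorted((a, b), key=order.get)
                pairs.append((a_, b_, r))
    pairs.sort(key=lambda t: (-abs(t[2]), order[t[0]], order[t[1]]))
    alive = set(cand)
    drop_log: list[tuple[str, str, float]] = []
    for a, b, r in pairs:
        if a in alive and b in alive:
            sa = power.get(a, float("-inf"))
            sb = power.get(b, float("-inf"))
            if (sa, -order[a]) >= (sb, -order[b]):
                keep, drop = a, b
            else:
                keep, drop = b, a
            alive.discard(drop)
            drop_log.append((drop, keep, r))
    retained = [c for c in cand if c in alive]
    return retained, drop_log


def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: accept the k smallest p-values where k is
    the largest index with p_(k) <= k q / m. Returns a boolean mask."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1) / m)
    below = p[order] <= thresh
    k = int(np.max(np.nonzero(below)[0]) + 1) if below.any() else 0
    accept = np.zeros(m, dtype=bool)
    accept[order[:k]] = True
    return accept


@dataclass
class ScreeningReport:
    """Everything the screening stage decided, serialisable to JSON."""

    candidates: list[str]
    spearman: pd.DataFrame
    drop_log: list[tuple[str, str, float]]
    score_stats: dict[str, float]
    score_pvalues: dict[str, float]
    fdr_q: float
    r_threshold: float
    accepted: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "candidates": self.candidates,
            "r_threshold": self.r_threshold,
            "fdr_q": self.fdr_q,
            "dropped": [{"dropped": d, "retained": k, "r": r}
                        for d, k, r in self.drop_log],
            "score_statistics": self.score_stats,
            "score_pvalues": self.score_pvalues,
            "accepted": self.accepted,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


def screen(table: pd.DataFrame, variables: Sequence[str],
           r_threshold: float = 0.8, q: float = 0.05,
           power: str = "score") -> ScreeningReport:
    """Run both screening stages (correlation filter first, then FDR)."""
    y = table["presence"].to_numpy(dtype=float)
    corr = spearman_matrix(table, variables)
    stats_, pvals = {}, {}
    for v in variables:
        s, p = rao_score_test(y, table[v].to_numpy(dtype=float))
        stats_[v], pvals[v] = s, p
    if power == "score":
        strength = {v: (-1.0 if np.isnan(stats_[v]) else stats_[v]) for v in variables}
    elif power == "auc":
        strength = {v: univariate_auc(y, table[v].to_numpy(dtype=float))
                    for v in variables}
    else:
        raise ValueError(f"unknown power criterion {power!r}")
    retained, drop_log = collinearity_filter(corr, strength, threshold=r_threshold)
    mask = bh_fdr([pvals[v] for v in retained], q=q)
    accepted = [v for v, ok in zip(retained, mask) if ok]
    return ScreeningReport(candidates=list(variables), spearman=corr,
                           drop_log=drop_log, score_stats=stats_,
                           score_pvalues=pvals, fdr_q=q,
                           r_threshold=r_threshold, accepted=accepted)
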