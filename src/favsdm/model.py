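"""Stepwise logistic regression and the favourability transform.

The probability of breeding at each OGU is modelled with binary logistic
regression fitted by maximum likelihood (iteratively reweighted least
squares). Variables are chosen by forward-backward stepwise selection:
entry by the Rao score test (the candidate's efficient score evaluated at
the current fit, no refit needed), removal by the Wald test.

Probabilities are then freed of the species' prevalence with the
favourability function

    F = odds(P) / (n1/n0 + odds(P)) = expit(logit(P) - ln(n1/n0)),

where n1 and n0 are the numbers of presence and absence cells in training.
F = 0.5 exactly where the local probability equals the prevalence, i.e.
where the environment neither favours nor disfavours the species, which
makes favourability surfaces comparable across species and directly usable
as fuzzy membership degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "SeparationError", "ConvergenceError", "LogitFit", "LogitModel",
    "fit_mle", "score_test_added", "stepwise_logistic",
    "favourability", "favourability_from_logit", "classify",
    "predict_surface", "response_curve", "wald_table",
]

CATEGORIES = ("unfavourable", "intermediate", "highly favourable")


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


class ConvergenceError(RuntimeError):
    pass


@dataclass
class LogitFit:
    """Raw maximum-likelihood fit: coefficients (intercept first) and curvature."""

    beta: np.ndarray
    cov: np.ndarray           # inverse observed information
    loglik: float
    iterations: int
    grad_norm: float

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _design(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    return np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + e^eta), stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_mle(y: np.ndarray, X: np.ndarray, tol: float = 1e-8,
            max_iter: int = 50) -> LogitFit:
    """Logistic MLE by IRLS with step-halving.

    ``X`` holds the predictor columns (no constant; one is prepended).
    Convergence when the log-likelihood change drops below ``tol``; standard
    errors come from the inverse observed information at the optimum.
    Separation is detected by coefficient divergence (any standardized
    coefficient |beta_j| * sd(x_j) beyond 30) and raised explicitly rather
    than silently returning huge coefficients.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    Z = _design(X)
    scale = Z.std(axis=0)
    scale[scale == 0] = 1.0
    beta = np.zeros(Z.shape[1])
    beta[0] = logit(y.mean())
    ll = _loglik(y, Z @ beta)
    for it in range(1, max_iter + 1):
        eta = Z @ beta
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        g = Z.T @ (y - p)
        H = (Z * w[:, None]).T @ Z
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as e:
            raise ConvergenceError(f"singular information matrix at iteration {it}") from e
        # step-halving keeps the likelihood ascent monotone
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = _loglik(y, Z @ cand)
            if ll_new >= ll - 1e-13:
                break
            t *= 0.5
        beta, ll_prev, ll = cand, ll, ll_new
        if np.any(np.abs(beta) * scale > 30.0):
            raise SeparationError(
                "coefficient divergence: data are (quasi-)separated, the MLE "
                "does not exist")
        if abs(ll - ll_prev) < tol:
            break
    else:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")
    eta = Z @ beta
    p = expit(eta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    H = (Z * w[:, None]).T @ Z
    grad = Z.T @ (y - p)
    return LogitFit(beta=beta, cov=np.linalg.inv(H), loglik=ll,
                    iterations=it, grad_norm=float(np.linalg.norm(grad)))


def score_test_added(y: np.ndarray, Z: np.ndarray, p: np.ndarray,
                     x_new: np.ndarray) -> tuple[float, float]:
    """Rao score test for adding one column to an already-fitted model.

    ``Z`` is the current design (constant included), ``p`` its fitted
    probabilities. The efficient score for the candidate is
    U = x'(y - p) with variance V = x'Wx - x'WZ (Z'WZ)^-1 Z'Wx,
    W = diag(p(1-p)); U^2/V is chi-square(1) under the null. Reduces to the
    classical one-variable formula when the current model is intercept-only.
    """
    w = np.clip(p * (1.0 - p), 1e-12, None)
    U = float(x_new @ (y - p))
    xw = x_new * w
    ZtWZ = (Z * w[:, None]).T @ Z
    ZtWx = Z.T @ xw
    try:
        V = float(x_new @ xw - ZtWx @ np.linalg.solve(ZtWZ, ZtWx))
    except np.linalg.LinAlgError:
        return float("nan"), 1.0
    if V <= 1e-12:
        return float("nan"), 1.0
    stat = U * U / V
    return stat, float(stats.chi2.sf(stat, df=1))


@dataclass
class LogitModel:
    """Fitted stepwise model: Table-1-style coefficients plus provenance."""

    variables: list[str]               # in entry order
    intercept: float
    coef: dict[str, float]
    se: dict[str, float]               # includes "(Constant)"
    n1: int
    n0: int
    iterations: int
    grad_norm: float
    loglik: float
    history: list[dict] = field(default_factory=list)

    @property
    def prevalence(self) -> float:
        return self.n1 / (self.n1 + self.n0)

    def wald(self, name: str) -> float:
        b = self.intercept if name == "(Constant)" else self.coef[name]
        return (b / self.se[name]) ** 2

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(table), self.intercept)
        for v in self.variables:
            if v not in table.columns:
                raise KeyError(f"model variable {v!r} missing from the table")
            eta += self.coef[v] * table[v].to_numpy(dtype=float)
        return eta

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "intercept": self.intercept,
            "coef": self.coef,
            "se": self.se,
            "n1": self.n1,
            "n0": self.n0,
            "loglik": self.loglik,
            "iterations": self.iterations,
            "grad_norm": self.grad_norm,
            "history": self.history,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "LogitModel":
        return cls(variables=list(d["variables"]), intercept=float(d["intercept"]),
                   coef={k: float(v) for k, v in d["coef"].items()},
                   se={k: float(v) for k, v in d["se"].items()},
                   n1=int(d["n1"]), n0=int(d["n0"]),
                   iterations=int(d.get("iterations", 0)),
                   grad_norm=float(d.get("grad_norm", float("nan"))),
                   loglik=float(d.get("loglik", float("nan"))),
                   history=list(d.get("history", [])))


def _fit_named(y: np.ndarray, table: pd.DataFrame, included: Sequence[str]) -> LogitFit:
    X = table[list(included)].to_numpy(dtype=float) if included else np.empty((len(y), 0))
    return fit_mle(y, X)


def stepwise_logistic(table: pd.DataFrame, candidates: Sequence[str],
                      alpha_in: float = 0.05, alpha_out: float = 0.10,
                      ) -> LogitModel:
    """Forward-backward stepwise logistic regression.

    Starts from the null (intercept-only) model, whose constant probability
    is the prevalence. Each forward step computes the Rao score test of every
    excluded candidate given the current fit and enters the most significant
    one if its p < alpha_in; after every entry, included variables whose Wald
    p exceeds alpha_out are removed (largest p first). A variable removed
    immediately after entering may not re-enter while the included set is
    unchanged (cycling guard). Stops when no excluded candidate qualifies.
    """
    y = table["presence"].to_numpy(dtype=float)
    included: list[str] = []
    entry_order: list[str] = []
    blocked: set[tuple[str, frozenset]] = set()
    history: list[dict] = []
    fit = _fit_named(y, table, included)
    step = 0
    while True:
        step += 1
        Z = _design(table[included].to_numpy(dtype=float) if included
                    else np.empty((len(y), 0)))
        p = expit(Z @ fit.beta)
        best, best_p, best_stat = None, 1.0, float("nan")
        for c in candidates:
            if c in included or (c, frozenset(included)) in blocked:
                continue
            s, pv = score_test_added(y, Z, p, table[c].to_numpy(dtype=float))
            if pv < best_p:
                best, best_p, best_stat = c, pv, s
        if best is None or best_p >= alpha_in:
            break
        try:
            new_fit = _fit_named(y, table, included + [best])
        except (SeparationError, ConvergenceError) as e:
            raise type(e)(f"step {step} (entering {best!r}): {e}") from e
        included.append(best)
        entry_order.append(best)
        fit = new_fit
        history.append({"step": step, "action": "enter", "variable": best,
                        "score_stat": best_stat, "p": best_p})
        # backward sweep: drop anything no longer significant, largest p first
        while included:
            se = fit.se
            walds = {v: (fit.beta[k + 1] / se[k + 1]) ** 2
                     for k, v in enumerate(included)}
            pvals = {v: float(stats.chi2.sf(w, df=1)) for v, w in walds.items()}
            worst = max(included, key=lambda v: pvals[v])
            if pvals[worst] <= alpha_out:
                break
            before = frozenset(included)
            included.remove(worst)
            if worst == entry_order[-1]:
                blocked.add((worst, frozenset(included)))
            entry_order.remove(worst)
            try:
                fit = _fit_named(y, table, included)
            except (SeparationError, ConvergenceError) as e:
                raise type(e)(f"step {step} (removing {worst!r}): {e}") from e
            history.append({"step": step, "action": "remove", "variable": worst,
                            "p": pvals[worst], "included_before": sorted(before)})
    n1 = int(y.sum())
    se_named = {"(Constant)": float(fit.se[0])}
    coef = {}
    for k, v in enumerate(entry_order):
        j = included.index(v) + 1
        coef[v] = float(fit.beta[j])
        se_named[v] = float(fit.se[j])
    return LogitModel(variables=entry_order, intercept=float(fit.beta[0]),
                      coef=coef, se=se_named, n1=n1, n0=int(len(y) - n1),
                      iterations=fit.iterations, grad_norm=fit.grad_norm,
                      loglik=fit.loglik, history=history)


# ---------------------------------------------------------------------------
# favourability


def favourability(P, n1: int, n0: int):
    """Prevalence-free favourability of a probability.

    F = odds(P) / (n1/n0 + odds(P)), equivalently expit(logit(P) - ln(n1/n0)).
    Strictly increasing bijection of [0, 1] onto itself (endpoints by
    continuity); F = 0.5 exactly at P = n1/(n1+n0).
    """
    if n1 < 1 or n0 < 1:
        raise ValueError("n1 and n0 must both be at least 1")
    P = np.asarray(P, dtype=float)
    if np.any((P < 0) | (P > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        out = expit(logit(P) - np.log(n1 / n0))
    # continuity at the endpoints, exact
    out = np.where(P == 0.0, 0.0, np.where(P == 1.0, 1.0, out))
    return float(out) if out.ndim == 0 else out


def favourability_from_logit(eta, n1: int, n0: int):
    """Favourability straight from the linear predictor (overflow-safe)."""
    if n1 < 1 or n0 < 1:
        raise ValueError("n1 and n0 must both be at least 1")
    return expit(np.asarray(eta, dtype=float) - np.log(n1 / n0))


def inverse_favourability(F, n1: int, n0: int):
    """Probability whose favourability is F (the exact inverse map)."""
    F = np.asarray(F, dtype=float)
    with np.errstate(divide="ignore"):
        out = expit(logit(F) + np.log(n1 / n0))
    out = np.where(F == 0.0, 0.0, np.where(F == 1.0, 1.0, out))
    return float(out) if out.ndim == 0 else out


def classify(F, lower: float = 0.2, upper: float = 0.8) -> np.ndarray:
    """Fuzzy three-band classification of favourability values.

    > upper (default 0.8, odds better than 4:1) highly favourable, < lower
    (default 0.2, odds worse than 1:4) unfavourable; both boundaries are
    inclusive to the intermediate band (lower <= F <= upper).
    """
    F = np.atleast_1d(np.asarray(F, dtype=float))
    if np.any((F < 0) | (F > 1)):
        raise ValueError("favourability must lie in [0, 1]")
    if not 0 < lower < upper < 1:
        raise ValueError("bands must satisfy 0 < lower < upper < 1")
    out = np.where(F > upper, CATEGORIES[2],
                   np.where(F < lower, CATEGORIES[0], CATEGORIES[1]))
    return out.astype(object)


def predict_surface(model: LogitModel, table: pd.DataFrame) -> pd.DataFrame:
    """Per-OGU probability, favourability and fuzzy category for a table."""
    eta = model.linear_predictor(table)
    P = expit(eta)
    F = favourability_from_logit(eta, model.n1, model.n0)
    return pd.DataFrame({
        "ogu_id": table["ogu_id"].to_numpy(),
        "P": P, "F": F, "category": classify(F),
    })


def response_curve(model: LogitModel, table: pd.DataFrame, variable: str,
                   n_points: int = 20) -> pd.DataFrame:
    """Mean favourability across the variable's observed range in equal bins.

    The range is split into ``n_points`` equal-width bins; each point is the
    mean favourability of the OGUs falling in that bin (NaN where a bin is
    empty), plotted against the bin midpoint.
    """
    if variable not in model.variables:
        raise KeyError(f"{variable!r} is not in the fitted model")
    x = table[variable].to_numpy(dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError(f"{variable!r} is constant; no range to profile")
    edges = np.linspace(lo, hi, n_points + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_points - 1)
    F = predict_surface(model, table)["F"].to_numpy()
    mean_F = np.full(n_points, np.nan)
    for b in range(n_points):
        sel = idx == b
        if sel.any():
            mean_F[b] = F[sel].mean()
    return pd.DataFrame({"midpoint": mid, "mean_favourability": mean_F})


def wald_table(model: LogitModel) -> pd.DataFrame:
    """Table-1-style report: beta, S.E., Wald = (beta/S.E.)^2, p; rows in
    entry order with the constant last."""
    rows = []
    for v in model.variables + ["(Constant)"]:
        b = model.intercept if v == "(Constant)" else model.coef[v]
        se = model.se[v]
        w = (b / se) ** 2 if se > 0 else (0.0 if b == 0 else float("inf"))
        p = float(stats.chi2.sf(w, df=1)) if np.isfinite(w) else 0.0
        rows.append({"variable": v, "beta": b, "se": se, "wald": w, "p": p})
    return pd.DataFrame(rows)
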