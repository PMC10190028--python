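"""Projection onto future climates and fuzzy ensemble forecasting.

The fitted coefficients are kept fixed and the climatic covariates in the
linear predictor are replaced by each scenario's expected values (topography
is carried over from the present unchanged). Each scenario yields a future
favourability surface; per period the surfaces are combined as

* ensemble mean  — arithmetic mean favourability per OGU;
* fuzzy union    — per-OGU maximum over members;
* fuzzy intersection — per-OGU minimum;
* uncertainty    — union minus intersection (0 iff all members agree).

Favourability values are degrees of membership in the fuzzy set of areas
favourable for breeding, which is what licenses the union/intersection
reading. An environmental-novelty check reports how much of each scenario
lies inside the training range of the model variables; it is reported only,
never used to mask projections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalogue import TOPOGRAPHIC
from .model import LogitModel, predict_surface
from .synthetic import Scenario, ScenarioSet  # canonical containers


def novelty_check(training: pd.DataFrame, scenario: pd.DataFrame,
                  variables: Sequence[str]) -> dict:
    """Fraction of scenario values lying within the training min-max range.

    Checked per model variable and per OGU; returns the overall fraction and
    a per-variable breakdown.
    """
    per_var: dict[str, float] = {}
    total = within = 0
    for v in variables:
        if v not in scenario.columns:
            raise KeyError(f"variable {v!r} missing from the scenario table")
        lo = float(training[v].min())
        hi = float(training[v].max())
        vals = scenario[v].to_numpy(dtype=float)
        ok = (vals >= lo) & (vals <= hi)
        per_var[v] = float(ok.mean())
        within += int(ok.sum())
        total += ok.size
    return {"fraction_within": within / total if total else float("nan"),
            "per_variable": per_var}


def project(model: LogitModel, scenario: pd.DataFrame,
            present: pd.DataFrame | None = None) -> pd.DataFrame:
    """Favourability surface under a scenario, with the present-day fit.

    Non-climatic model variables (e.g. altitude) may be absent from the
    scenario table; they are then taken from ``present`` unchanged. The
    favourability transform uses the training n1, n0 — prevalence is a
    property of the training data, not of the future.
    """
    table = scenario.copy()
    for v in model.variables:
        if v not in table.columns:
            if present is not None and v in TOPOGRAPHIC and v in present.columns:
                table[v] = present[v].to_numpy()
            else:
                raise KeyError(f"scenario table lacks model variable {v!r}")
    return predict_surface(model, table)


def _aligned_F(surfaces: Sequence[pd.DataFrame]) -> tuple[np.ndarray, np.ndarray]:
    if not surfaces:
        raise ValueError("need at least one surface")
    ids = surfaces[0]["ogu_id"].to_numpy()
    mat = np.empty((len(surfaces), len(ids)))
    for k, s in enumerate(surfaces):
        if not np.array_equal(s["ogu_id"].to_numpy(), ids):
            raise ValueError("surfaces are not aligned on the same OGU ids")
        mat[k] = s["F"].to_numpy(dtype=float)
    return ids, mat


def ensemble_mean(surfaces: Sequence[pd.DataFrame]) -> pd.DataFrame:
    ids, F = _aligned_F(surfaces)
    return pd.DataFrame({"ogu_id": ids, "F_mean": F.mean(axis=0)})


@dataclass
class EnsembleResult:
    """Per-OGU ensemble statistics and their scalar summaries."""

    table: pd.DataFrame          # ogu_id, F_mean, F_union, F_intersection, uncertainty
    n_members: int
    mean_uncertainty: float
    mean_favourability: float

    def summary(self) -> dict:
        return {"n_members": self.n_members,
                "mean_uncertainty": self.mean_uncertainty,
                "mean_favourability": self.mean_favourability}

    def to_json(self, **kw) -> str:
        return json.dumps(self.summary(), sort_keys=True, **kw)


def fuzzy_uncertainty(surfaces: Sequence[pd.DataFrame]) -> EnsembleResult:
    """Ensemble mean plus fuzzy union/intersection and their difference."""
    ids, F = _aligned_F(surfaces)
    union = F.max(axis=0)
    inter = F.min(axis=0)
    table = pd.DataFrame({
        "ogu_id": ids,
        "F_mean": F.mean(axis=0),
        "F_union": union,
        "F_intersection": inter,
        "uncertainty": union - inter,
    })
    return EnsembleResult(table=table, n_members=F.shape[0],
                          mean_uncertainty=float((union - inter).mean()),
                          mean_favourability=float(F.mean()))


def project_ensemble(model: LogitModel, scenarios: ScenarioSet,
                     present: pd.DataFrame) -> dict[str, EnsembleResult]:
    """Project every member of every period and ensemble them."""
    out: dict[str, EnsembleResult] = {}
    for period, members in sorted(scenarios.periods.items()):
        surfaces = [project(model, m.table, present=present) for m in members]
        out[period] = fuzzy_uncertainty(surfaces)
    return out
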