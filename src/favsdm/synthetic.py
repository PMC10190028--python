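"""Synthetic stand-in for the eBird / WorldClim inputs.

Generates, under one explicit seed: a covariate grid with a controlled
Spearman correlation structure (Gaussian copula on a latent correlation
matrix, then monotone marginal transforms, so the rank-correlation targets
survive); binary breeding presence from a known sparse logit at a calibrated
prevalence; perturbed future-scenario covariate tables (climate shifted,
topography fixed); and point occurrence records, including decoys outside
the breeding window, so the gridding filters are exercised end to end.

The defaults emulate the study conditions of the real dataset this package
was designed around: ~4177 one-degree cells over the Western Palearctic,
21 covariates (2 topographic, 19 bioclimatic) with several pairs correlated
above 0.8, prevalence 0.025 driven by three active variables (warm-quarter
precipitation negative, annual precipitation and altitude positive), and
8 scenario tables (4 RCPs x 2 GCMs) for each of two future periods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import catalogue
from .catalogue import CLIMATIC, TOPOGRAPHIC, Variable
from .grid import BREEDING_WINDOW, GridSpec, build_grid

logger = logging.getLogger(__name__)

RCPS = ("2.6", "4.5", "6.0", "8.5")
GCMS = ("HadGEM2-ES", "NorESM1-M")
PERIODS = ("2041-2060", "2061-2080")

#: additional mean warming (degC) per RCP, by period — plausible mid-range
#: values for the two horizons; the exact numbers only need to order the
#: scenarios and make the ensemble members disagree.
_WARMING = {
    "2041-2060": {"2.6": 1.2, "4.5": 1.6, "6.0": 1.8, "8.5": 2.2},
    "2061-2080": {"2.6": 1.3, "4.5": 2.1, "6.0": 2.6, "8.5": 3.6},
}
_GCM_OFFSET = {"HadGEM2-ES": 0.3, "NorESM1-M": -0.1}  # HadGEM2 runs warmer
#: fractional precipitation change per degree of warming (Mediterranean-style
#: drying), applied as an additive offset on each precipitation variable.
_PRECIP_PER_DEGC = -0.03

_TEMPERATURE_VARS = ("Tmean", "Tmax", "Tmin", "Twet", "Tdry", "Twarm", "Tcold")
_PRECIP_VARS = ("Prec", "Pmax", "Pmin", "Pwet", "Pdry", "Pwarm", "Pcold")


class InfeasibleCorrelationError(ValueError):
    """The requested latent correlation structure is not positive definite."""


def default_correlations() -> list[tuple[str, str, float]]:
    """Disjoint correlated pairs, several above the 0.8 screening threshold."""
    return [
        ("Tmax", "Twarm", 0.90),
        ("Tmean", "Tcold", 0.85),
        ("Pwet", "Pmax", 0.90),
        ("Prec", "Pcold", 0.82),
        ("Pwarm", "Pdry", 0.60),
        ("Alti", "Slope", 0.50),
        ("Tmin", "Twet", 0.70),
        ("Rtan", "Season", 0.75),
    ]


def default_shifts() -> dict[str, dict[str, dict[str, tuple[float, float]]]]:
    """period -> scenario id -> variable -> (additive offset, noise sd)."""
    shifts: dict[str, dict[str, dict[str, tuple[float, float]]]] = {}
    for period in PERIODS:
        shifts[period] = {}
        for rcp in RCPS:
            for gcm in GCMS:
                sid = f"RCP{rcp}_{gcm}"
                dT = _WARMING[period][rcp] + _GCM_OFFSET[gcm]
                per_var: dict[str, tuple[float, float]] = {}
                for code in _TEMPERATURE_VARS:
                    per_var[code] = (dT, 0.3)
                for code in _PRECIP_VARS:
                    base = catalogue.by_code(code).loc
                    per_var[code] = (base * _PRECIP_PER_DEGC * dT, 0.05 * base)
                shifts[period][sid] = per_var
    return shifts


@dataclass
class SyntheticSpec:
    """Everything the generator needs, seeds included — no global state."""

    n_ogus: int = 4177
    variables: tuple[Variable, ...] = catalogue.VARIABLES
    correlations: list[tuple[str, str, float]] = field(default_factory=default_correlations)
    true_beta: dict[str, float] = field(
        default_factory=lambda: {"Pwarm": -0.026, "Prec": 0.0017, "Alti": 0.0015})
    target_prevalence: float = 0.025
    shifts: dict[str, dict[str, dict[str, tuple[float, float]]]] = field(
        default_factory=default_shifts)
    grid: GridSpec = field(default_factory=GridSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_prevalence < 1.0):
            raise ValueError("target prevalence must lie strictly in (0, 1)")
        if self.n_ogus < 50:
            raise ValueError("n_ogus must be at least 50")
        codes = {v.code for v in self.variables}
        named = set(self.true_beta)
        for a, b, _ in self.correlations:
            named |= {a, b}
        unknown = named - codes
        if unknown:
            raise ValueError(f"variables not in the catalogue: {sorted(unknown)}")

    @property
    def codes(self) -> list[str]:
        return [v.code for v in self.variables]


def _latent_correlation(spec: SyntheticSpec) -> np.ndarray:
    """Pearson latent matrix hitting the Spearman targets under the copula.

    For bivariate Gaussian latents, Spearman rho_s relates to the Pearson
    rho by rho = 2 sin(pi rho_s / 6); monotone marginals leave rho_s alone.
    """
    codes = spec.codes
    k = len(codes)
    idx = {c: i for i, c in enumerate(codes)}
    R = np.eye(k)
    for a, b, rs in spec.correlations:
        rho = 2.0 * np.sin(np.pi * rs / 6.0)
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = rho
    w = np.linalg.eigvalsh(R)
    if w.min() <= 1e-10:
        raise InfeasibleCorrelationError(
            "latent correlation matrix is not positive definite; "
            f"offending targets: {spec.correlations}")
    return R


def gen_covariates(spec: SyntheticSpec) -> pd.DataFrame:
    """Covariate-only OGU table with the requested rank-correlation structure."""
    R = _latent_correlation(spec)
    rng = np.random.default_rng([spec.seed, 1])
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((spec.n_ogus, len(spec.codes))) @ L.T

    cells = build_grid(spec.grid)
    if len(cells) < spec.n_ogus:
        raise ValueError(
            f"grid has {len(cells)} cells, fewer than n_ogus={spec.n_ogus}")
    table = cells.iloc[: spec.n_ogus].reset_index(drop=True)

    for col, v in zip(Z.T, spec.variables):
        if v.kind == "nonneg":
            table[v.code] = v.loc * np.exp(v.scale * col)
        else:
            table[v.code] = v.loc + v.scale * col
    return table


def _linear_predictor(table: pd.DataFrame, beta: Mapping[str, float]) -> np.ndarray:
    eta = np.zeros(len(table))
    for code, b in beta.items():
        eta += b * table[code].to_numpy()
    return eta


def calibrate_intercept(eta: np.ndarray, target_prevalence: float,
                        lo: float = -30.0, hi: float = 30.0) -> float:
    """Intercept such that the mean Bernoulli probability hits the target.

    The mean of expit(a + eta) is strictly increasing in a, so a root
    bracketed on [lo, hi] is unique; solved to 1e-6 on the mean.
    """
    def gap(a: float) -> float:
        return float(expit(a + eta).mean()) - target_prevalence

    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"target prevalence {target_prevalence} unattainable with "
            f"intercept in [{lo}, {hi}] for the given coefficients")
    return float(brentq(gap, lo, hi, xtol=1e-12))


@dataclass
class PresenceSimulation:
    table: pd.DataFrame          # covariates + presence + true_probability
    intercept: float             # calibrated true intercept
    true_beta: dict[str, float]


def gen_presence(covariates: pd.DataFrame, true_beta: Mapping[str, float],
                 target_prevalence: float, seed: int) -> PresenceSimulation:
    """Draw presence ~ Bernoulli(sigmoid(a + X beta)) at calibrated prevalence."""
    missing = [c for c in true_beta if c not in covariates.columns]
    if missing:
        raise KeyError(f"true_beta names absent from the covariate table: {missing}")
    eta = _linear_predictor(covariates, true_beta)
    a = calibrate_intercept(eta, target_prevalence)
    p = expit(a + eta)
    rng = np.random.default_rng([seed, 2])
    table = covariates.copy()
    table["true_probability"] = p
    table["presence"] = (rng.random(len(p)) < p).astype(int)
    return PresenceSimulation(table=table, intercept=a, true_beta=dict(true_beta))


@dataclass
class Scenario:
    scenario_id: str
    table: pd.DataFrame


@dataclass
class ScenarioSet:
    """Labelled future covariate tables, grouped by period, aligned on OGUs."""

    periods: dict[str, list[Scenario]]

    def __post_init__(self) -> None:
        ids = None
        for members in self.periods.values():
            for s in members:
                cur = tuple(s.table["ogu_id"])
                if ids is None:
                    ids = cur
                elif cur != ids:
                    raise ValueError("scenario members do not share identical OGU ids")


def gen_scenarios(covariates: pd.DataFrame, spec: SyntheticSpec) -> ScenarioSet:
    """Perturbed climate tables per period; topography carried over unchanged."""
    periods: dict[str, list[Scenario]] = {}
    for pi, (period, members) in enumerate(sorted(spec.shifts.items())):
        periods[period] = []
        for si, (sid, per_var) in enumerate(sorted(members.items())):
            bad = sorted(set(per_var) & TOPOGRAPHIC)
            if bad:
                raise ValueError(
                    f"scenario {sid!r} shifts topographic variable(s) {bad}; "
                    "topography does not change in the future")
            rng = np.random.default_rng([spec.seed, 3, pi, si])
            tab = covariates.copy()
            tab = tab.drop(columns=[c for c in ("presence", "true_probability")
                                    if c in tab.columns])
            for code, (offset, noise_sd) in sorted(per_var.items()):
                col = tab[code].to_numpy(dtype=float)
                col = col + offset
                if noise_sd > 0:
                    col = col + rng.normal(0.0, noise_sd, size=len(col))
                if catalogue.by_code(code).kind == "nonneg":
                    col = np.clip(col, 0.0, None)
                tab[code] = col
            periods[period].append(Scenario(scenario_id=sid, table=tab))
    return ScenarioSet(periods=periods)


def gen_point_records(presence: pd.DataFrame, seed: int,
                      grid: GridSpec | None = None,
                      n_decoy_absence: int = 50) -> pd.DataFrame:
    """Occurrence records consistent with the presence table, plus decoys.

    Every presence cell gets 1-3 records dated inside the breeding window and
    placed inside the cell. Decoys — presence-cell records dated outside the
    window, and records in absence cells also dated outside the window — are
    added so the season filter and the presence assignment have something to
    reject; filtering then gridding the output reproduces ``presence``.
    """
    grid = grid or GridSpec()
    rng = np.random.default_rng([seed, 4])
    (m0, d0), (m1, d1) = BREEDING_WINDOW
    lons: list[float] = []
    lats: list[float] = []
    dates: list[pd.Timestamp] = []

    def cell_point(row) -> tuple[float, float]:
        x0 = grid.lon_min + row.lon_idx * grid.cell_size
        y0 = grid.lat_min + row.lat_idx * grid.cell_size
        return (x0 + rng.random() * grid.cell_size,
                y0 + rng.random() * grid.cell_size)

    def window_date() -> pd.Timestamp:
        year = int(rng.integers(2000, 2021))
        start = pd.Timestamp(year, m0, d0)
        span = (pd.Timestamp(year, m1, d1) - start).days
        return start + pd.Timedelta(days=int(rng.integers(0, span + 1)))

    def offseason_date() -> pd.Timestamp:
        year = int(rng.integers(2000, 2021))
        return pd.Timestamp(year, 12, 1) + pd.Timedelta(days=int(rng.integers(0, 28)))

    pres = presence[presence["presence"] == 1]
    absn = presence[presence["presence"] == 0]
    for row in pres.itertuples():
        for _ in range(int(rng.integers(1, 4))):
            lon, lat = cell_point(row)
            lons.append(lon); lats.append(lat); dates.append(window_date())
        lon, lat = cell_point(row)           # off-season decoy in a presence cell
        lons.append(lon); lats.append(lat); dates.append(offseason_date())
    n_dec = min(n_decoy_absence, len(absn))
    if n_dec:
        pick = absn.iloc[rng.choice(len(absn), size=n_dec, replace=False)]
        for row in pick.itertuples():        # off-season decoys in absence cells
            lon, lat = cell_point(row)
            lons.append(lon); lats.append(lat); dates.append(offseason_date())
    return pd.DataFrame({"longitude": lons, "latitude": lats, "date": dates})
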