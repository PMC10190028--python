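"""End-to-end orchestration: grid -> screen -> fit -> assess -> project.

A single :class:`RunConfig` drives the whole analysis, either from delimited
input files (occurrence records, covariate table, scenario tables) or from
the synthetic generator. Every stage writes its artifact to the output
directory and contributes to one machine-readable JSON run report; a fixed
seed makes the report byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import grid as gridmod
from . import synthetic as synth
from .catalogue import CODES
from .evaluation import evaluate
from .grid import BREEDING_WINDOW, GridSpec
from .model import classify, predict_surface, stepwise_logistic, wald_table
from .projection import fuzzy_uncertainty, novelty_check, project
from .screening import screen
from .synthetic import Scenario, ScenarioSet, SyntheticSpec

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; encodes the study defaults.

    Exactly one of (``records_path`` + ``covariates_path``) or ``synthetic``
    must be provided.
    """

    records_path: str | None = None
    covariates_path: str | None = None
    scenario_paths: dict[str, dict[str, str]] | None = None  # period -> id -> path
    synthetic: SyntheticSpec | None = None
    grid: GridSpec = field(default_factory=GridSpec)
    breeding_window: tuple = BREEDING_WINDOW
    variables: tuple[str, ...] = CODES
    r_threshold: float = 0.8
    fdr_q: float = 0.05
    alpha_in: float = 0.05
    alpha_out: float = 0.10
    band_lower: float = 0.2
    band_upper: float = 0.8
    eval_threshold: float = 0.5
    seed: int = 0
    outdir: str = "results/run"

    def __post_init__(self) -> None:
        from_files = self.records_path is not None or self.covariates_path is not None
        if from_files == (self.synthetic is not None):
            raise ValueError(
                "provide exactly one of input paths or a synthetic spec")
        if from_files and (self.records_path is None or self.covariates_path is None):
            raise ValueError("both records_path and covariates_path are required")
        for t in (self.r_threshold, self.fdr_q, self.alpha_in, self.alpha_out,
                  self.band_lower, self.band_upper, self.eval_threshold):
            if not (0.0 < t < 1.0):
                raise ValueError(f"threshold {t} outside (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "grid" in raw:
            raw["grid"] = GridSpec(**raw["grid"])
        if raw.get("synthetic") is not None:
            s = raw["synthetic"]
            raw["synthetic"] = SyntheticSpec(**s) if isinstance(s, dict) else s
        if "breeding_window" in raw:
            (m0, d0), (m1, d1) = raw["breeding_window"]
            raw["breeding_window"] = ((int(m0), int(d0)), (int(m1), int(d1)))
        if "variables" in raw:
            raw["variables"] = tuple(raw["variables"])
        return cls(**raw)


def _load_scenarios(cfg: RunConfig) -> ScenarioSet | None:
    if cfg.scenario_paths is None:
        return None
    periods = {
        period: [Scenario(sid, pd.read_csv(path))
                 for sid, path in sorted(members.items())]
        for period, members in sorted(cfg.scenario_paths.items())
    }
    return ScenarioSet(periods=periods)


def _prepare_inputs(cfg: RunConfig):
    """Assemble the modelling table (covariates + presence) and scenarios."""
    if cfg.synthetic is not None:
        spec = cfg.synthetic
        cov = synth.gen_covariates(spec)
        sim = synth.gen_presence(cov, spec.true_beta, spec.target_prevalence,
                                 seed=spec.seed)
        records = synth.gen_point_records(
            sim.table[["ogu_id", "lon_idx", "lat_idx", "presence"]],
            seed=spec.seed, grid=spec.grid)
        scenarios = synth.gen_scenarios(cov, spec)
        grid_cells = cov[["ogu_id", "lon_idx", "lat_idx"]]
        gspec = spec.grid
    else:
        records = gridmod.read_records(cfg.records_path)
        cov = pd.read_csv(cfg.covariates_path)
        grid_cells = cov[["ogu_id", "lon_idx", "lat_idx"]]
        scenarios = _load_scenarios(cfg)
        gspec = cfg.grid
    # grid the records: season filter, then binary presence per cell
    season = gridmod.filter_breeding_season(records, cfg.breeding_window)
    with_presence = gridmod.assign_presence(season, grid_cells, gspec)
    table = cov.drop(columns=[c for c in ("presence", "true_probability")
                              if c in cov.columns])
    table = table.merge(with_presence[["ogu_id", "presence"]], on="ogu_id")
    return table, records, scenarios


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return (and write) the JSON-ready run report."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    table, records, scenarios = _prepare_inputs(cfg)
    variables = [v for v in cfg.variables if v in table.columns]
    gridmod.write_records(records, out / "records.csv")
    gridmod.write_ogu_table(table, out / "ogu_table.csv")
    n1, n0 = gridmod.presence_counts(table)
    logger.info("OGU table: %d cells, n1=%d, n0=%d", len(table), n1, n0)

    report: dict = {
        "n_ogus": int(len(table)),
        "n1": n1,
        "n0": n0,
        "prevalence": n1 / (n1 + n0),
        "seed": cfg.seed,
    }

    screening = screen(table, variables, r_threshold=cfg.r_threshold, q=cfg.fdr_q)
    (out / "screening.json").write_text(screening.to_json(indent=2))
    report["screening"] = screening.to_dict()
    logger.info("screening: %d candidates -> %d accepted",
                len(variables), len(screening.accepted))

    model = stepwise_logistic(table, screening.accepted,
                              alpha_in=cfg.alpha_in, alpha_out=cfg.alpha_out)
    (out / "model.json").write_text(model.to_json(indent=2))
    t1 = wald_table(model)
    t1.to_csv(out / "coefficients.csv", index=False)
    report["model"] = model.to_dict()
    report["coefficients"] = t1.to_dict(orient="records")

    surface = predict_surface(model, table)
    surface["category"] = classify(surface["F"].to_numpy(),
                                   cfg.band_lower, cfg.band_upper)
    surface.to_csv(out / "surface_present.csv", index=False)
    report["present_surface"] = {
        "mean_F": float(surface["F"].mean()),
        "category_counts": surface["category"].value_counts().to_dict(),
    }

    ev = evaluate(surface["F"].to_numpy(), table["presence"].to_numpy(),
                  threshold=cfg.eval_threshold)
    (out / "evaluation.json").write_text(ev.to_json(indent=2))
    report["evaluation"] = json.loads(ev.to_json())

    if scenarios is not None and scenarios.periods:
        report["projection"] = {}
        for period, members in sorted(scenarios.periods.items()):
            surfaces, novelty = [], {}
            for m in members:
                novelty[m.scenario_id] = novelty_check(
                    table, m.table, model.variables)["fraction_within"]
                surfaces.append(project(model, m.table, present=table))
            ens = fuzzy_uncertainty(surfaces)
            ens.table.to_csv(out / f"ensemble_{period}.csv", index=False)
            report["projection"][period] = {
                "novelty_fraction_within": novelty,
                **ens.summary(),
            }

    payload = json.dumps(report, sort_keys=True, indent=2, allow_nan=True)
    (out / "report.json").write_text(payload)
    return report
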