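#!/usr/bin/env python
"""Project the fitted logit onto the future climate scenarios.

For each period the eight scenario tables (4 RCPs x 2 GCMs) are pushed
through the unchanged coefficients (topography carried from the present),
checked for environmental novelty against the training range, and combined
into an ensemble: mean favourability, fuzzy union (per-OGU max), fuzzy
intersection (per-OGU min) and their difference as the uncertainty.
"""

import json
from pathlib import Path

import pandas as pd

from favsdm import (LogitModel, fuzzy_uncertainty, novelty_check, project,
                    read_ogu_table)

OUT = Path("results")


def main() -> None:
    table = read_ogu_table(OUT / "data" / "ogu_table.csv")
    model = LogitModel.from_dict(json.loads((OUT / "model.json").read_text()))
    summary = {}
    for path in sorted((OUT / "data").glob("scenario_*.csv")):
        _, period, sid = path.stem.split("_", 2)
        scen = pd.read_csv(path)
        nov = novelty_check(table, scen, model.variables)
        surf = project(model, scen, present=table)
        summary.setdefault(period, {"surfaces": [], "novelty": {}})
        summary[period]["surfaces"].append(surf)
        summary[period]["novelty"][sid] = nov["fraction_within"]

    report = {}
    for period, d in sorted(summary.items()):
        ens = fuzzy_uncertainty(d["surfaces"])
        ens.table.to_csv(OUT / f"ensemble_{period}.csv", index=False)
        worst_novelty = min(d["novelty"].values())
        report[period] = {**ens.summary(),
                          "min_novelty_fraction": worst_novelty}
        print(f"{period}: ensemble of {ens.n_members} members, "
              f"mean favourability {ens.mean_favourability:.3f}, "
              f"mean uncertainty {ens.mean_uncertainty:.3f}; "
              f">= {worst_novelty:.1%} of projected values inside the "
              f"training range in every member")
    (OUT / "projection_summary.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
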