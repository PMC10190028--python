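#!/usr/bin/env python
"""Assess discrimination and classification of the present-day model.

AUC (rank-sum, with a tie-corrected normal-approximation p-value) plus the
classification measures at the neutrality threshold F = 0.5: sensitivity,
specificity, over-prediction rate (absences inside the favourable area) and
under-prediction rate (presences inside the unfavourable area). With a
prevalence near 0.025 a good model still over-predicts heavily: most of the
favourable area holds no recorded breeding.
"""

import pandas as pd
from pathlib import Path

from favsdm import evaluate, read_ogu_table

OUT = Path("results")


def main() -> None:
    table = read_ogu_table(OUT / "data" / "ogu_table.csv")
    surface = pd.read_csv(OUT / "surface_present.csv")
    rep = evaluate(surface["F"].to_numpy(), table["presence"].to_numpy())
    (OUT / "evaluation.json").write_text(rep.to_json(indent=2))

    print(f"AUC = {rep.auc:.3f} (p = {rep.auc_p:.3g})")
    print(f"sensitivity = {rep.sensitivity:.3f}, specificity = {rep.specificity:.3f}")
    print(f"OPR = {rep.opr:.3f}, UPR = {rep.upr:.3f}")
    print(f"confusion at F > 0.5: TP={rep.tp} FP={rep.fp} TN={rep.tn} FN={rep.fn}")


if __name__ == "__main__":
    main()
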