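#!/usr/bin/env python
"""LLoQ retention, modified z-scores and quartile stimulator groups.

Reads results/measurements.csv, drops analytes with more than 40% of
observations below the LLoQ, imputes sporadic censored values at LLoQ/2,
standardizes each analyte with the robust modified z-score
0.6745 * (x - median) / MAD, averages over donors, and labels top/bottom
quartile "high"/"low" stimulator cell lines per analyte.
"""

import json
from pathlib import Path

import pandas as pd

from tamscreen import scoring, simulate
from tamscreen.config import PipelineConfig
from tamscreen.io import read_measurement_table, write_results_table

SEED = 20260922
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = PipelineConfig(seed=SEED)
    truth = json.loads((OUT / "truth.json").read_text())
    scen = simulate.make_default_scenario(SEED)
    lloq_map = {a.name: a.lloq for a in scen.analytes}
    table = read_measurement_table(OUT / "measurements.csv", lloq_map)

    retained, excluded = scoring.filter_analytes_by_lloq(
        table, cfg.lloq_exclusion_fraction
    )
    print(f"retained {len(retained)}/{len(lloq_map)} analytes: {', '.join(retained)}")
    for name, frac in excluded:
        print(f"  excluded {name}: {frac:.0%} of observations below LLoQ")

    imputed = scoring.impute_censored(table, cfg.censored_imputation)
    matrix = scoring.score_table(imputed, retained,
                                 control_units={simulate.CONTROL_UNIT})
    write_results_table(matrix.per_unit, OUT / "scores_per_unit.csv",
                        cfg.to_dict(), SEED)

    labels = []
    for analyte in retained:
        lab = matrix.quartile_labels(analyte)
        top, bottom = scoring.assign_quartiles(matrix, analyte)
        labels.append(pd.DataFrame({"analyte": analyte, "unit": lab.index,
                                    "label": lab.to_numpy()}))
        print(f"{analyte}: top quartile {sorted(top)}")
    write_results_table(pd.concat(labels, ignore_index=True),
                        OUT / "quartile_labels.csv", cfg.to_dict(), SEED)


if __name__ == "__main__":
    main()
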