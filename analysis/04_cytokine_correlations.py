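#!/usr/bin/env python
"""Pairwise Spearman correlations between analytes' donor-mean scores
(21 pairs for a 7-analyte panel), BH-adjusted across the family."""

from pathlib import Path

from tamscreen import scoring, simulate
from tamscreen.association import pairwise_cytokine_correlations
from tamscreen.config import PipelineConfig
from tamscreen.io import read_measurement_table, write_results_table

SEED = 20260922
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = PipelineConfig(seed=SEED)
    scen = simulate.make_default_scenario(SEED)
    table = read_measurement_table(OUT / "measurements.csv",
                                   {a.name: a.lloq for a in scen.analytes})
    retained, _ = scoring.filter_analytes_by_lloq(table, cfg.lloq_exclusion_fraction)
    matrix = scoring.score_table(scoring.impute_censored(table), retained,
                                 control_units={simulate.CONTROL_UNIT})
    corr = pairwise_cytokine_correlations(matrix)
    write_results_table(corr, OUT / "cytokine_correlations.csv", cfg.to_dict(), SEED)
    best = corr.loc[corr["rho"].abs().idxmax()]
    print(f"{len(corr)} analyte pairs; strongest: "
          f"{best['analyte_a']}-{best['analyte_b']} rho={best['rho']:.3f} "
          f"(BH p={best['p_adj_bh']:.3g})")


if __name__ == "__main__":
    main()
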