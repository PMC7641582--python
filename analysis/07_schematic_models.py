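#!/usr/bin/env python
"""Sharpened-signal vs prediction-error schematic simulation (1000 reps).

Degrades binary word patterns ('clay' spoken; 'clay' or 'fast' as the
written prediction), adds uniform noise, and compares the two coding
schemes.  Prints the mean representational fidelity (squared correlation
with clean 'clay') per condition and the total |prediction error|, and
writes the summary table.  The prediction-error scheme shows the crossover
(fidelity falls with detail under matching priors, rises under mismatching
ones); sharpening improves with detail under both priors; |PE| is always
smallest when priors match.
"""

import logging
import warnings
from pathlib import Path

from stmtrf.schematic import run_grid, summarize_grid

SEED = 1
OUT = Path("results")


def main() -> None:
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    warnings.filterwarnings("ignore")
    OUT.mkdir(exist_ok=True)
    table = run_grid(n_reps=1000, seed=SEED)
    summary = summarize_grid(table)
    summary.to_csv(OUT / "schematic_summary.csv", index=False)
    fid = summary.pivot_table(index=["scheme", "prior"], columns="level",
                              values="fidelity_mean")[["low", "medium", "high"]]
    logging.info("mean fidelity (R^2 with clean 'clay'):\n%s", fid.round(3).to_string())
    pe = summary.query("scheme == 'prediction_error'").pivot_table(
        index="prior", columns="level", values="pe_magnitude_mean"
    )[["low", "medium", "high"]]
    logging.info("total |prediction error|:\n%s", pe.round(3).to_string())


if __name__ == "__main__":
    main()
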