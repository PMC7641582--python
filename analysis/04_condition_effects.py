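#!/usr/bin/env python
"""Condition effects on encoding accuracy: the prediction-error signature.

Runs the crossover-gain simulation for eight participants, fits per-condition
encoding models with lambda selected by the mode-of-argmax rule, selects the
top sensors per hemisphere, and tests the detail x prior interaction with a
repeated-measures ANOVA (Greenhouse-Geisser corrected).  Then re-runs the
accuracy pipeline under 100 within-trial feature permutations to z-score the
observed accuracies against their empirical null.

Expected result: accuracy rises with sensory detail under Mismatch and falls
under Match (the prediction-error interaction), and the within-trial null is
centred near zero.
"""

import logging
import warnings
from pathlib import Path

from stmtrf.experiments import (
    crossover_interaction_experiment,
    null_z_experiment,
)

SEED = 1
OUT = Path("results")


def main() -> None:
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    warnings.filterwarnings("ignore")
    OUT.mkdir(exist_ok=True)

    res = crossover_interaction_experiment(
        n_per_cell=6, n_sensors=20, n_participants=8, feature_space="envelope", seed=SEED
    )
    res["cells"].to_csv(OUT / "condition_accuracy.csv", index=False)
    res["effects"].to_csv(OUT / "condition_effects.csv", index=False)
    logging.info("selected lambda: %g", res["lambda"])
    means = res["cells"].groupby(["prior", "detail"])["accuracy"].mean()
    logging.info("cell means:\n%s", means.round(3).to_string())
    inter = res["effects"].set_index("effect").loc["prior x detail"]
    logging.info("interaction: F(%d,%d) = %.2f, partial eta2 = %.3f, p = %.2g",
                 inter["df1"], inter["df2"], inter["F"], inter["np2"], inter["p"])
    logging.info("sign pattern (rising under Mismatch, falling under Match): %s",
                 res["pattern"])

    z = null_z_experiment(
        scheme="within_trial_shuffle", n_per_cell=6, n_sensors=8,
        n_perm=100, true_null=False, seed=SEED,
    )
    z.to_csv(OUT / "null_z_within_trial.csv", index=False)
    logging.info("observed accuracies vs within-trial null (z):\n%s",
                 z[["condition", "accuracy", "z"]].round(2).to_string(index=False))


if __name__ == "__main__":
    main()
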