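#!/usr/bin/env python
"""Generate the synthetic experiment: design table, word audio, sensors.

Builds the full-scale 3 x 2 design (78 trials/cell over three blocks),
synthesizes RMS-equalized word-like audio for every trial, forward-simulates
one participant's sensor responses under the crossover gain pattern at
SNR 0 dB, and stores everything under results/ (design CSV, epoch container,
a few example WAVs).
"""

import logging
import warnings
from pathlib import Path

from stmtrf.audio import write_wav
from stmtrf.experiments import build_features
from stmtrf.io import save_epochs, save_features, write_design
from stmtrf.simulate import (
    CROSSOVER_GAIN,
    calibrate_noise_sd,
    make_design,
    make_ground_truth,
    synth_neural,
    synth_word_audio,
)
from stmtrf.trf import LagSpec

SEED = 1
OUT = Path("results")


def main() -> None:
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    warnings.filterwarnings("ignore")
    OUT.mkdir(exist_ok=True)

    design = make_design(78, 3, seed=SEED)
    write_design(OUT / "design.csv", design)
    logging.info("design: %d trials, %s per block", len(design),
                 design.groupby("block").size().tolist())

    lag_spec = LagSpec()
    feats = build_features(design, lag_spec, "envelope", SEED)
    save_features(OUT / "epochs.h5", feats, mode="w")

    truth = make_ground_truth(1, 20, lag_spec, condition_gain=CROSSOVER_GAIN, seed=SEED)
    truth.noise_sd = calibrate_noise_sd(feats, truth, design, snr_db=0.0)
    neural = synth_neural(feats, truth, design, 20)
    save_epochs(OUT / "epochs.h5", neural, mode="a")
    logging.info("simulated %d sensors x %d trials at %.0f Hz (noise SD %.3g)",
                 neural.n_sensors, neural.n_trials, neural.rate, truth.noise_sd)

    wav_dir = OUT / "example_words"
    wav_dir.mkdir(exist_ok=True)
    for wid in design["word_id"].head(3):
        write_wav(wav_dir / f"{wid}.wav", synth_word_audio(wid, seed=SEED))
    logging.info("wrote design, epoch container, and example WAVs to %s/", OUT)


if __name__ == "__main__":
    main()
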