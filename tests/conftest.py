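"""Shared fixtures: small synthetic worlds reused across test modules."""

import numpy as np
import pytest

from stmtrf.features import envelope_feature, prepare
from stmtrf.simulate import (
    make_design,
    make_ground_truth,
    synth_neural,
    synth_word_audio,
)
from stmtrf.trf import LagSpec

SEED = 1234


@pytest.fixture(scope="session")
def lag_spec():
    return LagSpec()


@pytest.fixture(scope="session")
def small_words():
    """Six RMS-matched synthetic words at 16 kHz."""
    return {f"w{i:03d}": synth_word_audio(f"w{i:03d}", seed=SEED) for i in range(6)}


@pytest.fixture(scope="session")
def small_design():
    return make_design(2, seed=SEED)  # 12 trials


@pytest.fixture(scope="session")
def envelope_world(small_design, lag_spec):
    """Prepared envelope features + noiseless ground truth + sensors."""
    feats = {
        w: prepare(
            envelope_feature(synth_word_audio(w, seed=SEED)),
            lag_spec.fit_min_ms,
            lag_spec.fit_max_ms,
        )
        for w in small_design["word_id"]
    }
    truth = make_ground_truth(1, 8, lag_spec, noise_sd=0.0, seed=SEED)
    neural = synth_neural(feats, truth, small_design, 8)
    return {"design": small_design, "feats": feats, "truth": truth, "neural": neural}
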