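"""Synthetic experiment: design table, word-like audio, simulated sensors.

The generator emulates the stated experiment: 468 monosyllabic spoken words
(372-903 ms, mean 591, SD 78) in a 3 x 2 design crossing vocoder sensory
detail (3/6/12 channels) with prior knowledge (Match/Mismatch written text),
78 trials per cell over three blocks of 156 trials.  Sensor responses are
generated by the forward encoding model itself — a lagged linear convolution
of the stimulus features with known temporal response functions — scaled by
a condition-dependent gain (the simulation's stand-in for prediction-error
coding) plus Gaussian white noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio import AudioWaveform
from .trf import LagSpec, TRFModel, lag_matrix

DETAIL_LEVELS = (3, 6, 12)
PRIORS = ("Match", "Mismatch")

# word-duration statistics of the study's recordings, in ms
DURATION_MEAN = 591.0
DURATION_SD = 78.0
DURATION_RANGE = (372.0, 903.0)


def _rng(seed: int, *keys) -> np.random.Generator:
    parts = [int(seed) & 0x7FFFFFFF]
    parts += [zlib.crc32(str(k).encode()) & 0x7FFFFFFF for k in keys]
    return np.random.default_rng(parts)


# ---------------------------------------------------------------------------
# design


def make_design(n_per_cell: int, n_blocks: int = 3, seed: int = 0) -> pd.DataFrame:
    """Trial table for the 3 x 2 (detail x prior) design.

    Every word is spoken exactly once; the written word equals the spoken
    word on Match trials and, on Mismatch trials, is a fixed-point-free
    permutation of the Mismatch trials' spoken words (so every mismatching
    written word is heard as speech on some other trial).
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = _rng(seed, "design")
    n = 6 * n_per_cell
    words = np.array([f"w{i:03d}" for i in range(n)])
    cells = [(d, p) for d in DETAIL_LEVELS for p in PRIORS]
    detail = np.repeat([c[0] for c in cells], n_per_cell)
    prior = np.repeat([c[1] for c in cells], n_per_cell)
    spoken = rng.permutation(words)
    written = spoken.copy()
    mm = np.flatnonzero(prior == "Mismatch")
    if mm.size >= 2:
        # random cyclic derangement of the mismatch trials' spoken words
        order = rng.permutation(mm)
        written[order] = spoken[np.roll(order, 1)]
    order = rng.permutation(n)  # presentation order
    df = pd.DataFrame(
        {
            "word_id": spoken[order],
            "written_word_id": written[order],
            "detail": detail[order],
            "prior": prior[order],
        }
    )
    block_sizes = np.full(n_blocks, n // n_blocks)
    block_sizes[: n % n_blocks] += 1
    df["block"] = np.repeat(np.arange(1, n_blocks + 1), block_sizes)
    df.insert(0, "trial_id", np.arange(n))
    return df


# ---------------------------------------------------------------------------
# word-like audio


def synth_word_audio(
    word_id: str,
    duration_ms: float | None = None,
    rate: float = 16000.0,
    seed: int = 0,
) -> AudioWaveform:
    """A parametric monosyllabic word-like sound, deterministic per (word_id, seed).

    A pitched harmonic source (f0 with a shallow downward glide) is shaped by
    three time-varying formant-like resonances, optionally preceded by a
    brief band-limited noise burst (plosive/fricative-like onset), and
    amplitude-enveloped into a single syllable.
    """
    if rate < 8000:
        raise ValueError("rate must be >= 8 kHz to cover the 5 kHz vocoder band")
    rng = _rng(seed, "word", word_id)
    if duration_ms is None:
        lo, hi = DURATION_RANGE
        duration_ms = float(np.clip(rng.normal(DURATION_MEAN, DURATION_SD), lo, hi))
    if not (DURATION_RANGE[0] <= duration_ms <= DURATION_RANGE[1]):
        raise ValueError(f"duration {duration_ms} ms outside configured range")
    n = int(round(duration_ms * rate / 1000.0))
    t = np.arange(n) / rate
    dur = n / rate

    f0_start = rng.uniform(100.0, 140.0)
    f0 = f0_start * (1.0 - 0.15 * t / dur)  # shallow declination
    f0 *= 1.0 + 0.01 * np.sin(2 * np.pi * rng.uniform(4.0, 7.0) * t)  # jitter
    phase0 = np.cumsum(2.0 * np.pi * f0 / rate)

    # 3 formant trajectories (linear glides), Gaussian resonance gains
    f1 = np.linspace(rng.uniform(300, 800), rng.uniform(300, 800), n)
    f2 = np.linspace(rng.uniform(900, 2200), rng.uniform(900, 2200), n)
    f3 = np.linspace(rng.uniform(2300, 3400), rng.uniform(2300, 3400), n)
    bws = (90.0, 130.0, 180.0)

    top = min(0.45 * rate, 7200.0)
    n_harm = int(top / f0_start)
    x = np.zeros(n)
    for h in range(1, n_harm + 1):
        fh = h * f0
        gain = np.zeros(n)
        for fc, bw in zip((f1, f2, f3), bws):
            gain += np.exp(-0.5 * ((fh - fc) / bw) ** 2)
        gain *= 1.0 / h  # ~ -6 dB/octave source tilt, as for natural voicing
        x += gain * np.sin(h * phase0 + rng.uniform(0, 2 * np.pi))

    # syllabic amplitude envelope: raised-cosine attack and decay
    attack = int(rng.uniform(0.03, 0.08) * rate)
    decay = int(rng.uniform(0.12, 0.2) * rate)
    env = np.ones(n)
    env[:attack] = 0.5 * (1 - np.cos(np.pi * np.arange(attack) / attack))
    env[-decay:] *= 0.5 * (1 + np.cos(np.pi * np.arange(decay) / decay))
    x *= env

    if rng.random() < 0.5:  # onset burst (consonant-like)
        from .vocoder import bandpass

        blen = int(rng.uniform(0.03, 0.06) * rate)
        burst = bandpass(rng.standard_normal(blen), 1500.0, min(6000.0, 0.45 * rate), rate)
        bt = np.arange(blen)
        burst *= np.exp(-bt / (0.015 * rate))
        x[:blen] += burst * np.max(np.abs(x)) * 0.6

    audio = AudioWaveform(x, rate)
    return audio.scaled_to_rms(0.05)


def synth_segmentation(word_id: str, duration_ms: float, seed: int = 0):
    """A plausible phoneme segmentation for a synthetic word (CVC-like)."""
    from .features import PhonemeSegmentation
    from .phonemes import phoneme_feature_table

    rng = _rng(seed, "segmentation", word_id)
    inv = phoneme_feature_table()
    vowels = [p for p in inv.index if inv.loc[p, ["Front", "Central", "Back"]].sum() > 0]
    consonants = [p for p in inv.index if p not in vowels]
    n_seg = int(rng.integers(2, 5))
    labels = []
    for k in range(n_seg):
        pool = vowels if k == n_seg // 2 else consonants
        labels.append(pool[int(rng.integers(len(pool)))])
    cuts = np.sort(rng.uniform(0.1, 0.9, size=n_seg - 1)) * duration_ms
    onsets = np.concatenate([[0.0], cuts])
    return PhonemeSegmentation(list(zip(labels, onsets)), duration_ms)


def ripple_sound(
    omega_s: float,
    omega_t: float,
    duration_s: float = 1.0,
    rate: float = 16000.0,
    lo: float = 250.0,
    hi: float = 6000.0,
    n_carriers: int = 64,
    depth: float = 0.9,
    direction: str = "up",
    seed: int = 0,
) -> AudioWaveform:
    """Moving ripple: log-spaced carriers with sinusoidal spectrotemporal AM.

    A diagnostic stimulus whose modulation energy is concentrated at the one
    (``omega_s`` cycles/octave, ``omega_t`` Hz) cell of the modulation grid.
    """
    rng = _rng(seed, "ripple")
    t = np.arange(int(duration_s * rate)) / rate
    octaves = np.linspace(0, np.log2(hi / lo), n_carriers)
    freqs = lo * 2.0**octaves
    sgn = 1.0 if direction == "up" else -1.0
    x = np.zeros(t.size)
    for xk, fk in zip(octaves, freqs):
        am = 1.0 + depth * np.sin(
            2 * np.pi * (omega_t * t - sgn * omega_s * xk) + rng.uniform(0, 2 * np.pi) * 0
        )
        x += am * np.sin(2 * np.pi * fk * t + rng.uniform(0, 2 * np.pi))
    return AudioWaveform(x / n_carriers, rate)


# ---------------------------------------------------------------------------
# neural simulation


@dataclass
class EpochedNeural:
    """Trial-wise sensor time series (trials may differ in length).

    ``trials`` is a list of (samples x sensors) arrays; hemispheres are
    labelled 'L'/'R' per sensor (assigned by the sign of a synthetic planar
    layout coordinate: the first half of the array is left).
    """

    trials: list
    rate: float
    sensor_names: list[str]
    hemispheres: np.ndarray
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.hemispheres = np.asarray(self.hemispheres)
        ns = {t.shape[1] for t in self.trials}
        if len(ns) > 1:
            raise ValueError("all trials must share the sensor dimension")
        if self.trials and self.trials[0].shape[1] != len(self.sensor_names):
            raise ValueError("sensor names inconsistent with data")

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_names)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def zscored(self) -> "EpochedNeural":
        """Per-trial, per-sensor z-scoring (constant series are zeroed)."""
        out = []
        for tr in self.trials:
            sd = tr.std(axis=0)
            sd[sd == 0] = 1.0
            out.append((tr - tr.mean(axis=0)) / sd)
        return EpochedNeural(out, self.rate, self.sensor_names, self.hemispheres, self.t0_ms)


def default_sensor_layout(n_sensors: int) -> tuple[list[str], np.ndarray]:
    names = [f"MEG{i:03d}" for i in range(n_sensors)]
    hemis = np.array(["L" if i < n_sensors // 2 else "R" for i in range(n_sensors)])
    return names, hemis


@dataclass
class GroundTruth:
    """Generating model for the simulated sensors."""

    trf: TRFModel
    noise_sd: float
    condition_gain: dict  # (detail, prior) -> gain
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        missing = [
            (d, p)
            for d in DETAIL_LEVELS
            for p in PRIORS
            if (d, p) not in self.condition_gain
        ]
        if missing:
            raise ValueError(f"condition_gain missing cells: {missing}")


CROSSOVER_GAIN = {
    (3, "Mismatch"): 0.5,
    (6, "Mismatch"): 1.0,
    (12, "Mismatch"): 1.5,
    (3, "Match"): 1.5,
    (6, "Match"): 1.0,
    (12, "Match"): 0.5,
}

FLAT_GAIN = {(d, p): 1.0 for d in DETAIL_LEVELS for p in PRIORS}


def make_ground_truth(
    n_features: int,
    n_sensors: int,
    lag_spec: LagSpec,
    peak_ms: tuple = (87.5, 150.0),
    peak_width_ms: float = 30.0,
    noise_sd: float = 1.0,
    condition_gain: dict | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Random smooth response functions with bumps at the given latencies."""
    rng = _rng(seed, "truth")
    lags_ms = lag_spec.lag_times_ms()
    temporal = np.zeros((len(peak_ms), lag_spec.n_lags))
    for i, pk in enumerate(peak_ms):
        temporal[i] = np.exp(-0.5 * ((lags_ms - pk) / peak_width_ms) ** 2)
    w = np.zeros((lag_spec.n_lags, n_features, n_sensors))
    for i in range(len(peak_ms)):
        loading = rng.standard_normal((n_features, n_sensors))
        sign = 1.0 if i == 0 else -0.6  # biphasic response
        w += sign * temporal[i][:, None, None] * loading[None, :, :]
    trf = TRFModel(w, "encoding", 0.0, lag_spec, "truth")
    return GroundTruth(
        trf,
        noise_sd,
        dict(condition_gain) if condition_gain else dict(FLAT_GAIN),
        seed,
    )


def calibrate_noise_sd(
    features: dict,
    truth: GroundTruth,
    design: pd.DataFrame,
    snr_db: float = 0.0,
) -> float:
    """Noise SD giving the requested SNR against the noiseless responses.

    SNR is power-based over all trials and sensors, with the condition
    gains applied, so 0 dB means noise power equals signal power.
    """
    L, F, S = truth.trf.weights.shape
    Wflat = truth.trf.weights.transpose(1, 0, 2).reshape(F * L, S)
    lags = truth.trf.lag_spec.fit_lags
    total, count = 0.0, 0
    for row in design.itertuples():
        X = lag_matrix(features[row.word_id].values, lags)
        gain = truth.condition_gain[(row.detail, row.prior)]
        y = gain * (X @ Wflat)
        total += float((y**2).sum())
        count += y.size
    signal_rms = np.sqrt(total / count)
    return float(signal_rms * 10.0 ** (-snr_db / 20.0))


def synth_neural(
    features: dict,
    truth: GroundTruth,
    design: pd.DataFrame,
    n_sensors: int | None = None,
    rate: float = 80.0,
) -> EpochedNeural:
    """Forward-simulate sensor responses for every trial of ``design``.

    ``features`` maps word_id -> prepared (padded) FeatureSpace.  Each
    trial's sensor series is ``gain * lag_matrix(features) @ W + noise``
    with the gain taken from ``truth.condition_gain`` for the trial's cell.
    """
    L, F, S = truth.trf.weights.shape
    if n_sensors is None:
        n_sensors = S
    if n_sensors != S:
        raise ValueError("n_sensors inconsistent with ground-truth TRF")
    Wflat = truth.trf.weights.transpose(1, 0, 2).reshape(F * L, S)
    lags = truth.trf.lag_spec.fit_lags
    rng = _rng(truth.seed, "neural")
    trials = []
    for row in design.itertuples():
        space = features[row.word_id]
        if space.values.shape[1] != F:
            raise ValueError(
                f"trial {row.trial_id}: {space.values.shape[1]} features, truth has {F}"
            )
        X = lag_matrix(space.values, lags)
        gain = truth.condition_gain[(row.detail, row.prior)]
        y = gain * (X @ Wflat)
        if truth.noise_sd > 0:
            y = y + rng.normal(0.0, truth.noise_sd, size=y.shape)
        trials.append(y)
    names, hemis = default_sensor_layout(n_sensors)
    pre_ms = next(iter(features.values())).pad_pre_ms
    return EpochedNeural(trials, rate, names, hemis, t0_ms=-pre_ms)
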