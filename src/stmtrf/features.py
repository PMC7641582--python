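"""Stimulus feature spaces for the encoding/decoding models.

Four families of features are built from the *clear* (pre-vocoding) audio,
so any condition difference in downstream model accuracy reflects neural
encoding rather than acoustics:

1. envelope — broadband envelope (sum of 24 Greenwood-channel envelopes);
2. spectrogram — the 24 channel envelopes kept separate (optionally
   power-law compressed, exponent 0.3);
3. spectral_derivative — half-wave-rectified temporal derivative of the
   spectrogram (spectral onsets);
4. stm — spectrotemporal modulation energy: a 128-channel constant-Q
   "auditory" spectrogram filtered with a 2-D modulation filterbank at
   5 spectral scales x 5 temporal rates, magnitudes averaged over frequency
   channels and up/down sweep direction (25 features);
5. phonetic — 13 binary articulatory features from a phoneme segmentation.

All spaces are delivered at 80 Hz.  `prepare` z-scores the acoustic spaces
per trial and zero-pads each trial by the extreme model lags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from math import ceil

import numpy as np
from scipy import signal
from scipy.fft import fft2, fftfreq, ifft2, next_fast_len

from .audio import AudioWaveform
from .phonemes import PHONETIC_FEATURES, feature_vector, phoneme_feature_table
from .vocoder import ChannelBank, channel_envelopes, greenwood_bank

NEURAL_RATE = 80.0

SPECTRAL_MODS = (0.5, 1.0, 2.0, 4.0, 8.0)  # cycles/octave
TEMPORAL_MODS = (1.0, 2.0, 4.0, 8.0, 16.0)  # Hz


@dataclass(frozen=True)
class ModulationAxes:
    spectral_mods: tuple = SPECTRAL_MODS
    temporal_mods: tuple = TEMPORAL_MODS

    def labels(self) -> list[str]:
        # row-major: spectral outer, temporal inner — fixed everywhere
        return [
            f"{s:g}cpo_{t:g}Hz" for s in self.spectral_mods for t in self.temporal_mods
        ]

    def grid(self, flat_values: np.ndarray) -> np.ndarray:
        """Reshape a 25-vector (spectral-major) into the 5 x 5 grid."""
        return np.asarray(flat_values).reshape(len(self.spectral_mods), len(self.temporal_mods))


@dataclass
class Band:
    """Column block of a (possibly combined) feature space."""

    space_id: str
    start: int
    stop: int
    acoustic: bool


@dataclass
class FeatureSpace:
    values: np.ndarray  # time x feature
    rate: float
    feature_labels: list[str]
    space_id: str
    bands: list[Band] = field(default_factory=list)
    pad_pre_ms: float = 0.0
    pad_post_ms: float = 0.0
    zero_variance_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature space contains non-finite values")
        if len(self.feature_labels) != self.values.shape[1]:
            raise ValueError("one label per feature column required")
        if not self.bands:
            self.bands = [Band(self.space_id, 0, self.values.shape[1], True)]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def resample_to(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Polyphase anti-aliased resampling along axis 0 to exactly ``rate_out``."""
    frac = Fraction(rate_out / rate_in).limit_denominator(10**6)
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=0)


# ---------------------------------------------------------------------------
# envelope / spectrogram family


def spectrogram_feature(
    audio: AudioWaveform,
    compress_exponent: float | None = None,
    bank: ChannelBank | None = None,
    out_rate: float = NEURAL_RATE,
) -> FeatureSpace:
    """24 Greenwood-channel envelopes at 80 Hz, optional power-law compression."""
    if bank is None:
        bank = greenwood_bank(24)
    env = channel_envelopes(audio, bank)
    env = resample_to(env, audio.rate, out_rate)
    if compress_exponent is not None and compress_exponent != 1.0:
        env = np.power(np.maximum(env, 0.0), compress_exponent)
    labels = [f"ch{c:02d}_{bank.centers[c]:.0f}Hz" for c in range(bank.n_channels)]
    return FeatureSpace(
        env,
        out_rate,
        labels,
        "spectrogram",
        bands=[Band("spectrogram", 0, bank.n_channels, True)],
    )


def envelope_feature(
    audio: AudioWaveform, bank: ChannelBank | None = None, out_rate: float = NEURAL_RATE
) -> FeatureSpace:
    """Broadband envelope: the column-sum of the 24-channel spectrogram."""
    spec = spectrogram_feature(audio, bank=bank, out_rate=out_rate)
    values = spec.values.sum(axis=1, keepdims=True)
    return FeatureSpace(
        values, out_rate, ["envelope"], "envelope", bands=[Band("envelope", 0, 1, True)]
    )


def spectral_derivative(spectrogram: FeatureSpace) -> FeatureSpace:
    """Half-wave-rectified first temporal difference of the spectrogram."""
    if spectrogram.space_id != "spectrogram":
        raise ValueError("spectral_derivative expects a spectrogram feature space")
    d = np.diff(spectrogram.values, axis=0, prepend=spectrogram.values[:1])
    d = np.maximum(d, 0.0)
    labels = [f"d_{lab}" for lab in spectrogram.feature_labels]
    return FeatureSpace(
        d,
        spectrogram.rate,
        labels,
        "spectral_derivative",
        bands=[Band("spectral_derivative", 0, d.shape[1], True)],
    )


# ---------------------------------------------------------------------------
# auditory spectrogram and spectrotemporal modulations


def auditory_spectrogram(
    audio: AudioWaveform,
    n_channels: int = 128,
    lo: float = 180.0,
    hi: float = 7040.0,
    frame_ms: float = 8.0,
    time_constant_ms: float = 8.0,
    q: float = 24.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Constant-Q log-frequency spectrogram; one frame per ``frame_ms``.

    Returns ``(A, centers)`` with ``A`` frames x channels (magnitude) and
    ``centers`` the channel center frequencies in Hz.  Each channel is an
    analytic Gaussian band-pass (bandwidth = center/q, matching the ~1/24
    octave channel spacing) applied in the Fourier domain of the full
    waveform; channel envelopes are averaged within 8 ms frames and smoothed
    by first-order leaky integration with the given time constant.
    """
    if audio.rate < 16000:
        raise ValueError("auditory spectrogram requires audio rate >= 16 kHz")
    hop = int(round(audio.rate * frame_ms / 1000.0))
    n = audio.samples.size
    n_frames = ceil(n / hop)
    nfft = next_fast_len(n + 2 * hop)
    X = np.fft.fft(audio.samples, n=nfft)
    freqs = np.fft.fftfreq(nfft, 1.0 / audio.rate)
    centers = lo * (hi / lo) ** ((np.arange(n_channels) + 0.5) / n_channels)
    sigma = centers / q
    # analytic band-pass: positive frequencies only, doubled
    w = 2.0 * np.exp(-0.5 * ((freqs[None, :] - centers[:, None]) / sigma[:, None]) ** 2)
    w[:, freqs < 0] = 0.0
    env = np.abs(np.fft.ifft(X[None, :] * w, axis=1))[:, :n]  # channels x samples
    pad = (-n) % hop
    if pad:
        env = np.pad(env, ((0, 0), (0, pad)))
    A = env.reshape(n_channels, n_frames, hop).mean(axis=2).T  # frames x channels
    alpha = np.exp(-frame_ms / time_constant_ms)
    A = signal.lfilter([1.0 - alpha], [1.0, -alpha], A, axis=0)
    return A, centers


def _modulation_transfer(f: np.ndarray, peak: float) -> np.ndarray:
    """Band-pass magnitude response peaking at ``peak``; ~octave bandwidth."""
    r = np.abs(f) / peak
    return (r**2) * np.exp(2.0 * (1.0 - r))


def modulation_decomposition(
    A: np.ndarray,
    frame_rate: float,
    oct_per_channel: float,
    axes: ModulationAxes = ModulationAxes(),
) -> np.ndarray:
    """2-D modulation filterbank magnitudes of an auditory spectrogram.

    Returns the pre-averaging tensor of shape
    (frames, channels, n_spectral, n_temporal, 2) where the last axis holds
    the upward / downward sweep directions.  Filters are quadrant-separated
    analytic 2-D band-passes built in the 2-D Fourier domain of the
    (time x log-frequency) spectrogram.
    """
    T, C = A.shape
    Tp = next_fast_len(2 * T)
    Cp = next_fast_len(2 * C)
    F = fft2(A, s=(Tp, Cp))
    w = fftfreq(Tp, 1.0 / frame_rate)  # temporal modulation, Hz
    s = fftfreq(Cp, oct_per_channel)  # spectral modulation, cycles/octave
    sign_w = np.sign(w)[:, None]
    sign_s = np.sign(s)[None, :]
    up = (sign_w * sign_s) < 0  # rising frequency sweeps
    down = (sign_w * sign_s) > 0
    out = np.empty((T, C, len(axes.spectral_mods), len(axes.temporal_mods), 2))
    for i, sm in enumerate(axes.spectral_mods):
        Hs = _modulation_transfer(s, sm)[None, :]
        for j, tm in enumerate(axes.temporal_mods):
            Ht = _modulation_transfer(w, tm)[:, None]
            base = Ht * Hs
            for d, mask in enumerate((up, down)):
                Y = ifft2(F * (2.0 * base * mask))
                out[:, :, i, j, d] = np.abs(Y[:T, :C])
    return out


def stm_feature(
    audio: AudioWaveform,
    axes: ModulationAxes = ModulationAxes(),
    out_rate: float = NEURAL_RATE,
    return_full: bool = False,
):
    """Spectrotemporal modulation feature space: 25 magnitude time series.

    The 6400-dimensional per-frame tensor (128 channels x 5 x 5 x 2
    directions) is averaged over channels and directions, then resampled to
    80 Hz.  With ``return_full`` the pre-averaging tensor is also returned.
    """
    spec_kw = dict()
    A, centers = auditory_spectrogram(audio, **spec_kw)
    frame_rate = 125.0  # 8 ms frames
    oct_per_channel = np.log2(centers[-1] / centers[0]) / (len(centers) - 1)
    full = modulation_decomposition(A, frame_rate, oct_per_channel, axes)
    avg = full.mean(axis=(1, 4))  # over channels and directions -> (T, 5, 5)
    flat = avg.reshape(avg.shape[0], -1)  # spectral-major ordering
    flat = np.maximum(resample_to(flat, frame_rate, out_rate), 0.0)
    space = FeatureSpace(
        flat,
        out_rate,
        axes.labels(),
        "stm",
        bands=[Band("stm", 0, flat.shape[1], True)],
    )
    if return_full:
        return space, full
    return space


# ---------------------------------------------------------------------------
# phonetic features


@dataclass
class PhonemeSegmentation:
    """Ordered (phoneme, onset_ms) pairs plus the word offset in ms."""

    segments: list[tuple[str, float]]
    word_duration_ms: float

    def __post_init__(self) -> None:
        onsets = [o for _, o in self.segments]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("phoneme onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] >= self.word_duration_ms):
            raise ValueError("phoneme onsets must lie within the word")


def phonetic_feature(
    segmentation: PhonemeSegmentation, out_rate: float = NEURAL_RATE
) -> FeatureSpace:
    """13 articulatory features; piecewise constant between phoneme onsets."""
    table = phoneme_feature_table()
    n = max(1, int(round(segmentation.word_duration_ms * out_rate / 1000.0)))
    values = np.zeros((n, len(PHONETIC_FEATURES)))
    onsets = [o for _, o in segmentation.segments] + [segmentation.word_duration_ms]
    for k, (ph, _) in enumerate(segmentation.segments):
        vec = feature_vector(ph, table)
        i0 = int(round(onsets[k] * out_rate / 1000.0))
        i1 = int(round(onsets[k + 1] * out_rate / 1000.0))
        values[i0 : max(i1, i0 + 1)] = vec
    return FeatureSpace(
        values,
        out_rate,
        list(PHONETIC_FEATURES),
        "phonetic",
        bands=[Band("phonetic", 0, len(PHONETIC_FEATURES), False)],
    )


def read_segmentations(path) -> dict[str, PhonemeSegmentation]:
    """Read tab-separated (word_id, phoneme, onset_ms) rows; a row with
    phoneme '<end>' gives the word offset."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", names=["word_id", "phoneme", "onset_ms"], header=0)
    out = {}
    for wid, grp in df.groupby("word_id", sort=False):
        grp = grp.sort_values("onset_ms")
        end = grp[grp["phoneme"] == "<end>"]
        if end.empty:
            raise ValueError(f"word {wid} has no <end> row")
        dur = float(end["onset_ms"].iloc[0])
        segs = [
            (str(r.phoneme), float(r.onset_ms))
            for r in grp.itertuples()
            if r.phoneme != "<end>"
        ]
        out[str(wid)] = PhonemeSegmentation(segs, dur)
    return out


# ---------------------------------------------------------------------------
# combination and preparation


def combine(*spaces: FeatureSpace) -> FeatureSpace:
    """Column-concatenate feature spaces, recording band boundaries."""
    if len(spaces) == 1:
        return spaces[0]
    if len({s.rate for s in spaces}) != 1:
        raise ValueError("feature spaces must share a sampling rate")
    if len({s.n_samples for s in spaces}) != 1:
        raise ValueError("feature spaces must share a time axis")
    values = np.hstack([s.values for s in spaces])
    labels, bands, ofs = [], [], 0
    for s in spaces:
        labels.extend(f"{s.space_id}:{lab}" for lab in s.feature_labels)
        for b in s.bands:
            bands.append(Band(b.space_id, b.start + ofs, b.stop + ofs, b.acoustic))
        ofs += s.n_features
    space_id = "combined(" + "+".join(s.space_id for s in spaces) + ")"
    return FeatureSpace(values, spaces[0].rate, labels, space_id, bands=bands)


def prepare(
    space: FeatureSpace,
    lag_min_ms: float = -100.0,
    lag_max_ms: float = 300.0,
    zscore: bool | str = "auto",
) -> FeatureSpace:
    """Per-trial preparation for model fitting.

    Acoustic columns are z-scored (mean 0, SD 1 per time series per trial);
    phonetic columns are left as 0/1 indicators.  Zeros equal to the extreme
    lags are prepended/appended so that word onsets and offsets can inform
    negative and positive lags respectively.
    """
    v = space.values.copy()
    flagged = []
    if zscore is True:
        cols = range(v.shape[1])
    elif zscore is False:
        cols = []
    else:
        cols = [
            c for b in space.bands if b.acoustic for c in range(b.start, b.stop)
        ]
    for c in cols:
        sd = v[:, c].std()
        if sd == 0:
            v[:, c] = 0.0
            flagged.append(c)
        else:
            v[:, c] = (v[:, c] - v[:, c].mean()) / sd
    pre = int(round(abs(min(lag_min_ms, 0.0)) * space.rate / 1000.0))
    post = int(round(max(lag_max_ms, 0.0) * space.rate / 1000.0))
    padded = np.vstack(
        [np.zeros((pre, v.shape[1])), v, np.zeros((post, v.shape[1]))]
    )
    return replace(
        space,
        values=padded,
        pad_pre_ms=pre * 1000.0 / space.rate,
        pad_post_ms=post * 1000.0 / space.rate,
        zero_variance_columns=flagged,
    )
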