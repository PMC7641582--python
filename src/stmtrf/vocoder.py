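"""Noise-vocoding of speech.

A noise vocoder divides the signal into spectral channels, extracts each
channel's temporal envelope, and re-imposes those envelopes onto band-limited
white-noise carriers.  Summing the modulated carriers yields speech-shaped
noise whose spectral detail is controlled by the number of channels: temporal
structure is preserved, narrowband spectral structure is progressively
destroyed as the channel count falls.

Channel boundaries are equally spaced on the cochlear-position axis given by
Greenwood's frequency-position function

    F(x) = A (10**(a x) - k),   x in [0, 1]

with the standard human parameters A = 165.4, a = 2.1, k = 0.88.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .audio import AudioWaveform

GREENWOOD_A = 165.4
GREENWOOD_ALPHA = 2.1
GREENWOOD_K = 0.88


def greenwood_position(freq_hz, A=GREENWOOD_A, a=GREENWOOD_ALPHA, k=GREENWOOD_K):
    """Cochlear position (fraction of basilar-membrane length) of a frequency."""
    return np.log10(np.asarray(freq_hz, dtype=float) / A + k) / a


def greenwood_frequency(x, A=GREENWOOD_A, a=GREENWOOD_ALPHA, k=GREENWOOD_K):
    """Inverse of :func:`greenwood_position`."""
    return A * (10.0 ** (a * np.asarray(x, dtype=float)) - k)


@dataclass
class ChannelBank:
    """Contiguous band-pass channels covering [lo, hi] Hz."""

    edges: np.ndarray
    centers: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("channel edges must be strictly increasing")
        if self.centers.size != self.edges.size - 1:
            raise ValueError("need exactly one center per channel")
        if np.any(self.centers <= self.edges[:-1]) or np.any(self.centers >= self.edges[1:]):
            raise ValueError("centers must lie inside their channels")

    @property
    def n_channels(self) -> int:
        return self.centers.size

    @property
    def lo(self) -> float:
        return float(self.edges[0])

    @property
    def hi(self) -> float:
        return float(self.edges[-1])


def greenwood_bank(
    n_channels: int,
    lo: float = 70.0,
    hi: float = 5000.0,
    centers_override: np.ndarray | None = None,
) -> ChannelBank:
    """Channel bank with edges equally spaced on the Greenwood position axis.

    Channel centers default to the frequency at the midpoint position of each
    channel; ``centers_override`` substitutes an explicit list (the original
    study prints center frequencies whose exact convention is unknown and
    which differ from the midpoint convention by a few percent).
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if lo >= hi:
        raise ValueError("lo must be < hi")
    pos = np.linspace(greenwood_position(lo), greenwood_position(hi), n_channels + 1)
    edges = greenwood_frequency(pos)
    # pin the end points exactly; the round trip is accurate to ~1e-12 anyway
    edges[0], edges[-1] = lo, hi
    if centers_override is not None:
        centers = np.asarray(centers_override, dtype=float)
    else:
        centers = greenwood_frequency((pos[:-1] + pos[1:]) / 2.0)
    return ChannelBank(edges=edges, centers=centers)


def _bandpass_sos(lo: float, hi: float, rate: float, order: int = 4):
    nyq = rate / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz reaches Nyquist ({nyq} Hz)")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")


def bandpass(x: np.ndarray, lo: float, hi: float, rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (applied forward-backward)."""
    return signal.sosfiltfilt(_bandpass_sos(lo, hi, rate, order), x)


def extract_envelope(band_signal: np.ndarray, rate: float, cutoff: float = 30.0) -> np.ndarray:
    """Half-wave rectification followed by a 2nd-order low-pass at ``cutoff``.

    The smoothing filter is applied forward-backward so the envelope carries
    no group delay; mild negative undershoot from filtering is left in place.
    """
    x = np.asarray(band_signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("band signal contains non-finite values")
    if cutoff >= rate / 2.0:
        raise ValueError("envelope cutoff must be below Nyquist")
    rectified = np.maximum(x, 0.0)
    sos = signal.butter(2, cutoff, btype="lowpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, rectified)


def channel_envelopes(
    audio: AudioWaveform, bank: ChannelBank, cutoff: float = 30.0
) -> np.ndarray:
    """Per-channel envelopes at the audio rate; shape (n_samples, n_channels)."""
    out = np.empty((audio.samples.size, bank.n_channels))
    for c in range(bank.n_channels):
        band = bandpass(audio.samples, bank.edges[c], bank.edges[c + 1], audio.rate)
        out[:, c] = extract_envelope(band, audio.rate, cutoff)
    return out


def vocode(
    audio: AudioWaveform,
    n_channels: int,
    seed: int = 0,
    bank: ChannelBank | None = None,
    reference_rms: float | None = None,
    envelope_cutoff: float = 30.0,
) -> AudioWaveform:
    """Noise-vocode ``audio`` with ``n_channels`` Greenwood-spaced channels.

    Per channel: band-pass analysis -> envelope -> multiply band-passed white
    noise by the envelope -> band-pass again -> sum across channels.  The
    output RMS is set to ``reference_rms`` (default: the input RMS).
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if bank is None:
        bank = greenwood_bank(n_channels)
    if audio.rate < 2.0 * bank.hi:
        raise ValueError("audio rate too low for the requested channel bank")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(audio.samples)
    for c in range(bank.n_channels):
        lo, hi = bank.edges[c], bank.edges[c + 1]
        band = bandpass(audio.samples, lo, hi, audio.rate)
        env = extract_envelope(band, audio.rate, envelope_cutoff)
        carrier = bandpass(rng.standard_normal(audio.samples.size), lo, hi, audio.rate)
        out += bandpass(carrier * env, lo, hi, audio.rate)
    target = audio.rms if reference_rms is None else reference_rms
    voc = AudioWaveform(out, audio.rate)
    return voc.scaled_to_rms(target)


def rms_equalize(audios: list[AudioWaveform], target_rms: float = 0.05) -> list[AudioWaveform]:
    """Rescale every waveform to a common RMS level."""
    for a in audios:
        if a.rms == 0:
            raise ValueError("cannot RMS-equalize a silent waveform")
    return [a.scaled_to_rms(target_rms) for a in audios]
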