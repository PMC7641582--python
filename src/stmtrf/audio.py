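"""Audio container and 16-bit PCM WAV input/output."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile


@dataclass
class AudioWaveform:
    """A mono waveform in arbitrary units.

    Attributes
    ----------
    samples : 1-D float array
    rate : sampling rate in Hz
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def scaled_to_rms(self, target_rms: float) -> "AudioWaveform":
        r = self.rms
        if r == 0:
            raise ValueError("cannot rescale a silent waveform")
        return AudioWaveform(self.samples * (target_rms / r), self.rate)


def write_wav(path: str | Path, audio: AudioWaveform) -> None:
    """Write as 16-bit PCM, scaling peak amplitude to 90% full scale."""
    peak = np.max(np.abs(audio.samples))
    scale = 0.9 * 32767 / peak if peak > 0 else 1.0
    data = np.round(audio.samples * scale).astype(np.int16)
    wavfile.write(str(path), int(audio.rate), data)


def read_wav(path: str | Path) -> AudioWaveform:
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:  # mixdown; the pipeline is mono throughout
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return AudioWaveform(np.asarray(data, dtype=float), float(rate))
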