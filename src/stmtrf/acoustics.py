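"""Stimulus-side modulation analysis: what vocoding does to the words.

For every word the spectrotemporal modulation (STM) decomposition yields a
5 x 5 grid of cell magnitudes (time-mean of the non-z-scored filterbank
magnitude).  Comparing grids across vocoder channel counts characterizes
which modulations carry the spectral detail the vocoder removes, and
between-word Euclidean distances per cell show which modulations
discriminate words.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .audio import AudioWaveform
from .features import ModulationAxes, stm_feature
from .stats import fdr_bh
from .vocoder import vocode


@dataclass
class ModulationGrid:
    """5 x 5 grid over (spectral mods x temporal mods)."""

    values: np.ndarray
    statistic: str  # magnitude | distance | t | effect
    axes: ModulationAxes = ModulationAxes()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.axes.spectral_mods), len(self.axes.temporal_mods))
        if self.values.shape != expected:
            raise ValueError(f"grid must be {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid contains non-finite values")

    def argmax_cell(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.values), self.values.shape)
        return self.axes.spectral_mods[i], self.axes.temporal_mods[j]


def _word_stm(audio: AudioWaveform, n_channels: int | None, seed: int) -> np.ndarray:
    if n_channels is not None:
        audio = vocode(audio, n_channels, seed=seed)
    return stm_feature(audio).values  # time x 25, non-z-scored magnitudes


def modulation_magnitude(
    words: dict[str, AudioWaveform], n_channels: int | None = None, seed: int = 0
) -> dict[str, ModulationGrid]:
    """Per-word time-mean STM magnitude grid (``n_channels=None`` = clear)."""
    axes = ModulationAxes()
    out = {}
    for wid, audio in words.items():
        values = _word_stm(audio, n_channels, seed)
        out[wid] = ModulationGrid(axes.grid(values.mean(axis=0)), "magnitude")
    return out


def between_word_distance(
    words: dict[str, AudioWaveform], n_channels: int | None = None, seed: int = 0
) -> ModulationGrid:
    """Mean pairwise Euclidean distance between cell time series.

    Words are zero-padded to the longest duration before the distances are
    taken; the mean runs over all N(N-1)/2 word pairs.
    """
    if len(words) < 2:
        raise ValueError("need at least 2 words for between-word distances")
    series = [_word_stm(a, n_channels, seed) for a in words.values()]
    T = max(s.shape[0] for s in series)
    padded = np.stack(
        [np.vstack([s, np.zeros((T - s.shape[0], s.shape[1]))]) for s in series]
    )
    dists = np.zeros(padded.shape[2])
    pairs = list(combinations(range(len(series)), 2))
    for i, j in pairs:
        dists += np.sqrt(((padded[i] - padded[j]) ** 2).sum(axis=0))
    axes = ModulationAxes()
    return ModulationGrid(axes.grid(dists / len(pairs)), "distance")


def channel_contrast(
    grids_a: list[ModulationGrid], grids_b: list[ModulationGrid], q: float = 0.05
):
    """Per-cell paired t over words for two vocoding conditions (a - b).

    Returns (t grid, p grid, BH-FDR rejection mask at ``q`` across the 25
    cells).
    """
    from .stats import paired_t

    if len(grids_a) != len(grids_b):
        raise ValueError("need the same word set in both conditions")
    A = np.stack([g.values for g in grids_a])  # words x 5 x 5
    B = np.stack([g.values for g in grids_b])
    tgrid = np.zeros(A.shape[1:])
    pgrid = np.ones(A.shape[1:])
    for i in range(A.shape[1]):
        for j in range(A.shape[2]):
            res = paired_t(A[:, i, j], B[:, i, j])
            tgrid[i, j], pgrid[i, j] = res["t"], res["p"]
    mask, _ = fdr_bh(pgrid, q=q)
    return ModulationGrid(tgrid, "t"), pgrid, mask
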