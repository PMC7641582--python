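"""Phoneme -> articulatory-feature mapping.

The inventory is ARPABET-like and maps each phoneme to 13 binary features
(voicing, place, manner, vowel backness).  Postalveolar consonants are folded
into Alveolar, glides into Liquid, and labiodental/dental are merged into a
single place feature.  Diphthongs and affricates are listed as composites
(e.g. ``CH = T+SH``) and carry the mean of their component feature vectors.

The table ships as an editable CSV (``data/phoneme_features.csv``).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

PHONETIC_FEATURES = (
    "Voiced",
    "Unvoiced",
    "Bilabial",
    "Labiodental/Dental",
    "Alveolar",
    "Velar",
    "Plosive",
    "Nasal",
    "Fricative",
    "Liquid",
    "Front",
    "Central",
    "Back",
)


class UnknownPhonemeError(KeyError):
    pass


@lru_cache(maxsize=None)
def phoneme_feature_table(path: str | None = None) -> pd.DataFrame:
    """Phoneme-by-feature table with composites resolved to mean vectors."""
    if path is None:
        src = resources.files("stmtrf.data").joinpath("phoneme_features.csv")
        with resources.as_file(src) as p:
            raw = pd.read_csv(p, dtype={"phoneme": str, "components": str})
    else:
        raw = pd.read_csv(path, dtype={"phoneme": str, "components": str})
    raw = raw.set_index("phoneme")
    base = raw[raw["components"].isna()][list(PHONETIC_FEATURES)].astype(float)
    rows = {ph: base.loc[ph].to_numpy() for ph in base.index}
    for ph, comp in raw["components"].dropna().items():
        parts = [c.strip() for c in comp.split("+")]
        missing = [c for c in parts if c not in rows]
        if missing:
            raise ValueError(f"composite {ph} refers to unknown phonemes {missing}")
        rows[ph] = np.mean([rows[c] for c in parts], axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(PHONETIC_FEATURES))


def feature_vector(phoneme: str, table: pd.DataFrame | None = None) -> np.ndarray:
    table = phoneme_feature_table() if table is None else table
    if phoneme not in table.index:
        raise UnknownPhonemeError(f"phoneme {phoneme!r} not in the shipped inventory")
    return table.loc[phoneme].to_numpy()
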