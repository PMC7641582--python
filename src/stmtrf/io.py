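"""Formats, configuration, and the end-to-end pipeline driver.

The epoch container is an HDF5 layout defined here (no community standard
fits trial-wise audio/feature/neural bundles): ``/data`` holds trials x
sensors x samples zero-padded to the longest trial with ``/lengths`` giving
true lengths, ``/sensors`` and ``/hemisphere`` label the sensor axis, and
feature spaces / fitted models live under ``/features`` and ``/models``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import Band, FeatureSpace, prepare, stm_feature
from .simulate import (
    CROSSOVER_GAIN,
    EpochedNeural,
    make_design,
    make_ground_truth,
    synth_neural,
    synth_word_audio,
)
from .trf import LagSpec, RidgeConfig, loto_cv, select_lambda
from .vocoder import rms_equalize

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# design / table round trips

DESIGN_COLUMNS = ["trial_id", "word_id", "written_word_id", "detail", "prior", "block"]


def write_design(path, design: pd.DataFrame) -> None:
    design[DESIGN_COLUMNS].to_csv(path, index=False)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"design file missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# epoch container


def save_epochs(path, epochs: EpochedNeural, mode: str = "w") -> None:
    lengths = np.array([t.shape[0] for t in epochs.trials])
    data = np.zeros((epochs.n_trials, epochs.n_sensors, lengths.max()))
    for i, t in enumerate(epochs.trials):
        data[i, :, : t.shape[0]] = t.T
    with h5py.File(path, mode) as f:
        f.create_dataset("data", data=data)
        f.create_dataset("lengths", data=lengths)
        f.create_dataset("sensors", data=np.array(epochs.sensor_names, dtype="S"))
        f.create_dataset("hemisphere", data=np.array(epochs.hemispheres, dtype="S"))
        f.attrs["rate"] = epochs.rate
        f.attrs["t0_ms"] = epochs.t0_ms


def load_epochs(path) -> EpochedNeural:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        lengths = f["lengths"][()]
        names = [s.decode() for s in f["sensors"][()]]
        hemis = np.array([s.decode() for s in f["hemisphere"][()]])
        rate = float(f.attrs["rate"])
        t0 = float(f.attrs["t0_ms"])
    trials = [data[i, :, : lengths[i]].T for i in range(data.shape[0])]
    return EpochedNeural(trials, rate, names, hemis, t0)


def save_features(path, spaces: dict[str, FeatureSpace], mode: str = "a") -> None:
    """Store per-trial feature spaces under /features/<space_id>/<word_id>."""
    with h5py.File(path, mode) as f:
        for wid, sp in spaces.items():
            g = f.require_group(f"features/{sp.space_id}")
            if wid in g:
                del g[wid]
            d = g.create_dataset(wid, data=sp.values)
            d.attrs["rate"] = sp.rate
            d.attrs["labels"] = np.array(sp.feature_labels, dtype="S")
            d.attrs["pad_pre_ms"] = sp.pad_pre_ms
            d.attrs["pad_post_ms"] = sp.pad_post_ms
            d.attrs["bands"] = json.dumps(
                [[b.space_id, b.start, b.stop, b.acoustic] for b in sp.bands]
            )


def load_features(path, space_id: str) -> dict[str, FeatureSpace]:
    out = {}
    with h5py.File(path, "r") as f:
        g = f[f"features/{space_id}"]
        for wid in g:
            d = g[wid]
            bands = [
                Band(bid, int(s), int(e), bool(a))
                for bid, s, e, a in json.loads(d.attrs["bands"])
            ]
            out[wid] = FeatureSpace(
                d[()],
                float(d.attrs["rate"]),
                [s.decode() for s in d.attrs["labels"]],
                space_id,
                bands=bands,
                pad_pre_ms=float(d.attrs["pad_pre_ms"]),
                pad_post_ms=float(d.attrs["pad_post_ms"]),
            )
    return out


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end synthetic pipeline."""

    n_per_cell: int = 6
    n_blocks: int = 3
    n_participants: int = 6
    n_sensors: int = 20
    top_k_sensors: int = 5
    audio_rate: float = 16000.0
    neural_rate: float = 80.0
    feature_space: str = "stm"
    snr_db: float = 0.0
    lambda_exponent_max: float = 20.0
    n_lambdas: int = 17
    n_perm: int = 20
    schematic_reps: int = 200
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.n_per_cell < 1 or self.n_participants < 1 or self.n_sensors < 2:
            raise ValueError("invalid pipeline sizes")
        if self.feature_space not in ("stm", "envelope", "spectrogram"):
            raise ValueError(f"unsupported feature space {self.feature_space!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def ridge_config(self) -> RidgeConfig:
        grid = tuple(2.0 ** np.linspace(0.0, self.lambda_exponent_max, self.n_lambdas))
        return RidgeConfig(lambda_grid=grid)

    def lag_spec(self) -> LagSpec:
        return LagSpec(rate=self.neural_rate)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# pipeline


def build_word_features(
    design: pd.DataFrame,
    config: PipelineConfig,
    lag_spec: LagSpec,
) -> tuple[dict, dict]:
    """Synthesize (RMS-equalized) clear audio and prepared features per word."""
    from .features import envelope_feature, spectrogram_feature

    words = {}
    for wid in design["word_id"]:
        words[wid] = synth_word_audio(wid, rate=config.audio_rate, seed=config.seed)
    eq = rms_equalize(list(words.values()))
    words = dict(zip(words.keys(), eq))
    builder = {
        "stm": stm_feature,
        "envelope": envelope_feature,
        "spectrogram": spectrogram_feature,
    }[config.feature_space]
    feats = {
        wid: prepare(builder(a), lag_spec.fit_min_ms, lag_spec.fit_max_ms)
        for wid, a in words.items()
    }
    return words, feats


def condition_accuracies(
    feats: dict,
    design: pd.DataFrame,
    truth,
    config: PipelineConfig,
    lam: float | None = None,
    participant: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition leave-one-trial-out encoding accuracies for one simulated
    participant.  Returns (per-sensor table, per-lambda aggregate table)."""
    import dataclasses as _dc

    lag_spec = config.lag_spec()
    ridge = config.ridge_config()
    if lam is not None:
        ridge = RidgeConfig(lambda_grid=(lam,))
    truth_p = _dc.replace(truth, seed=truth.seed + 1000 * (participant + 1))
    neural = synth_neural(feats, truth_p, design, config.n_sensors, config.neural_rate).zscored()
    rows, agg = [], []
    for (detail, prior), grp in design.groupby(["detail", "prior"]):
        idx = grp.index.to_numpy()
        X = [feats[design.loc[i, "word_id"]].values for i in idx]
        Y = [neural.trials[i] for i in idx]
        cv = loto_cv(X, Y, lag_spec, ridge, "encoding")
        acc = cv.accuracy.groupby(["lambda", "output"])["r"].mean().reset_index()
        acc["detail"], acc["prior"], acc["participant"] = detail, prior, participant
        rows.append(acc)
        m = cv.mean_accuracy().reset_index().rename(columns={"r": "accuracy"})
        m["condition"] = f"{detail}-{prior}"
        m["participant"] = participant
        agg.append(m)
    return pd.concat(rows, ignore_index=True), pd.concat(agg, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> features -> fit -> stats -> schematic end to end.

    Writes result tables and a provenance manifest under ``config.out_dir``
    and returns them as a dict of DataFrames.  Stage failures raise
    `StageError`; tables written before the failure are left in place.
    """
    from .schematic import run_grid, summarize_grid
    from .simulate import calibrate_noise_sd
    from .stats import rm_anova_2x3, select_top_sensors

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    t_start = time.time()
    log.info("pipeline start: seed=%d hash=%s", config.seed, config.hash())

    current = {"stage": "init"}

    def stage(name):
        current["stage"] = name
        log.info("stage %-12s t=%.1fs", name, time.time() - t_start)

    try:
        stage("simulate")
        design = make_design(config.n_per_cell, config.n_blocks, config.seed)
        write_design(out / "design.csv", design)
        results["design"] = design

        stage("features")
        lag_spec = config.lag_spec()
        _, feats = build_word_features(design, config, lag_spec)
        n_features = next(iter(feats.values())).n_features

        stage("fit")
        truth = make_ground_truth(
            n_features,
            config.n_sensors,
            lag_spec,
            condition_gain=CROSSOVER_GAIN,
            seed=config.seed,
        )
        truth.noise_sd = calibrate_noise_sd(feats, truth, design, config.snr_db)
        per_sensor, per_lambda = [], []
        for p in range(config.n_participants):
            s, a = condition_accuracies(feats, design, truth, config, participant=p)
            per_sensor.append(s)
            per_lambda.append(a)
        per_sensor = pd.concat(per_sensor, ignore_index=True)
        per_lambda = pd.concat(per_lambda, ignore_index=True)
        lam = select_lambda(per_lambda)
        results["lambda"] = lam
        log.info("selected lambda = %g", lam)

        stage("stats")
        sel = per_sensor[per_sensor["lambda"] == lam]
        cell_rows = []
        hemis = np.array(["L" if i < config.n_sensors // 2 else "R" for i in range(config.n_sensors)])
        for p, grp in sel.groupby("participant"):
            mean_per_sensor = grp.groupby("output")["r"].mean().to_numpy()
            chosen = select_top_sensors(mean_per_sensor, hemis, k=config.top_k_sensors)
            chosen_idx = np.concatenate(list(chosen.values()))
            for (detail, prior), g in grp.groupby(["detail", "prior"]):
                acc = g[g["output"].isin(chosen_idx)]["r"].mean()
                cell_rows.append(
                    {"participant": p, "detail": detail, "prior": prior, "accuracy": acc}
                )
        cells = pd.DataFrame(cell_rows)
        cells.to_csv(out / "condition_accuracy.csv", index=False)
        effects = rm_anova_2x3(cells)
        effects.to_csv(out / "condition_effects.csv", index=False)
        results["cells"], results["effects"] = cells, effects

        stage("schematic")
        table = run_grid(n_reps=config.schematic_reps, seed=config.seed)
        summary = summarize_grid(table)
        summary.to_csv(out / "schematic_summary.csv", index=False)
        results["schematic"] = summary

        stage("manifest")
        manifest = {
            "package_version": __version__,
            "config": config.to_dict(),
            "config_hash": config.hash(),
            "seed": config.seed,
            "selected_lambda": float(lam),
            "runtime_s": round(time.time() - t_start, 2),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        results["manifest"] = manifest
    except Exception as exc:  # label the failing stage, keep partial results
        raise StageError(current["stage"], exc) from exc
    log.info("pipeline done in %.1fs", time.time() - t_start)
    return results
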