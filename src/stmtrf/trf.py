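"""Lagged linear encoding/decoding with ridge and banded-ridge regularization.

The encoding model is ``y = S w + e``: the neural time series at each sensor
is a linear function of the stimulus features concatenated over time lags.
The decoding model ``s = Y w + e`` runs the other way, from lagged neural
data (reduced to principal components) back to stimulus features.  Models
are fitted per trial, the per-trial weights averaged over the training set
(leave-one-trial-out), and accuracy is the Pearson correlation between the
predicted and observed held-out trial.

Conventions
-----------
* Lags are in ms and must be integer multiples of the sample period.
  Positive lag = neural response *after* the stimulus, in both directions.
* Lag-matrix column ordering is feature-major, lag-minor:
  column ``f * n_lags + i`` holds feature ``f`` at the ``i``-th lag.
* Fitting uses the wide lag range (default -100..300 ms); prediction uses
  only the weight blocks inside the narrower predict range (default
  0..250 ms) to avoid edge artefacts.
* An unpenalized intercept is handled by centering predictors and targets
  within each trial before solving; `fit_ridge` itself is the bare
  penalized solver so that it matches the normal-equations form exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

log = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = tuple(2.0 ** np.linspace(0.0, 20.0, 17))


@dataclass(frozen=True)
class LagSpec:
    """Fit and prediction lag ranges in ms at a given sampling rate."""

    fit_min_ms: float = -100.0
    fit_max_ms: float = 300.0
    predict_min_ms: float = 0.0
    predict_max_ms: float = 250.0
    rate: float = 80.0

    def __post_init__(self) -> None:
        if not (
            self.fit_min_ms <= self.predict_min_ms
            and self.predict_max_ms <= self.fit_max_ms
        ):
            raise ValueError("fit lag range must contain the predict range")
        for ms in (self.fit_min_ms, self.fit_max_ms, self.predict_min_ms, self.predict_max_ms):
            self._to_samples(ms)

    def _to_samples(self, ms: float) -> int:
        x = ms * self.rate / 1000.0
        if abs(x - round(x)) > 1e-9:
            raise ValueError(f"lag {ms} ms is not a multiple of the sample period")
        return int(round(x))

    @property
    def fit_lags(self) -> np.ndarray:
        """Integer sample shifts of the fitted lags."""
        return np.arange(self._to_samples(self.fit_min_ms), self._to_samples(self.fit_max_ms) + 1)

    @property
    def predict_mask(self) -> np.ndarray:
        """Boolean mask over fit lags selecting the prediction range."""
        lo = self._to_samples(self.predict_min_ms)
        hi = self._to_samples(self.predict_max_ms)
        return (self.fit_lags >= lo) & (self.fit_lags <= hi)

    @property
    def n_lags(self) -> int:
        return self.fit_lags.size

    def lag_times_ms(self) -> np.ndarray:
        return self.fit_lags * 1000.0 / self.rate


@dataclass
class RidgeConfig:
    """Regularization grid; 17 log2-equispaced values from 2^0 to 2^20."""

    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    banded: bool = False
    per_band_grids: tuple | None = None

    def __post_init__(self) -> None:
        lg = np.asarray(self.lambda_grid, dtype=float)
        if np.any(lg <= 0) or np.any(np.diff(lg) <= 0):
            raise ValueError("lambda grid must be positive and ascending")

    def band_grid(self, n_bands: int) -> list[tuple]:
        """Cartesian per-band lambda combinations (17 x 17 = 289 for two bands)."""
        grids = (
            self.per_band_grids
            if self.per_band_grids is not None
            else tuple([self.lambda_grid] * n_bands)
        )
        combos = [()]
        for g in grids:
            combos = [c + (lam,) for c in combos for lam in g]
        return combos


@dataclass
class TRFModel:
    """Fitted lagged linear model.

    ``weights`` has shape (n_lags, n_features, n_outputs); for an encoding
    model outputs are sensors, for decoding they are stimulus features.
    """

    weights: np.ndarray
    direction: str  # "encoding" | "decoding"
    lambda_used: float | tuple
    lag_spec: LagSpec
    space_id: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("TRF weights must be finite")
        if self.weights.shape[0] != self.lag_spec.n_lags:
            raise ValueError("weight lag axis inconsistent with lag spec")

    def lag_rms(self) -> np.ndarray:
        """RMS of the weights over features and outputs, per lag."""
        return np.sqrt(np.mean(self.weights**2, axis=(1, 2)))

    def peak_latency_ms(self) -> float:
        return float(self.lag_spec.lag_times_ms()[np.argmax(self.lag_rms())])


def lag_matrix(x: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Concatenate time-shifted copies of ``x`` (time x feature).

    Column ``f * n_lags + i`` holds ``x[t - lags[i], f]``; out-of-range
    samples are zero.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1:
        x = x.T
    T, F = x.shape
    lags = np.asarray(lags, dtype=int)
    L = lags.size
    out = np.zeros((T, F * L))
    for i, l in enumerate(lags):
        if l >= 0:
            out[l:, i::L] = x[: T - l] if l > 0 else x
        else:
            out[:l, i::L] = x[-l:]
    return out


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge solution ``argmin ||y - Xw||^2 + lam ||w||^2``.

    Uses the primal normal equations when samples >= features and the dual
    (kernel) form otherwise; the two agree exactly for lam > 0.  ``lam = 0``
    falls back to the minimum-norm least-squares solution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have the same number of rows")
    if lam == 0:
        return np.linalg.lstsq(X, y, rcond=None)[0]
    n, p = X.shape
    if n >= p:
        A = X.T @ X + lam * np.eye(p)
        return _solve_spd(A, X.T @ y)
    A = X @ X.T + lam * np.eye(n)
    return X.T @ _solve_spd(A, y)


def _solve_spd(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve a (near-)SPD system, falling back to least squares when the
    regularization is too small to keep the Cholesky factorization stable."""
    try:
        return linalg.solve(A, b, assume_a="pos")
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def fit_banded(
    X: np.ndarray, y: np.ndarray, band_slices: list[slice], lambdas: tuple
) -> np.ndarray:
    """Ridge with a separate penalty per column band.

    Solved by rescaling each band by ``1/sqrt(lambda_b)`` and fitting plain
    ridge with unit penalty, so equal lambdas reduce exactly to `fit_ridge`.
    """
    X = np.asarray(X, dtype=float)
    if len(band_slices) != len(lambdas):
        raise ValueError("one lambda per band required")
    cover = np.zeros(X.shape[1], dtype=int)
    for s in band_slices:
        cover[s] += 1
    if not np.all(cover == 1):
        raise ValueError("bands must partition the columns exactly")
    scale = np.empty(X.shape[1])
    for s, lam in zip(band_slices, lambdas):
        if lam <= 0:
            raise ValueError("banded ridge requires positive lambdas")
        scale[s] = 1.0 / np.sqrt(lam)
    w = fit_ridge(X * scale, y, 1.0)
    return w * scale[:, None] if w.ndim == 2 else w * scale


# ---------------------------------------------------------------------------
# leave-one-trial-out cross-validation


class _TrialSolver:
    """Cached eigendecomposition for multi-lambda single-trial ridge fits."""

    def __init__(self, X: np.ndarray, Y: np.ndarray):
        self.xm = X.mean(axis=0)
        self.ym = Y.mean(axis=0)
        Xc = X - self.xm
        Yc = Y - self.ym
        n, p = Xc.shape
        self.dual = n < p
        if self.dual:
            e, U = np.linalg.eigh(Xc @ Xc.T)
            self.G = Xc.T @ U  # p x n
            self.b = U.T @ Yc  # n x outputs
        else:
            e, V = np.linalg.eigh(Xc.T @ Xc)
            self.G = V  # p x p
            self.b = V.T @ (Xc.T @ Yc)
        self.e = np.maximum(e, 0.0)

    def solve(self, lam: float) -> np.ndarray:
        return self.G @ (self.b / (self.e + lam)[:, None])


@dataclass
class CVResult:
    """Leave-one-trial-out accuracies and averaged weights per lambda."""

    accuracy: pd.DataFrame  # columns: trial, output, lambda, r
    weights: dict  # lambda -> (p, n_outputs) averaged weights
    trial_weights: dict  # lambda -> (n_trials, p, n_outputs)
    lag_spec: LagSpec
    n_features: int
    direction: str
    space_id: str = ""

    def mean_accuracy(self) -> pd.Series:
        """Mean r per lambda: averaged over trials first, then outputs."""
        per_output = self.accuracy.groupby(["lambda", "output"])["r"].mean()
        return per_output.groupby("lambda").mean()

    def model(self, lam: float) -> TRFModel:
        w = self.weights[lam]
        L = self.lag_spec.n_lags
        weights = w.reshape(self.n_features, L, -1).transpose(1, 0, 2)
        return TRFModel(weights, self.direction, lam, self.lag_spec, self.space_id)


def _pearson_rows(pred: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r; zero-variance columns give r = 0."""
    pc = pred - pred.mean(axis=0)
    oc = obs - obs.mean(axis=0)
    num = (pc * oc).sum(axis=0)
    den = np.sqrt((pc**2).sum(axis=0) * (oc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(np.isfinite(r), r, 0.0)


def loto_cv(
    X_trials: list[np.ndarray],
    Y_trials: list[np.ndarray],
    lag_spec: LagSpec,
    ridge_config: RidgeConfig | None = None,
    direction: str = "encoding",
    space_id: str = "",
    keep_trial_weights: bool = False,
    band_slices: list[slice] | None = None,
) -> CVResult:
    """Leave-one-trial-out lagged ridge.

    For every trial a model is fitted on that trial alone; predictions for a
    held-out trial use the average of the other trials' weights, restricted
    to the predict lag range.  ``X_trials`` are prepared (padded) predictor
    matrices, ``Y_trials`` the targets; both per trial, time x columns.

    For decoding pass the neural data as X and the stimulus features as Y:
    positive lags then mean the neural sample *follows* the decoded stimulus
    sample (shifts are negated internally).
    """
    if ridge_config is None:
        ridge_config = RidgeConfig()
    if direction not in ("encoding", "decoding"):
        raise ValueError("direction must be 'encoding' or 'decoding'")
    if len(X_trials) != len(Y_trials):
        raise ValueError("one target per predictor trial required")
    if len(X_trials) < 3:
        raise ValueError("leave-one-trial-out needs at least 3 trials")
    lags = lag_spec.fit_lags
    shifts = lags if direction == "encoding" else -lags
    L = lags.size
    n_feat = np.atleast_2d(X_trials[0]).shape[1]
    min_len = L  # a trial must at least span the lag window
    solvers, keep = [], []
    for t, (X, Y) in enumerate(zip(X_trials, Y_trials)):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if X.shape[0] != Y.shape[0]:
            raise ValueError(f"trial {t}: predictor/target length mismatch")
        if X.shape[0] < min_len:
            warnings.warn(f"trial {t} shorter than the lag window; excluded")
            continue
        keep.append(t)
        solvers.append((_TrialSolver(lag_matrix(X, shifts), Y), X, Y))
    if len(solvers) < 3:
        raise ValueError("fewer than 3 usable trials")
    n_trials = len(solvers)
    pmask = np.repeat(lag_spec.predict_mask[None, :], n_feat, axis=0).ravel()
    if ridge_config.banded:
        if band_slices is None:
            raise ValueError("banded ridge requires feature band slices")
        col_slices = [
            slice(s.start * L, s.stop * L) for s in band_slices
        ]  # feature-major layout keeps bands contiguous over lag columns
        lam_list = ridge_config.band_grid(len(band_slices))
    else:
        lam_list = list(ridge_config.lambda_grid)
    lagged = [lag_matrix(X, shifts)[:, pmask] for _, X, _ in solvers]
    trial_col, output_col, lam_col, r_col = [], [], [], []
    weights, trial_weights = {}, {}
    for lam in lam_list:
        if ridge_config.banded:
            fits = []
            for _, X, Y in solvers:
                Xl = lag_matrix(X, shifts)
                fits.append(
                    fit_banded(Xl - Xl.mean(axis=0), Y - Y.mean(axis=0), col_slices, lam)
                )
            W = np.stack(fits)
        else:
            W = np.stack([s.solve(lam) for s, _, _ in solvers])  # trials x p x out
        Wsum = W.sum(axis=0)
        for j, (trial_idx, (_, Xj, Yj)) in enumerate(zip(keep, solvers)):
            Wbar = (Wsum - W[j]) / (n_trials - 1)
            pred = lagged[j] @ Wbar[pmask]
            r = _pearson_rows(pred, Yj)
            trial_col.append(np.full(r.size, trial_idx))
            output_col.append(np.arange(r.size))
            lam_col.extend([lam] * r.size)
            r_col.append(r)
        weights[lam] = Wsum / n_trials
        if keep_trial_weights:
            trial_weights[lam] = W
    acc = pd.DataFrame(
        {
            "trial": np.concatenate(trial_col),
            "output": np.concatenate(output_col),
            "lambda": lam_col,
            "r": np.concatenate(r_col),
        }
    )
    return CVResult(acc, weights, trial_weights, lag_spec, n_feat, direction, space_id)


def aggregate_accuracy(cv: CVResult) -> pd.Series:
    """Accuracy per lambda in the stated order: trials, then outputs."""
    return cv.mean_accuracy()


def select_lambda(
    acc: pd.DataFrame, method: str = "mode_argmax"
) -> float:
    """Select the regularization strength from a table of accuracies.

    ``acc`` must have columns (participant, condition, lambda, accuracy),
    already averaged over trials and outputs.  The default takes, per
    (participant, condition) cell, the lambda with the highest accuracy and
    returns the mode over cells; ``method='pooled_peak'`` instead returns
    the lambda maximizing the pooled mean accuracy.  All ties break toward
    the smaller lambda.
    """
    if acc.empty:
        raise ValueError("empty accuracy table")
    if method == "pooled_peak":
        pooled = acc.groupby("lambda")["accuracy"].mean().sort_index()
        return float(pooled.index[np.argmax(pooled.to_numpy())])
    if method != "mode_argmax":
        raise ValueError(f"unknown method {method!r}")
    picks = []
    for _, cell in acc.groupby(["participant", "condition"]):
        cell = cell.sort_values("lambda")
        picks.append(float(cell["lambda"].iloc[np.argmax(cell["accuracy"].to_numpy())]))
    vals, counts = np.unique(picks, return_counts=True)
    return float(vals[np.argmax(counts)])  # np.unique sorts: first max = smallest


# ---------------------------------------------------------------------------
# decoding helpers


@dataclass
class PCAReduction:
    components: np.ndarray  # n_components x n_sensors
    mean: np.ndarray
    explained_variance: np.ndarray

    def transform(self, data: np.ndarray) -> np.ndarray:
        return (data - self.mean) @ self.components.T

    def inverse_transform(self, reduced: np.ndarray) -> np.ndarray:
        return reduced @ self.components + self.mean


def decode_setup(
    neural_trials: list[np.ndarray], n_components: int = 50
) -> tuple[list[np.ndarray], PCAReduction]:
    """Fit PCA on all trials jointly and project each trial.

    ``neural_trials`` are time x sensor matrices.  If fewer sensors than
    requested components are available the reduction keeps all sensors,
    with a warning.
    """
    from sklearn.decomposition import PCA

    stacked = np.vstack(neural_trials)
    n_sensors = stacked.shape[1]
    if n_sensors < n_components:
        warnings.warn(
            f"only {n_sensors} sensors available; keeping {n_sensors} components"
        )
        n_components = n_sensors
    pca = PCA(n_components=n_components, svd_solver="full").fit(stacked)
    red = PCAReduction(pca.components_, pca.mean_, pca.explained_variance_)
    return [red.transform(t) for t in neural_trials], red


def decode(
    reduced_trials: list[np.ndarray],
    target_trials: list[np.ndarray],
    lag_spec: LagSpec,
    ridge_config: RidgeConfig | None = None,
    space_id: str = "stm",
) -> CVResult:
    """Leave-one-trial-out decoding from reduced neural data to features."""
    return loto_cv(
        reduced_trials,
        target_trials,
        lag_spec,
        ridge_config,
        direction="decoding",
        space_id=space_id,
    )


def single_lag_decode(
    reduced_trials: list[np.ndarray],
    target_trials: list[np.ndarray],
    rate: float = 80.0,
    lag_min_ms: float = -50.0,
    lag_max_ms: float = 250.0,
    ridge_config: RidgeConfig | None = None,
) -> pd.DataFrame:
    """Decoding with a separate one-lag model per lag.

    Lambda is optimized independently at every lag (argmax of the mean CV
    accuracy over the grid).  Returns rows (lag_ms, lambda, trial, output, r).
    """
    if ridge_config is None:
        ridge_config = RidgeConfig()
    step = 1000.0 / rate
    lags = np.arange(round(lag_min_ms / step), round(lag_max_ms / step) + 1)
    out = []
    for l in lags:
        ms = l * step
        spec = LagSpec(ms, ms, ms, ms, rate)
        cv = loto_cv(reduced_trials, target_trials, spec, ridge_config, "decoding")
        mean_acc = cv.mean_accuracy()
        lam = float(mean_acc.index[np.argmax(mean_acc.to_numpy())])
        sub = cv.accuracy[cv.accuracy["lambda"] == lam].copy()
        sub["lag_ms"] = ms
        sub["lambda"] = lam
        out.append(sub)
    return pd.concat(out, ignore_index=True)
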