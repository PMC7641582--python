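"""Condition-level inference: sensor selection, repeated-measures tests,
permutation null distributions, and z-scoring against nulls.

The repeated-measures ANOVA is implemented for the balanced, complete
2 (prior) x 3 (detail) within-subject design via orthonormal contrasts;
Greenhouse-Geisser correction is applied to every effect involving the
3-level factor.  The two permutation schemes destroy, respectively, the
internal structure of each word's feature representation (within-trial
shuffle) and the word-to-trial assignment (across-trial shuffle, performed
within condition so the condition structure is preserved).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .features import FeatureSpace


# ---------------------------------------------------------------------------
# sensor selection


def select_top_sensors(
    accuracy: np.ndarray, hemispheres: np.ndarray, k: int = 20
) -> dict[str, np.ndarray]:
    """Indices of the ``k`` highest-accuracy sensors per hemisphere.

    ``accuracy`` is one mean accuracy per sensor.  Hemispheres with fewer
    than ``k`` sensors contribute all of them.
    """
    accuracy = np.asarray(accuracy, dtype=float)
    hemispheres = np.asarray(hemispheres)
    out = {}
    for h in ("L", "R"):
        idx = np.flatnonzero(hemispheres == h)
        if idx.size == 0:
            continue
        kk = min(k, idx.size)
        order = idx[np.argsort(accuracy[idx])[::-1]]
        out[h] = np.sort(order[:kk])
    return out


# ---------------------------------------------------------------------------
# repeated-measures ANOVA (balanced 2 x 3 within-subject)


def _orthonormal_polynomial(n: int) -> np.ndarray:
    """(n-1) x n orthonormal contrast rows, each orthogonal to the mean."""
    X = np.vander(np.arange(n, dtype=float), n, increasing=True)
    Q, _ = np.linalg.qr(X)
    return Q[:, 1:].T


def _within_effect(Y_cells: np.ndarray, C: np.ndarray) -> dict:
    """Univariate within-subject F test for the effect spanned by rows of C.

    ``Y_cells`` is subjects x cells; ``C`` has orthonormal rows in cell
    space.  Returns F, dfs, partial eta squared, uncorrected and
    Greenhouse-Geisser p values.
    """
    Z = Y_cells @ C.T  # subjects x q contrast scores
    n, q = Z.shape
    m = Z.mean(axis=0)
    ss_effect = n * float(m @ m)
    R = Z - m
    ss_error = float((R**2).sum())
    df1, df2 = q, q * (n - 1)
    if ss_error == 0:
        raise ValueError("zero error variance in repeated-measures effect")
    F = (ss_effect / df1) / (ss_error / df2)
    # Greenhouse-Geisser epsilon from the contrast-score covariance
    S = (R.T @ R) / (n - 1)
    eps = (np.trace(S) ** 2) / (q * float((S * S.T).sum())) if q > 1 else 1.0
    eps = float(np.clip(eps, 1.0 / q, 1.0))
    p_unc = float(sps.f.sf(F, df1, df2))
    p_gg = float(sps.f.sf(F, df1 * eps, df2 * eps))
    return {
        "F": F,
        "df1": df1,
        "df2": df2,
        "np2": ss_effect / (ss_effect + ss_error),
        "eps": eps,
        "p_unc": p_unc,
        "p_gg": p_gg,
        "p": p_gg if q > 1 else p_unc,
    }


def rm_anova_2x3(
    data: pd.DataFrame,
    value: str = "accuracy",
    prior_col: str = "prior",
    detail_col: str = "detail",
    subject_col: str = "participant",
) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA for the prior x detail design.

    Requires a complete, balanced table (one value per subject per cell).
    Returns main effects, the interaction, and simple effects of detail at
    each prior level.  Partial eta squared is SS_effect/(SS_effect+SS_error);
    p values for 3-level effects are Greenhouse-Geisser corrected.
    """
    priors = sorted(data[prior_col].unique())
    details = sorted(data[detail_col].unique())
    if len(priors) != 2 or len(details) != 3:
        raise ValueError("expected a 2 x 3 design")
    pivot = data.pivot_table(
        index=subject_col, columns=[prior_col, detail_col], values=value, aggfunc="mean"
    )
    cells = [(p, d) for p in priors for d in details]
    if pivot.isna().any().any() or pivot.shape[1] != 6:
        raise ValueError("design must be complete for every subject")
    Y = pivot[cells].to_numpy()  # subjects x 6, prior-major ordering
    ca = _orthonormal_polynomial(2)  # 1 x 2
    cb = _orthonormal_polynomial(3)  # 2 x 3
    one2 = np.full((1, 2), 1 / np.sqrt(2))
    one3 = np.full((1, 3), 1 / np.sqrt(3))
    rows = []
    for name, C in (
        ("prior", np.kron(ca, one3)),
        ("detail", np.kron(one2, cb)),
        ("prior x detail", np.kron(ca, cb)),
    ):
        rows.append({"effect": name, **_within_effect(Y, C)})
    # simple effects of detail at each prior level
    for ip, p in enumerate(priors):
        Yp = Y[:, ip * 3 : (ip + 1) * 3]
        rows.append({"effect": f"detail @ {p}", **_within_effect(Yp, cb)})
    return pd.DataFrame(rows)


def paired_t(x: np.ndarray, y: np.ndarray) -> dict:
    """Two-sided paired t test with Cohen's dz = mean(diff)/SD(diff)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance difference; t test undefined")
    t, p = sps.ttest_rel(x, y)
    return {"t": float(t), "df": d.size - 1, "dz": float(d.mean() / sd), "p": float(p)}


# ---------------------------------------------------------------------------
# permutation machinery


def shuffle_within_trial(space: FeatureSpace, seed: int) -> FeatureSpace:
    """Jointly permute all (feature, time) entries of one trial's features."""
    rng = np.random.default_rng(seed)
    flat = space.values.ravel()
    shuffled = rng.permutation(flat).reshape(space.values.shape)
    return replace(space, values=shuffled)


def shuffle_across_trials(
    features: dict,
    design: pd.DataFrame,
    seed: int,
    scope: str = "condition",
) -> dict:
    """Permute the word -> trial assignment, keeping each word's features intact.

    With ``scope='condition'`` the permutation happens within every
    (detail, prior) cell so the condition structure is preserved.  The
    identity permutation is excluded whenever a group has >= 2 trials.
    Returns a mapping trial_id -> word_id giving the reassigned features.
    """
    rng = np.random.default_rng(seed)
    if scope == "condition":
        groups = [g for _, g in design.groupby(["detail", "prior"], sort=False)]
    elif scope == "all":
        groups = [design]
    else:
        raise ValueError("scope must be 'condition' or 'all'")
    assignment = {}
    for g in groups:
        words = g["word_id"].to_numpy()
        if words.size < 2:
            perm = words
        else:
            for _ in range(100):
                perm = rng.permutation(words)
                if not np.array_equal(perm, words):
                    break
        for tid, w in zip(g["trial_id"].to_numpy(), perm):
            assignment[int(tid)] = w
    return assignment


@dataclass
class NullDistribution:
    scheme: str  # "within_trial_shuffle" | "across_trial_shuffle"
    values: pd.DataFrame  # columns: permutation, condition [, participant], accuracy
    seed: int

    def stats(self) -> pd.DataFrame:
        group_cols = [c for c in ("condition", "participant") if c in self.values]
        g = self.values.groupby(group_cols)["accuracy"]
        return g.agg(["mean", "std"]).reset_index()


def null_distribution(
    pipeline,
    scheme: str,
    n_perm: int = 100,
    seed: int = 0,
) -> NullDistribution:
    """Re-run a fixed-lambda accuracy pipeline under feature permutations.

    ``pipeline(scheme, perm_seed)`` must perform one full shuffled analysis
    (using the lambda optimized on the unshuffled data) and return a
    DataFrame with at least (condition, accuracy) rows.
    """
    if scheme not in ("within_trial_shuffle", "across_trial_shuffle"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    frames = []
    for k in range(n_perm):
        res = pipeline(scheme, seed + k).copy()
        res["permutation"] = k
        frames.append(res)
    return NullDistribution(scheme, pd.concat(frames, ignore_index=True), seed)


def zscore_vs_null(
    observed: pd.DataFrame, null: NullDistribution, on: list[str] | None = None
) -> pd.DataFrame:
    """z = (observed - null mean) / null SD, per condition (and participant)."""
    if on is None:
        on = [c for c in ("condition", "participant") if c in observed.columns]
    ns = null.stats()
    merged = observed.merge(ns, on=on, validate="many_to_one")
    if (merged["std"] <= 0).any():
        raise ValueError("null distribution has zero standard deviation")
    merged["z"] = (merged["accuracy"] - merged["mean"]) / merged["std"]
    return merged.drop(columns=["mean", "std"])


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject mask, adjusted p values)."""
    pvals = np.asarray(pvals, dtype=float)
    reject, p_adj, _, _ = multipletests(pvals.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(pvals.shape), p_adj.reshape(pvals.shape)


def interaction_contrast(
    acc: pd.DataFrame,
    value: str = "accuracy",
    unit_col: str = "unit",
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-unit interaction contrast (12-3, Mismatch) - (12-3, Match).

    ``acc`` needs columns (participant, detail, prior, unit, value) with
    detail levels 3 and 12 present.  A paired t across participants tests
    the contrast against zero per unit, BH-FDR corrected over units.
    """
    pivot = acc.pivot_table(
        index=["participant", unit_col], columns=["detail", "prior"], values=value
    )
    for cell in [(12, "Mismatch"), (3, "Mismatch"), (12, "Match"), (3, "Match")]:
        if cell not in pivot.columns:
            raise ValueError(f"missing condition cell {cell}")
    contrast = (pivot[(12, "Mismatch")] - pivot[(3, "Mismatch")]) - (
        pivot[(12, "Match")] - pivot[(3, "Match")]
    )
    wide = contrast.unstack(unit_col)  # participants x units
    rows = []
    for unit in wide.columns:
        d = wide[unit].to_numpy()
        res = paired_t(d, np.zeros_like(d))
        rows.append({"unit": unit, "contrast": d.mean(), **res})
    out = pd.DataFrame(rows)
    out["reject"], out["p_fdr"] = fdr_bh(out["p"].to_numpy(), q=q)
    return out
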