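"""Condition-level inference: sensor selection, RM-ANOVA, permutation
machinery, FDR, and the interaction contrast."""

import numpy as np
import pandas as pd
import pytest

from stmtrf.features import FeatureSpace
from stmtrf.simulate import make_design
from stmtrf.stats import (
    fdr_bh,
    interaction_contrast,
    paired_t,
    rm_anova_2x3,
    select_top_sensors,
    shuffle_across_trials,
    shuffle_within_trial,
    zscore_vs_null,
)


def _cell_table(Y, priors=("Match", "Mismatch"), details=(3, 6, 12)):
    """subjects x 6 matrix (prior-major) -> tidy accuracy table."""
    rows = []
    for s in range(Y.shape[0]):
        k = 0
        for p in priors:
            for d in details:
                rows.append(
                    {"participant": s, "prior": p, "detail": d, "accuracy": Y[s, k]}
                )
                k += 1
    return pd.DataFrame(rows)


class TestSelectTopSensors:
    hemis = np.array(["L"] * 5 + ["R"] * 5)

    def test_k1_is_argmax_per_hemisphere(self):
        acc = np.array([0.1, 0.9, 0.2, 0.3, 0.4, 0.8, 0.1, 0.2, 0.3, 0.4])
        sel = select_top_sensors(acc, self.hemis, k=1)
        assert sel["L"].tolist() == [1] and sel["R"].tolist() == [5]

    def test_k_all_reduces_to_plain_average(self):
        rng = np.random.default_rng(0)
        acc = rng.random(10)
        sel = select_top_sensors(acc, self.hemis, k=5)
        chosen = np.concatenate([sel["L"], sel["R"]])
        assert np.mean(acc[chosen]) == pytest.approx(np.mean(acc))

    def test_fewer_than_k_takes_all(self):
        acc = np.array([0.3, 0.1, 0.5])
        sel = select_top_sensors(acc, np.array(["L", "L", "R"]), k=20)
        assert sel["L"].tolist() == [0, 1] and sel["R"].tolist() == [2]

    def test_selections_independent_across_participants(self):
        a = select_top_sensors(np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 1.0]), self.hemis, 1)
        b = select_top_sensors(np.array([0, 1, 0, 0, 0, 1, 0, 0, 0, 0.0]), self.hemis, 1)
        assert a["L"].tolist() != b["L"].tolist()


class TestRmAnova:
    def test_degrees_of_freedom_21_participants(self):
        """The 3-level detail effects carry (2, 40) df with n = 21."""
        rng = np.random.default_rng(0)
        eff = rm_anova_2x3(_cell_table(rng.standard_normal((21, 6))))
        inter = eff.set_index("effect").loc["prior x detail"]
        assert (inter["df1"], inter["df2"]) == (2, 40)
        prior = eff.set_index("effect").loc["prior"]
        assert (prior["df1"], prior["df2"]) == (1, 20)

    def test_matches_pingouin(self):
        """F, uncorrected and GG-corrected p, and epsilon agree with the
        independent pingouin implementation."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        Y = rng.standard_normal((14, 6)) + np.linspace(0, 1, 6)
        data = _cell_table(Y)
        eff = rm_anova_2x3(data).set_index("effect")
        ref = pg.rm_anova(
            dv="accuracy", within=["prior", "detail"], subject="participant",
            data=data, detailed=True,
        ).set_index("Source")
        for ours, theirs in [
            ("prior", "prior"), ("detail", "detail"), ("prior x detail", "prior * detail")
        ]:
            assert eff.loc[ours, "F"] == pytest.approx(ref.loc[theirs, "F"], rel=1e-9)
            assert eff.loc[ours, "p_unc"] == pytest.approx(ref.loc[theirs, "p_unc"], rel=1e-6)
            assert eff.loc[ours, "p_gg"] == pytest.approx(
                ref.loc[theirs, "p_GG_corr"], rel=1e-6
            )
        simple = pg.rm_anova(
            dv="accuracy", within="detail", subject="participant",
            data=data[data["prior"] == "Match"], correction=True, detailed=True,
        )
        assert eff.loc["detail @ Match", "F"] == pytest.approx(simple["F"].iloc[0], rel=1e-9)

    def test_type_one_error_calibrated(self):
        """Interaction false-positive rate within [0.03, 0.07] at alpha=.05
        over 1000 null simulations."""
        rng = np.random.default_rng(7)
        hits = 0
        n = 1000
        for _ in range(n):
            eff = rm_anova_2x3(_cell_table(rng.standard_normal((12, 6))))
            hits += eff.set_index("effect").loc["prior x detail", "p"] < 0.05
        assert 0.03 <= hits / n <= 0.07

    def test_missing_cell_rejected(self):
        rng = np.random.default_rng(1)
        data = _cell_table(rng.standard_normal((6, 6)))
        with pytest.raises(ValueError):
            rm_anova_2x3(data[~((data.participant == 0) & (data.detail == 6))])


class TestPairedT:
    def test_identical_samples(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):  # zero-variance difference
            paired_t(x, x)

    def test_df_and_dz(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(21)
        y = x + rng.standard_normal(21) * 0.5 + 0.2
        res = paired_t(x, y)
        assert res["df"] == 20
        d = x - y
        assert res["dz"] == pytest.approx(d.mean() / d.std(ddof=1))

    def test_constant_offset_zero_variance_flagged(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError):
            paired_t(x, x + 1.0)


class TestShuffles:
    def _space(self, seed=0):
        rng = np.random.default_rng(seed)
        return FeatureSpace(rng.standard_normal((50, 4)), 80.0, list("abcd"), "stm")

    def test_within_trial_multiset_preserved_and_deterministic(self):
        sp = self._space()
        s1 = shuffle_within_trial(sp, seed=5)
        s2 = shuffle_within_trial(sp, seed=5)
        assert np.array_equal(np.sort(s1.values.ravel()), np.sort(sp.values.ravel()))
        assert np.array_equal(s1.values, s2.values)
        assert not np.array_equal(s1.values, sp.values)

    def test_within_trial_destroys_autocorrelation(self):
        t = np.arange(400)
        slow = np.sin(2 * np.pi * t / 100.0)[:, None] * np.ones((1, 4))
        sp = FeatureSpace(slow, 80.0, list("abcd"), "stm")
        sh = shuffle_within_trial(sp, seed=1).values[:, 0]
        ac = np.corrcoef(sh[:-1], sh[1:])[0, 1]
        assert abs(ac) < 0.1

    def test_across_trials_permutes_within_condition(self):
        design = make_design(3, seed=0)
        feats = {w: object() for w in design["word_id"]}
        assign = shuffle_across_trials(feats, design, seed=2)
        assert len(assign) == len(design)
        # every word still used exactly once
        assert sorted(assign.values()) == sorted(design["word_id"])
        for _, grp in design.groupby(["detail", "prior"]):
            words = set(grp["word_id"])
            reassigned = {assign[int(t)] for t in grp["trial_id"]}
            assert reassigned == words  # scope respected
        moved = sum(
            assign[int(r.trial_id)] != r.word_id for r in design.itertuples()
        )
        assert moved > 0

    def test_identity_excluded_over_seeds(self):
        design = make_design(2, seed=0)
        feats = {w: None for w in design["word_id"]}
        for seed in range(10):
            assign = shuffle_across_trials(feats, design, seed=seed)
            for _, grp in design.groupby(["detail", "prior"]):
                same = all(
                    assign[int(r.trial_id)] == r.word_id for r in grp.itertuples()
                )
                assert not same


class TestZscoreAndFDR:
    def _null(self):
        from stmtrf.stats import NullDistribution

        rng = np.random.default_rng(0)
        vals = pd.DataFrame(
            {
                "permutation": np.repeat(np.arange(200), 1),
                "condition": "c",
                "accuracy": rng.normal(0.1, 0.05, 200),
            }
        )
        return NullDistribution("within_trial_shuffle", vals, 0)

    def test_z_of_mean_and_mean_plus_2sd(self):
        null = self._null()
        st = null.stats()
        mu, sd = float(st["mean"].iloc[0]), float(st["std"].iloc[0])
        obs = pd.DataFrame({"condition": ["c", "c"], "accuracy": [mu, mu + 2 * sd]})
        z = zscore_vs_null(obs, null)["z"]
        assert z.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert z.iloc[1] == pytest.approx(2.0, abs=1e-12)

    def test_zero_sd_null_rejected(self):
        from stmtrf.stats import NullDistribution

        vals = pd.DataFrame(
            {"permutation": [0, 1], "condition": "c", "accuracy": [0.1, 0.1]}
        )
        null = NullDistribution("within_trial_shuffle", vals, 0)
        obs = pd.DataFrame({"condition": ["c"], "accuracy": [0.3]})
        with pytest.raises(ValueError):
            zscore_vs_null(obs, null)

    def test_fdr_all_small_all_rejected(self):
        reject, _ = fdr_bh(np.full(25, 0.001))
        assert reject.all()

    def test_fdr_single_marginal_p_not_rejected(self):
        """p = 0.04 against 24 at 1.0 fails the BH threshold 0.05/25."""
        p = np.concatenate([[0.04], np.ones(24)])
        reject, _ = fdr_bh(p)
        assert not reject.any()

    def test_permutation_p_rank_bound(self):
        """Observed above all 100 null values implies p <= 1/101."""
        null_vals = np.random.default_rng(0).normal(0, 0.01, 100)
        obs = 0.5
        p = (1 + np.sum(null_vals >= obs)) / (1 + null_vals.size)
        assert p <= 1 / 101 + 1e-12


class TestInteractionContrast:
    def _acc(self, effect=0.0, seed=0, n_sub=10, n_units=3):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_sub):
            for u in range(n_units):
                for d in (3, 12):
                    for p in ("Match", "Mismatch"):
                        val = rng.normal(0, 0.01)
                        if p == "Mismatch" and d == 12 and u == 0:
                            val += effect
                        if p == "Match" and d == 12 and u == 0:
                            val -= effect
                        rows.append(
                            {
                                "participant": s,
                                "unit": u,
                                "detail": d,
                                "prior": p,
                                "accuracy": val,
                            }
                        )
        return pd.DataFrame(rows)

    def test_null_contrast_near_zero(self):
        out = interaction_contrast(self._acc(0.0))
        assert np.all(np.abs(out["contrast"]) < 0.02)
        assert not out["reject"].any()

    def test_crossover_detected_in_injected_unit(self):
        out = interaction_contrast(self._acc(0.2)).set_index("unit")
        assert out.loc[0, "reject"]
        assert out.loc[0, "contrast"] > 0.3
        assert not out.loc[[1, 2], "reject"].any()

    def test_antisymmetric_under_prior_swap(self):
        acc = self._acc(0.1, seed=3)
        swapped = acc.copy()
        swapped["prior"] = swapped["prior"].map({"Match": "Mismatch", "Mismatch": "Match"})
        a = interaction_contrast(acc)["contrast"].to_numpy()
        b = interaction_contrast(swapped)["contrast"].to_numpy()
        np.testing.assert_allclose(a, -b, atol=1e-12)
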