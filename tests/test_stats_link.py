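import numpy as np
import pandas as pd
import pytest

from fmtlink.errors import NotEstimableError
from fmtlink.stats_link import (
    fdr_bh,
    fit_lmm_random_intercept,
    multilevel_split,
    preprocess_metabolites,
    procrustes_test,
    spearman_link,
)


class TestPreprocessMetabolites:
    def test_worked_example_impute_then_scale(self):
        out = preprocess_metabolites(pd.DataFrame({"m": [2.0, 4.0, np.nan]}))
        assert out["m"].tolist() == [1.0, 2.0, 0.5]

    def test_median_is_one_without_missing(self, rng):
        raw = pd.DataFrame(rng.lognormal(0, 0.5, size=(20, 5)),
                           columns=list("abcde"))
        out = preprocess_metabolites(raw)
        assert (out.median(axis=0) == 1.0).all()

    def test_constant_column_maps_to_ones(self):
        out = preprocess_metabolites(pd.DataFrame({"m": [3.0] * 5}))
        assert (out["m"] == 1.0).all()

    def test_imputed_values_below_observed_minimum(self, rng):
        raw = pd.DataFrame({"m": [1.0, 2.0, 3.0, np.nan, np.nan]})
        out = preprocess_metabolites(raw)
        observed_min = out["m"].iloc[:3].min()
        assert (out["m"].iloc[3:] < observed_min).all()

    def test_all_missing_metabolite_dropped(self):
        raw = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "gone": [np.nan] * 3})
        with pytest.warns(UserWarning, match="gone"):
            out = preprocess_metabolites(raw)
        assert list(out.columns) == ["ok"]

    def test_even_length_columns_still_get_exact_unit_median(self, rng):
        raw = pd.DataFrame(rng.lognormal(0, 0.4, size=(58, 8)))
        out = preprocess_metabolites(raw)
        assert (out.median(axis=0) == 1.0).all()


class TestLmm:
    def did_data(self, effect=-16.0, noise=0.0, n=20, rng=None):
        rows = []
        for i in range(n):
            eng = 1.0 if i < n // 2 else 0.0
            pre = 80.0 + i
            post = pre + effect * eng
            if rng is not None:
                pre += rng.normal(0, noise)
                post += rng.normal(0, noise)
            rows.append((f"s{i}", eng, 0.0, pre))
            rows.append((f"s{i}", eng, 1.0, post))
        df = pd.DataFrame(
            rows, columns=["subject_id", "engrafted", "time_post", "value"]
        )
        df["engrafted_time"] = df["engrafted"] * df["time_post"]
        return df

    FIXED = ["engrafted", "time_post", "engrafted_time"]

    def test_interaction_equals_difference_in_differences_exactly(self):
        fit = fit_lmm_random_intercept(self.did_data(), "value", self.FIXED)
        assert fit.params["engrafted_time"] == pytest.approx(-16.0, abs=1e-8)

    def test_matches_statsmodels_mixedlm_on_noisy_data(self, rng):
        import statsmodels.formula.api as smf

        df = self.did_data(effect=-5.0, noise=3.0, rng=rng)
        fit = fit_lmm_random_intercept(df, "value", self.FIXED)
        ref = smf.mixedlm(
            "value ~ engrafted + time_post + engrafted_time",
            df,
            groups=df["subject_id"],
        ).fit(reml=True)
        assert fit.params["engrafted_time"] == pytest.approx(
            ref.params["engrafted_time"], abs=1e-6
        )
        assert fit.bse["engrafted_time"] == pytest.approx(
            ref.bse["engrafted_time"], rel=1e-3
        )
        assert fit.sigma2 == pytest.approx(ref.scale, rel=1e-3)

    def test_satterthwaite_df_positive_and_at_most_residual_df(self, rng):
        df = self.did_data(effect=0.0, noise=4.0, n=29, rng=rng)
        fit = fit_lmm_random_intercept(df, "value", self.FIXED)
        assert 1.0 <= fit.df["engrafted_time"] <= 58 - 4

    def test_needs_two_subjects(self):
        df = self.did_data(n=1)
        with pytest.raises(NotEstimableError):
            fit_lmm_random_intercept(df, "value", self.FIXED)


class TestFdr:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            fdr_bh(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_pvalue_unchanged(self):
        assert fdr_bh(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_adjustment_never_decreases_and_preserves_order(self, rng):
        p = rng.uniform(size=50)
        q = fdr_bh(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestSpearman:
    def test_perfect_monotone_is_plus_one(self):
        res = spearman_link([1, 2, 3, 4, 5], [10, 20, 40, 80, 160])
        assert res.rho == pytest.approx(1.0)
        # exact permutation null at n=5: only identity and reversal reach |1|
        assert res.pvalue == pytest.approx(2 / 120)

    def test_reversed_is_minus_one(self):
        res = spearman_link([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert res.rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        from scipy import stats

        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        res = spearman_link(x, y)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert res.rho == pytest.approx(oracle, abs=1e-12)
        assert res.method == "t-approx"

    def test_constant_vector_flagged(self):
        with pytest.raises(NotEstimableError, match="constant"):
            spearman_link([1, 1, 1, 1], [1, 2, 3, 4])

    def test_pairwise_complete_handling(self):
        res = spearman_link(
            [1, 2, 3, 4, np.nan, 6], [2, 4, 6, 8, 10, np.nan]
        )
        assert res.n == 4


class TestProcrustes:
    def test_rotated_copy_is_perfectly_concordant(self, rng):
        A = rng.normal(size=(19, 5))
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        res = procrustes_test(A, A @ Q, n_perm=999, seed=0)
        assert res.m2 < 1e-10
        assert res.pvalue == pytest.approx(1 / 1000)

    def test_m2_invariant_to_orthogonal_rotation_of_either_input(self, rng):
        A = rng.normal(size=(15, 4))
        B = rng.normal(size=(15, 4)) + 0.5 * A
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        r0 = procrustes_test(A, B, n_perm=19, seed=0)
        r1 = procrustes_test(A @ Q, B, n_perm=19, seed=0)
        r2 = procrustes_test(A, B @ Q, n_perm=19, seed=0)
        assert r1.m2 == pytest.approx(r0.m2, abs=1e-10)
        assert r2.m2 == pytest.approx(r0.m2, abs=1e-10)

    def test_fixed_seed_reproducible(self, rng):
        A = rng.normal(size=(12, 4))
        B = rng.normal(size=(12, 4))
        p1 = procrustes_test(A, B, n_perm=99, seed=5).pvalue
        p2 = procrustes_test(A, B, n_perm=99, seed=5).pvalue
        assert p1 == p2

    def test_too_few_subjects_rejected(self, rng):
        A = rng.normal(size=(3, 4))
        with pytest.raises(NotEstimableError):
            procrustes_test(A, A, n_perm=9, seed=0)


class TestMultilevelSplit:
    def frame(self, rows, cols=3):
        idx = pd.MultiIndex.from_tuples(rows, names=["subject_id", "time"])
        rng = np.random.default_rng(1)
        return pd.DataFrame(
            rng.normal(size=(len(rows), cols)), index=idx,
            columns=[f"m{i}" for i in range(cols)],
        )

    def test_between_plus_within_reconstructs_exactly(self):
        X = self.frame([("a", "pre"), ("a", "post"), ("b", "pre"), ("b", "post")])
        between, within, _ = multilevel_split(
            X, X.index.get_level_values("subject_id")
        )
        pd.testing.assert_frame_equal(between + within, X)

    def test_identical_pre_post_rows_give_zero_within(self):
        X = self.frame([("a", "pre"), ("b", "pre")])
        X = pd.concat([X, X.rename(index={"pre": "post"}, level="time")])
        _, within, _ = multilevel_split(X, X.index.get_level_values("subject_id"))
        assert np.allclose(within.to_numpy(), 0.0)

    def test_single_observation_subject_flagged(self):
        X = self.frame([("a", "pre"), ("a", "post"), ("c", "pre")])
        _, within, flagged = multilevel_split(
            X, X.index.get_level_values("subject_id")
        )
        assert flagged == ["c"]
        assert np.allclose(within.loc["c"].to_numpy(), 0.0)

    def test_planted_within_axis_recovered_by_first_within_pc(self, rng):
        subjects = [f"s{i}" for i in range(25)]
        direction = rng.normal(size=6)
        direction /= np.linalg.norm(direction)
        rows, data = [], []
        for s in subjects:
            base = rng.normal(0, 5.0, 6)  # large between-subject spread
            shift = rng.normal(2.0, 0.3) * direction
            rows += [(s, "pre"), (s, "post")]
            data += [base - shift / 2, base + shift / 2]
        X = pd.DataFrame(
            data,
            index=pd.MultiIndex.from_tuples(rows, names=["subject_id", "time"]),
        )
        _, within, _ = multilevel_split(X, X.index.get_level_values("subject_id"))
        _, _, Vt = np.linalg.svd(within.to_numpy() - within.to_numpy().mean(0))
        assert abs(Vt[0] @ direction) > 0.95
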