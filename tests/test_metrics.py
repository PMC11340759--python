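import numpy as np
import pandas as pd
import pytest

from fmtlink.errors import IntegrityError, NotEstimableError
from fmtlink.metrics import (
    build_dissimilarity_pairs,
    classify_pattern,
    compare_abundance,
    export_network,
    fit_dissimilarity_model,
    post_fractions,
    sharing_rate,
    SharingResult,
)
from fmtlink.strain_calling import ThresholdEntry

from test_strain_calling import make_dset, make_triads


def entry(sgb_id, t=0.1):
    return ThresholdEntry(
        sgb_id=sgb_id, threshold=t, rule="pct3", n_related=10,
        n_unrelated=100, passed_filters=True, estimable=True,
    )


def toy_cohort(n_sgb=10, n_shared=5):
    """Two samples profiled in n_sgb SGBs, sharing in the first n_shared."""
    dsets, thresholds = [], {}
    for k in range(n_sgb):
        d = 0.01 if k < n_shared else 0.5
        dsets.append(make_dset(["a", "b"], {("a", "b"): d}, sgb_id=f"SGB{k}"))
        thresholds[f"SGB{k}"] = entry(f"SGB{k}")
    return dsets, thresholds


class TestSharingRate:
    def test_five_shared_of_ten_common(self):
        dsets, thresholds = toy_cohort(10, 5)
        res = sharing_rate("a", "b", dsets, thresholds)
        assert res.n_shared == 5 and res.n_common_species == 10
        assert res.rate == 0.5

    def test_zero_shared_is_zero_rate(self):
        dsets, thresholds = toy_cohort(4, 0)
        assert sharing_rate("a", "b", dsets, thresholds).rate == 0.0

    def test_zero_common_species_is_missing(self):
        dsets, thresholds = toy_cohort(3, 1)
        res = sharing_rate("a", "zzz", dsets, thresholds)
        assert res.n_common_species == 0
        assert np.isnan(res.rate)

    def test_rate_is_symmetric_in_sample_order(self):
        dsets, thresholds = toy_cohort(7, 3)
        assert (
            sharing_rate("a", "b", dsets, thresholds).rate
            == sharing_rate("b", "a", dsets, thresholds).rate
        )


class TestPostFractions:
    def build(self, d_pre, d_donor, n_sgb=4):
        triads = make_triads(1)
        t = triads.triads()[0]
        dsets, thresholds = [], {}
        for k in range(n_sgb):
            dsets.append(
                make_dset(
                    [t.donor_sample, t.pre_sample, t.post_sample],
                    {
                        (t.pre_sample, t.post_sample): d_pre,
                        (t.donor_sample, t.post_sample): d_donor,
                    },
                    sgb_id=f"SGB{k}",
                )
            )
            thresholds[f"SGB{k}"] = entry(f"SGB{k}")
        return t, dsets, thresholds

    def test_all_post_strains_from_pre_none_from_donor(self):
        t, dsets, thresholds = self.build(d_pre=0.01, d_donor=0.5)
        assert post_fractions(t, dsets, thresholds) == (0.0, 1.0)

    def test_perfect_engraftment_gives_full_donor_fraction(self):
        t, dsets, thresholds = self.build(d_pre=0.5, d_donor=0.01)
        f_donor, _ = post_fractions(t, dsets, thresholds)
        assert f_donor == 1.0

    def test_fractions_can_sum_above_one(self):
        # post strain shared with both sides counts in both numerators
        t, dsets, thresholds = self.build(d_pre=0.01, d_donor=0.02)
        f_donor, f_pre = post_fractions(t, dsets, thresholds)
        assert f_donor + f_pre == 2.0

    def test_ground_truth_tallies_on_separable_cohort(self, small_bundle):
        # fixed mid threshold: with distances at exactly 0.01 / 0.5 a cut at
        # 0.25 makes sharing coincide with the planted same-strain relation
        b = small_bundle
        entries = {d.sgb_id: entry(d.sgb_id, t=0.25) for d in b.distance_sets}
        truth = b.ground_truth
        for triad in b.triads.triads():
            f_donor, _ = post_fractions(triad, b.distance_sets, entries)
            # oracle recount from ground truth: engrafted SGBs / profiled post
            post_profiled = [
                d.sgb_id for d in b.distance_sets if triad.post_sample in d
            ]
            if not post_profiled:
                continue
            expected = (
                sum(
                    truth.engraftment.at[s, triad.subject_id]
                    for s in post_profiled
                )
                / len(post_profiled)
            )
            assert f_donor == pytest.approx(expected)


class TestDissimilarityModel:
    def synthetic_pairs(self, beta=-0.2, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for post in (0, 1):
            for donor in (0, 1):
                for _ in range(25):
                    d = 0.9 - 0.05 * post - 0.05 * donor + beta * post * donor
                    rows.append(
                        {
                            "post": post,
                            "donor": donor,
                            "dissimilarity": d + rng.normal(0, noise),
                        }
                    )
        return pd.DataFrame(rows)

    def test_noiseless_planted_interaction_recovered_exactly(self):
        fit = fit_dissimilarity_model(self.synthetic_pairs(beta=-0.2))
        assert fit.beta_donor_post == pytest.approx(-0.2, abs=1e-12)

    def test_ols_matches_normal_equation_oracle(self):
        pairs = self.synthetic_pairs(beta=-0.1, noise=0.05, seed=3)
        fit = fit_dissimilarity_model(pairs)
        X = np.column_stack(
            [
                np.ones(len(pairs)),
                pairs.post,
                pairs.donor,
                pairs.post * pairs.donor,
            ]
        ).astype(float)
        y = pairs.dissimilarity.to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_null_interaction_is_small_on_average(self):
        estimates = [
            fit_dissimilarity_model(
                self.synthetic_pairs(beta=0.0, noise=0.05, seed=s)
            ).beta_donor_post
            for s in range(30)
        ]
        assert abs(np.mean(estimates)) < 0.01

    def test_rank_deficient_design_names_aliased_column(self):
        pairs = self.synthetic_pairs()
        pairs["donor"] = 1  # aliased with the intercept
        with pytest.raises(IntegrityError, match="donor"):
            fit_dissimilarity_model(pairs)

    def test_pair_universe_from_separable_cohort(self, small_bundle):
        b = small_bundle
        entries = {d.sgb_id: entry(d.sgb_id, t=0.25) for d in b.distance_sets}
        pairs = build_dissimilarity_pairs(b.triads, b.distance_sets, entries)
        assert ((pairs.dissimilarity >= 0) & (pairs.dissimilarity <= 1)).all()
        fit = fit_dissimilarity_model(pairs)
        # donor-related post samples are strictly less dissimilar
        assert fit.beta_donor_post < 0


class TestCompareAbundance:
    def test_identical_vectors_not_significant(self):
        pre = np.array([0.01, 0.02, 0.03, 0.04])
        assert compare_abundance(pre, pre.copy())[1] == 1.0

    def test_six_concordant_increases_exact_p(self):
        pre = np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.06])
        _, p = compare_abundance(pre, pre * 2)
        assert p == pytest.approx(0.03125)

    def test_fewer_than_three_pairs_not_testable(self):
        with pytest.raises(NotEstimableError):
            compare_abundance(np.array([0.1, 0.2]), np.array([0.2, 0.3]))

    def test_power_rises_with_planted_shift(self, rng):
        n = 12
        pre = rng.uniform(0.01, 0.05, n)

        def reject_rate(shift, reps=60):
            hits = 0
            for _ in range(reps):
                post = pre * shift + rng.normal(0, 0.002, n)
                hits += compare_abundance(pre, post)[1] < 0.05
            return hits / reps

        assert reject_rate(1.0) < 0.2 < reject_rate(2.0)


class TestClassifyPattern:
    def matrix(self, subjects, engrafted):
        m = pd.DataFrame(
            0, index=pd.Index(["SGB1"], name="sgb_id"), columns=subjects
        )
        for s in engrafted:
            m.at["SGB1", s] = 1
        return m

    def test_pre_absent_engrafted_is_novel(self):
        subjects = ["s1", "s2", "s3"]
        m = self.matrix(subjects, ["s1"])
        call = classify_pattern(
            "SGB1", "s1", m, {"s1": 0.0, "s2": 0.01, "s3": 0.02},
            {"s1": 0.05, "s2": 0.01, "s3": 0.02},
        )
        assert call.pattern == "novel"

    def test_unchanged_abundance_is_replacement(self):
        subjects = [f"s{i}" for i in range(6)]
        m = self.matrix(subjects, subjects)
        pre = {s: 0.02 for s in subjects}
        call = classify_pattern("SGB1", "s0", m, pre, dict(pre))
        assert call.pattern == "replacement"

    def test_planted_doubling_is_expansion(self):
        subjects = [f"s{i}" for i in range(8)]
        m = self.matrix(subjects, subjects)
        pre = {s: 0.01 + 0.002 * i for i, s in enumerate(subjects)}
        post = {s: v * 2 for s, v in pre.items()}
        call = classify_pattern("SGB1", "s0", m, pre, post)
        assert call.pattern == "expansion"

    def test_missing_abundance_flagged(self):
        m = self.matrix(["s1"], ["s1"])
        call = classify_pattern("SGB1", "s1", m, {}, {})
        assert call.pattern == "missing"


class TestNetworkExport:
    def test_single_shared_strain_single_edge_weight_one(self):
        nodes, edges = export_network(
            [SharingResult("a", "b", 1, 4)], roles={"a": "pre", "b": "post"}
        )
        assert len(edges) == 1
        assert edges.iloc[0].weight == 1.0
        assert set(nodes.sample_id) == {"a", "b"}

    def test_squared_edge_weights(self):
        _, edges = export_network(
            [SharingResult("a", "b", 3, 5)], roles={"a": "pre", "b": "post"}
        )
        assert edges.iloc[0].weight == 9.0

    def test_no_sharing_gives_edgeless_graph(self):
        nodes, edges = export_network(
            [SharingResult("a", "b", 0, 4)], roles={"a": "pre", "b": "post"}
        )
        assert len(edges) == 0 and len(nodes) == 2

    def test_layout_is_deterministic_under_seed(self):
        sharing = [
            SharingResult("a", "b", 2, 4),
            SharingResult("b", "c", 1, 4),
        ]
        roles = {"a": "pre", "b": "post", "c": "donor"}
        n1, _ = export_network(sharing, roles, seed=5)
        n2, _ = export_network(sharing, roles, seed=5)
        pd.testing.assert_frame_equal(n1, n2)
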