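import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmtlink.io import DistanceSet, SampleRecord, TriadTable
from fmtlink.strain_calling import (
    PairLabeling,
    assign_origin,
    build_engraftment_matrix,
    call_cohort,
    call_sharing,
    estimate_threshold,
    filter_profiles,
    label_pairs,
    youden_threshold,
)


def make_dset(sample_ids, dist, sgb_id="SGB1", marker_counts=None):
    n = len(sample_ids)
    D = np.zeros((n, n))
    idx = {s: i for i, s in enumerate(sample_ids)}
    for (a, b), d in dist.items():
        D[idx[a], idx[b]] = D[idx[b], idx[a]] = d
    return DistanceSet(
        sgb_id=sgb_id,
        sample_ids=list(sample_ids),
        D=D,
        marker_counts=marker_counts or {s: 100 for s in sample_ids},
    )


def make_triads(n, shared_donor=False):
    records = []
    donors = 1 if shared_donor else n
    for d in range(donors):
        records.append(SampleRecord(f"D{d}_don", f"D{d}", "donor", "A", ""))
    for i in range(n):
        d = 0 if shared_donor else i
        records.append(SampleRecord(f"S{i}_pre", f"S{i}", "pre", "A", f"D{d}"))
        records.append(SampleRecord(f"S{i}_post", f"S{i}", "post", "A", f"D{d}"))
    return TriadTable(records)


class TestFilterProfiles:
    def test_marker_count_boundary_is_inclusive_at_20(self):
        ids = ["a", "b", "c"]
        dset = make_dset(ids, {}, marker_counts={"a": 19, "b": 20, "c": 100})
        filtered, usable = filter_profiles(dset)
        assert filtered.sample_ids == ["b", "c"]
        assert usable

    def test_fewer_than_two_samples_flags_sgb_unusable(self):
        dset = make_dset(["a", "b"], {}, marker_counts={"a": 5, "b": 100})
        _, usable = filter_profiles(dset)
        assert not usable

    def test_marker_prevalence_boundary_is_inclusive_at_half(self):
        ids = ["a", "b", "c", "d"]
        # marker m1 present in exactly 50% of samples -> retained
        presence = pd.DataFrame(
            {
                **{f"m{j}": [True] * 4 for j in range(25)},
                "m_half": [True, True, False, False],
            },
            index=ids,
        )
        dset = make_dset(ids, {})
        filtered, usable = filter_profiles(dset, marker_presence=presence)
        assert usable
        # all samples keep >= 20 markers after the prevalence rule
        assert filtered.sample_ids == ids


class TestLabelPairs:
    def test_complete_triad_yields_two_related_pairs(self):
        triads = make_triads(1)
        dset = make_dset(["D0_don", "S0_pre", "S0_post"], {})
        lab = label_pairs(triads, dset)
        assert (lab.pairs.label == "related").sum() == 2

    def test_two_triads_pair_classification_matches_brute_force(self):
        triads = make_triads(2)
        ids = ["D0_don", "D1_don", "S0_pre", "S0_post", "S1_pre", "S1_post"]
        dset = make_dset(ids, {})
        lab = label_pairs(triads, dset)
        # independent enumeration from the definition: related = same-subject
        # pre/post + within-triad donor/post; everything else cross-subject
        # (including within-triad donor/pre) is unrelated
        related = {
            frozenset(p)
            for p in [
                ("S0_pre", "S0_post"),
                ("D0_don", "S0_post"),
                ("S1_pre", "S1_post"),
                ("D1_don", "S1_post"),
            ]
        }
        subject = {s: s.split("_")[0] for s in ids}
        expected_unrelated = {
            frozenset((a, b))
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
            if frozenset((a, b)) not in related and subject[a] != subject[b]
        }
        got_related = {
            frozenset((r.sample_a, r.sample_b))
            for r in lab.pairs[lab.pairs.label == "related"].itertuples()
        }
        got_unrelated = {
            frozenset((r.sample_a, r.sample_b))
            for r in lab.pairs[lab.pairs.label == "unrelated"].itertuples()
        }
        assert got_related == related
        assert got_unrelated == expected_unrelated
        assert len(got_related) == 4 and len(got_unrelated) == 11

    def test_triad_missing_pre_sample_keeps_donor_post_pair_only(self):
        triads = make_triads(1)
        dset = make_dset(["D0_don", "S0_post"], {})
        lab = label_pairs(triads, dset)
        rel = lab.pairs[lab.pairs.label == "related"]
        assert len(rel) == 1
        assert {rel.iloc[0].sample_a, rel.iloc[0].sample_b} == {
            "D0_don",
            "S0_post",
        }


class TestEstimateThreshold:
    def pairs(self, related, unrelated):
        return PairLabeling(
            "x",
            pd.DataFrame(
                {
                    "sample_a": "a",
                    "sample_b": "b",
                    "label": ["related"] * len(related)
                    + ["unrelated"] * len(unrelated),
                    "distance": np.concatenate([related, unrelated]),
                }
            ),
        )

    def test_pct3_with_linear_interpolation(self):
        unrelated = np.round(np.arange(1, 101) * 0.01, 10)
        entry = estimate_threshold(self.pairs(np.full(10, 0.005), unrelated))
        assert entry.rule == "pct3"
        assert entry.threshold == pytest.approx(0.0397)

    def test_youden_tie_breaks_to_smallest_threshold(self):
        related = np.linspace(0.01, 0.1, 60)
        unrelated = np.linspace(0.5, 1.0, 100)
        entry = estimate_threshold(self.pairs(related, unrelated))
        # J = 1 anywhere in [0.1, 0.5); smallest optimum is max(related)
        assert entry.rule == "youden"
        assert entry.threshold == pytest.approx(0.1)
        assert entry.youden_j == pytest.approx(1.0)

    def test_most_conservative_rule_picks_smaller_of_youden_and_pct5(self):
        # identically distributed related/unrelated: no signal, pct5 governs
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.1, 0.9, 200)
        entry = estimate_threshold(self.pairs(vals[:60], vals[60:]))
        assert entry.rule == "pct5"
        assert entry.threshold == pytest.approx(np.percentile(vals[60:], 5))

    def test_zero_unrelated_pairs_not_estimable(self):
        entry = estimate_threshold(self.pairs(np.full(10, 0.01), np.array([])))
        assert not entry.estimable

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_youden_agrees_with_midpoint_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        related = rng.normal(0.2, 0.1, 30).clip(0)
        unrelated = rng.normal(0.5, 0.2, 40).clip(0)
        _, j = youden_threshold(related, unrelated)
        # brute force over midpoints between consecutive sorted distances
        pooled = np.sort(np.unique(np.concatenate([related, unrelated])))
        mids = (pooled[:-1] + pooled[1:]) / 2
        candidates = np.concatenate([mids, pooled, [pooled[-1] + 1]])
        best = max(
            np.mean(related <= t) - np.mean(unrelated <= t) for t in candidates
        )
        assert j == pytest.approx(best, abs=1e-12)


class TestSharingAndOrigin:
    def test_sharing_boundary_is_inclusive(self):
        assert call_sharing(0.0, 0.0)
        assert call_sharing(0.1, 0.1)
        assert not call_sharing(0.1 + 1e-12, 0.1)

    def triad(self):
        return make_triads(1).triads()[0]

    def test_shared_only_with_pre_is_recipient(self):
        dset = make_dset(
            ["D0_don", "S0_pre", "S0_post"],
            {("S0_pre", "S0_post"): 0.01, ("D0_don", "S0_post"): 0.6},
        )
        call = assign_origin(self.triad(), dset, threshold=0.1)
        assert call.origin == "recipient"
        assert call.shared_with_pre and not call.shared_with_donor

    def test_shared_with_both_resolved_by_lowest_distance(self):
        dset = make_dset(
            ["D0_don", "S0_pre", "S0_post"],
            {("S0_pre", "S0_post"): 0.04, ("D0_don", "S0_post"): 0.02},
        )
        call = assign_origin(self.triad(), dset, threshold=0.1)
        assert call.origin == "donor"

    def test_absent_pre_profile_with_donor_sharing_is_novel(self):
        dset = make_dset(
            ["D0_don", "S0_post"], {("D0_don", "S0_post"): 0.02}
        )
        call = assign_origin(self.triad(), dset, threshold=0.1)
        assert call.origin == "novel_donor"

    def test_shared_with_neither_is_retained_unshared(self):
        dset = make_dset(
            ["D0_don", "S0_pre", "S0_post"],
            {("S0_pre", "S0_post"): 0.5, ("D0_don", "S0_post"): 0.6},
        )
        call = assign_origin(self.triad(), dset, threshold=0.1)
        assert call.origin == "retained_unshared"
        assert not call.de_novo

    def test_present_post_only_is_de_novo_flagged(self):
        dset = make_dset(["S0_post", "X"], {("S0_post", "X"): 0.5})
        call = assign_origin(self.triad(), dset, threshold=0.1)
        assert call.origin == "retained_unshared"
        assert call.de_novo

    def test_post_sample_not_profiled_is_absent(self):
        dset = make_dset(["D0_don", "S0_pre"], {})
        call = assign_origin(self.triad(), dset, threshold=0.1)
        assert call.origin == "absent"


class TestEngraftmentMatrix:
    def test_all_recipient_origins_give_zero_matrix(self):
        triads = make_triads(2)
        calls = []
        for t in triads.triads():
            dset = make_dset(
                [t.donor_sample, t.pre_sample, t.post_sample],
                {
                    (t.pre_sample, t.post_sample): 0.01,
                    (t.donor_sample, t.post_sample): 0.5,
                },
            )
            calls.append(assign_origin(t, dset, threshold=0.1))
        m = build_engraftment_matrix(calls)
        assert m.to_numpy().sum() == 0

    def test_novel_donor_counts_as_engraftment(self):
        triads = make_triads(1)
        t = triads.triads()[0]
        dset = make_dset([t.donor_sample, t.post_sample],
                         {(t.donor_sample, t.post_sample): 0.02})
        m = build_engraftment_matrix([assign_origin(t, dset, 0.1)])
        assert m.at["SGB1", "S0"] == 1

    def test_perfect_separation_recovers_ground_truth(self, small_bundle):
        b = small_bundle
        _, calls, _ = call_cohort(b.triads, b.distance_sets)
        truth = b.ground_truth.engraftment
        called = build_engraftment_matrix(
            calls, sgb_ids=list(truth.index), subjects=list(truth.columns)
        )
        assert (called == truth).all().all()


class TestThresholdMonotonicity:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_raising_threshold_never_reduces_sharing_calls(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 1, 50)
        thresholds = np.sort(rng.uniform(0, 1, 10))
        counts = [np.sum(d <= t) for t in thresholds]
        assert all(a <= b for a, b in zip(counts, counts[1:]))
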