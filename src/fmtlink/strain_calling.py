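"""Per-SGB strain-identity thresholds, strain-sharing calls and post-FMT
origin assignment.

The operational definition of "same strain" is species-specific: for each
SGB the distribution of normalized phylogenetic distances between
*potentially related* sample pairs (pre/post of the same recipient, and
donor/post within a triad — donor strains may engraft) is compared with the
distribution between *unrelated* pairs (samples of different subjects with
no transplantation link). When at least ``min_related`` related pairs are
available the threshold is the more conservative (smaller) of the
Youden-optimal cut and the 5th percentile of the unrelated distances;
otherwise the 3rd percentile of the unrelated distances is used. Two
samples share a strain when their distance is at or below the threshold
(inclusive boundary). A post-FMT strain shared with both the donor and the
recipient's own pre-FMT sample is assigned to the side with the lower
distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import NotEstimableError
from .io import DistanceSet, Triad, TriadTable

log = logging.getLogger(__name__)

Origin = Literal["donor", "recipient", "novel_donor", "retained_unshared", "absent"]

#: Minimum related-pair count for the Youden / 5th-percentile rule.
MIN_RELATED_DEFAULT = 50


@dataclass
class PairLabeling:
    """Related/unrelated pair labels with distances for one SGB."""

    sgb_id: str
    pairs: pd.DataFrame  # columns: sample_a, sample_b, label, distance

    @property
    def related(self) -> np.ndarray:
        return self.pairs.loc[self.pairs.label == "related", "distance"].to_numpy()

    @property
    def unrelated(self) -> np.ndarray:
        return self.pairs.loc[self.pairs.label == "unrelated", "distance"].to_numpy()


@dataclass
class ThresholdEntry:
    """Strain-identity threshold for one SGB and the rule that produced it."""

    sgb_id: str
    threshold: float
    rule: Literal["youden", "pct5", "pct3", "none"]
    n_related: int
    n_unrelated: int
    passed_filters: bool
    estimable: bool
    youden_j: float = float("nan")

    def to_row(self) -> dict:
        return {
            "sgb_id": self.sgb_id,
            "threshold": self.threshold,
            "rule": self.rule,
            "n_related": self.n_related,
            "n_unrelated": self.n_unrelated,
            "passed_filters": self.passed_filters,
            "estimable": self.estimable,
            "youden_j": self.youden_j,
        }


@dataclass
class OriginCall:
    """Origin of the strain observed in one post-FMT sample for one SGB."""

    sgb_id: str
    post_sample: str
    subject_id: str
    origin: Origin
    d_pre: float | None
    d_donor: float | None
    shared_with_pre: bool
    shared_with_donor: bool
    de_novo: bool = False


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_profiles(
    dset: DistanceSet,
    marker_counts: dict[str, int] | None = None,
    min_markers: int = 20,
    marker_presence: pd.DataFrame | None = None,
    min_marker_prevalence: float = 0.5,
) -> tuple[DistanceSet, bool]:
    """Apply the profile quality filters to one SGB's distance set.

    Samples with fewer than ``min_markers`` markers are dropped (a sample
    with exactly 20 markers is retained: the boundary is inclusive). When a
    boolean sample × marker presence table is supplied, markers present in
    at least half of the retained samples are kept and the per-sample
    counts recomputed on the retained markers before the sample filter is
    re-applied. Returns the filtered set and a flag: False when fewer than
    2 samples remain (the SGB is not usable for pair labeling).
    """
    counts = dict(marker_counts or dset.marker_counts)
    if marker_presence is not None:
        pres = marker_presence.loc[
            [s for s in dset.sample_ids if s in marker_presence.index]
        ].astype(bool)
        keep_samples = pres.sum(axis=1) >= min_markers
        pres = pres.loc[keep_samples]
        if len(pres):
            prevalence = pres.mean(axis=0)
            pres = pres.loc[:, prevalence >= min_marker_prevalence]
        counts = pres.sum(axis=1).to_dict()
    keep = [s for s in dset.sample_ids if counts.get(s, 0) >= min_markers]
    filtered = dset.subset(keep)
    return filtered, len(filtered.sample_ids) >= 2


# ---------------------------------------------------------------------------
# Pair labeling
# ---------------------------------------------------------------------------


def label_pairs(triads: TriadTable, dset: DistanceSet) -> PairLabeling:
    """Label every distance in the set as a related or an unrelated pair.

    Related pairs: (pre, post) of the same subject and (donor, post) of the
    same triad. Everything else between samples of *different* subjects —
    including the within-triad donor–pre pair, which shares no
    transplantation link — is unrelated. Pairs whose samples belong to the
    same subject but are not a pre/post pair do not arise from a valid
    triad table. Triads referencing a sample absent from the distance set
    contribute only the pairs whose samples are both present.
    """
    present = set(dset.sample_ids)
    related: set[frozenset] = set()
    incomplete = 0
    for t in triads.triads():
        if {t.pre_sample, t.post_sample} <= present:
            related.add(frozenset((t.pre_sample, t.post_sample)))
        if {t.donor_sample, t.post_sample} <= present:
            related.add(frozenset((t.donor_sample, t.post_sample)))
        if set(t.sample_ids) - present:
            incomplete += 1
    if incomplete:
        # absence of a profile in some triad samples is expected biology;
        # pairs involving them are simply omitted
        log.debug(
            "SGB %s: %d triad(s) not fully profiled; their missing pairs skipped",
            dset.sgb_id,
            incomplete,
        )
    known = {r.sample_id: r.subject_id for r in triads.records}
    rows = []
    ids = [s for s in dset.sample_ids if s in known]
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            key = frozenset((a, b))
            if key in related:
                label = "related"
            elif known[a] != known[b]:
                label = "unrelated"
            else:
                continue  # same-subject pair that is not a pre/post pair
            rows.append((a, b, label, dset.distance(a, b)))
    pairs = pd.DataFrame(rows, columns=["sample_a", "sample_b", "label", "distance"])
    return PairLabeling(sgb_id=dset.sgb_id, pairs=pairs)


# ---------------------------------------------------------------------------
# Threshold estimation
# ---------------------------------------------------------------------------


def youden_threshold(
    related: np.ndarray, unrelated: np.ndarray
) -> tuple[float, float]:
    """Youden-optimal threshold for the rule "related ⇔ distance ≤ t".

    J(t) = sensitivity(t) + specificity(t) − 1 with related pairs as the
    positive class. Candidates are the observed distances (the sharing
    boundary is inclusive, so J only changes at observed values); ties in
    J are broken toward the smallest threshold. Returns (t, J).
    """
    related = np.asarray(related, dtype=float)
    unrelated = np.asarray(unrelated, dtype=float)
    if related.size == 0 or unrelated.size == 0:
        raise NotEstimableError("Youden needs both related and unrelated pairs")
    candidates = np.unique(np.concatenate([related, unrelated]))
    rel_sorted = np.sort(related)
    unr_sorted = np.sort(unrelated)
    sens = np.searchsorted(rel_sorted, candidates, side="right") / related.size
    fpr = np.searchsorted(unr_sorted, candidates, side="right") / unrelated.size
    j = sens - fpr
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximizer
    return float(candidates[best]), float(j[best])


def estimate_threshold(
    labeling: PairLabeling,
    min_related: int = MIN_RELATED_DEFAULT,
    passed_filters: bool = True,
) -> ThresholdEntry:
    """Estimate the strain-identity threshold for one SGB.

    With ≥ ``min_related`` related pairs: the smaller (more conservative)
    of the Youden threshold and the 5th percentile of the unrelated
    distances. Otherwise: the 3rd percentile of the unrelated distances.
    Percentiles use linear interpolation between order statistics. SGBs
    with no unrelated pairs are flagged not estimable.
    """
    related = labeling.related
    unrelated = labeling.unrelated
    n_rel, n_unr = related.size, unrelated.size
    if n_unr == 0:
        return ThresholdEntry(
            sgb_id=labeling.sgb_id,
            threshold=float("nan"),
            rule="none",
            n_related=n_rel,
            n_unrelated=0,
            passed_filters=passed_filters,
            estimable=False,
        )
    if n_rel >= min_related:
        t_youden, j = youden_threshold(related, unrelated)
        t_pct5 = float(np.percentile(unrelated, 5))
        if t_youden <= t_pct5:
            t, rule = t_youden, "youden"
        else:
            t, rule = t_pct5, "pct5"
    else:
        t, rule, j = float(np.percentile(unrelated, 3)), "pct3", float("nan")
    return ThresholdEntry(
        sgb_id=labeling.sgb_id,
        threshold=t,
        rule=rule,
        n_related=n_rel,
        n_unrelated=n_unr,
        passed_filters=passed_filters,
        estimable=True,
        youden_j=j,
    )


def thresholds_to_frame(entries: Iterable[ThresholdEntry]) -> pd.DataFrame:
    return pd.DataFrame([e.to_row() for e in entries])


# ---------------------------------------------------------------------------
# Sharing and origin
# ---------------------------------------------------------------------------


def call_sharing(d: float, t: float) -> bool:
    """Two samples share a strain iff their distance is ≤ t (inclusive)."""
    return bool(d <= t)


def assign_origin(
    triad: Triad, dset: DistanceSet, threshold: float
) -> OriginCall:
    """Assign the origin of the strain in a triad's post-FMT sample.

    Shared only with the donor → donor (or novel_donor when the SGB was
    absent pre-FMT, the niche-filling pattern); shared only with the
    pre-FMT sample → recipient; shared with both → the side with the
    lower distance (a tie goes to the recipient); shared with neither →
    retained_unshared, flagged de novo when the SGB was present in
    neither the donor nor the pre-FMT sample.
    """
    post = triad.post_sample
    if post not in dset:
        return OriginCall(
            sgb_id=dset.sgb_id,
            post_sample=post,
            subject_id=triad.subject_id,
            origin="absent",
            d_pre=None,
            d_donor=None,
            shared_with_pre=False,
            shared_with_donor=False,
        )
    pre_present = triad.pre_sample in dset
    donor_present = triad.donor_sample in dset
    d_pre = dset.distance(triad.pre_sample, post) if pre_present else None
    d_donor = dset.distance(triad.donor_sample, post) if donor_present else None
    shared_pre = pre_present and call_sharing(d_pre, threshold)
    shared_donor = donor_present and call_sharing(d_donor, threshold)

    if shared_pre and shared_donor:
        origin: Origin = "donor" if d_donor < d_pre else "recipient"
    elif shared_donor:
        origin = "novel_donor" if not pre_present else "donor"
    elif shared_pre:
        origin = "recipient"
    else:
        origin = "retained_unshared"
    return OriginCall(
        sgb_id=dset.sgb_id,
        post_sample=post,
        subject_id=triad.subject_id,
        origin=origin,
        d_pre=d_pre,
        d_donor=d_donor,
        shared_with_pre=bool(shared_pre),
        shared_with_donor=bool(shared_donor),
        de_novo=not pre_present and not donor_present,
    )


def build_engraftment_matrix(
    calls: Iterable[OriginCall],
    sgb_ids: Iterable[str] | None = None,
    subjects: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Binary SGB × recipient matrix: 1 ⇔ origin ∈ {donor, novel_donor}."""
    calls = list(calls)
    sgbs = list(sgb_ids) if sgb_ids is not None else sorted({c.sgb_id for c in calls})
    subj = (
        list(subjects) if subjects is not None else sorted({c.subject_id for c in calls})
    )
    matrix = pd.DataFrame(0, index=pd.Index(sgbs, name="sgb_id"),
                          columns=pd.Index(subj, name="subject_id"), dtype=int)
    for c in calls:
        if c.origin in ("donor", "novel_donor"):
            matrix.at[c.sgb_id, c.subject_id] = 1
    return matrix


def origin_calls_to_frame(calls: Iterable[OriginCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sgb_id": c.sgb_id,
                "post_sample": c.post_sample,
                "subject_id": c.subject_id,
                "origin": c.origin,
                "d_pre": np.nan if c.d_pre is None else c.d_pre,
                "d_donor": np.nan if c.d_donor is None else c.d_donor,
                "shared_with_pre": c.shared_with_pre,
                "shared_with_donor": c.shared_with_donor,
                "de_novo": c.de_novo,
            }
            for c in calls
        ]
    )


def call_cohort(
    triads: TriadTable,
    dsets: Iterable[DistanceSet],
    min_related: int = MIN_RELATED_DEFAULT,
    min_markers: int = 20,
) -> tuple[pd.DataFrame, list[OriginCall], dict[str, ThresholdEntry]]:
    """Filter, label, estimate thresholds and call origins for a whole cohort.

    Returns the threshold table (one row per SGB), all origin calls, and
    the threshold entries keyed by SGB.
    """
    entries: dict[str, ThresholdEntry] = {}
    all_calls: list[OriginCall] = []
    for dset in dsets:
        filtered, usable = filter_profiles(dset, min_markers=min_markers)
        if not usable:
            entries[dset.sgb_id] = ThresholdEntry(
                sgb_id=dset.sgb_id,
                threshold=float("nan"),
                rule="none",
                n_related=0,
                n_unrelated=0,
                passed_filters=False,
                estimable=False,
            )
            continue
        labeling = label_pairs(triads, filtered)
        entry = estimate_threshold(labeling, min_related=min_related)
        entries[dset.sgb_id] = entry
        if not entry.estimable:
            continue
        for triad in triads.triads():
            all_calls.append(assign_origin(triad, filtered, entry.threshold))
    return thresholds_to_frame(entries.values()), all_calls, entries
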