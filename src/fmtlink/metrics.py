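"""Cohort-level sharing statistics, dissimilarity regression,
engraftment-pattern classification and strain-sharing network export.

The strain-sharing rate between two samples is the number of shared
strains divided by the number of SGBs strain-profiled in *both* samples.
The post-FMT anchored fractions divide instead by the number of strains
profiled in the post-FMT sample, so the donor fraction and the pre
fraction of the same sample can sum to more than 1 (a strain shared with
both counts in each numerator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import IntegrityError, NotEstimableError
from .io import DistanceSet, Triad, TriadTable
from .strain_calling import ThresholdEntry, call_sharing


@dataclass
class SharingResult:
    """Strain sharing between one pair of samples."""

    sample_a: str
    sample_b: str
    n_shared: int
    n_common_species: int

    @property
    def rate(self) -> float:
        if self.n_common_species == 0:
            return float("nan")
        return self.n_shared / self.n_common_species


@dataclass
class DissimilarityModelResult:
    """OLS fit of strain dissimilarity on sample type and donor identity."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    nobs: int
    model: Literal["interaction", "main_effects"]

    @property
    def beta_donor_post(self) -> float:
        return float(self.params["donor:post"])


@dataclass
class PatternCall:
    """Engraftment pattern of one (SGB, recipient) cell."""

    sgb_id: str
    subject_id: str
    pattern: Literal["novel", "replacement", "expansion", "missing", "not_engrafted"]
    abundance_pre: float
    abundance_post: float


def _shared_over(
    a: str,
    b: str,
    dsets: Iterable[DistanceSet],
    thresholds: Mapping[str, ThresholdEntry],
) -> tuple[int, int]:
    n_shared = n_common = 0
    for dset in dsets:
        entry = thresholds.get(dset.sgb_id)
        if entry is None or not entry.estimable:
            continue
        if a in dset and b in dset:
            n_common += 1
            if call_sharing(dset.distance(a, b), entry.threshold):
                n_shared += 1
    return n_shared, n_common


def sharing_rate(
    a: str,
    b: str,
    dsets: Iterable[DistanceSet],
    thresholds: Mapping[str, ThresholdEntry],
) -> SharingResult:
    """Strain-sharing rate over the SGBs profiled in both samples."""
    n_shared, n_common = _shared_over(a, b, dsets, thresholds)
    return SharingResult(a, b, n_shared, n_common)


def post_fractions(
    triad: Triad,
    dsets: Iterable[DistanceSet],
    thresholds: Mapping[str, ThresholdEntry],
) -> tuple[float, float]:
    """(f_donor, f_pre): fractions of post-FMT strains shared with the donor
    and with the recipient's own pre-FMT sample.

    Both denominators are the number of strains profiled in the post-FMT
    sample; the two fractions may therefore sum to more than 1.
    """
    n_post = n_donor = n_pre = 0
    for dset in dsets:
        entry = thresholds.get(dset.sgb_id)
        if entry is None or not entry.estimable or triad.post_sample not in dset:
            continue
        n_post += 1
        if triad.donor_sample in dset and call_sharing(
            dset.distance(triad.donor_sample, triad.post_sample), entry.threshold
        ):
            n_donor += 1
        if triad.pre_sample in dset and call_sharing(
            dset.distance(triad.pre_sample, triad.post_sample), entry.threshold
        ):
            n_pre += 1
    if n_post == 0:
        return float("nan"), float("nan")
    return n_donor / n_post, n_pre / n_post


# ---------------------------------------------------------------------------
# Dissimilarity regression
# ---------------------------------------------------------------------------


def build_dissimilarity_pairs(
    triads: TriadTable,
    dsets: Iterable[DistanceSet],
    thresholds: Mapping[str, ThresholdEntry],
    substudy: str | None = None,
) -> pd.DataFrame:
    """Recipient-sample × donor-sample pairs with strain dissimilarity.

    Dissimilarity D = 1 − n_shared / n_common, where n_common counts the
    SGBs strain-profiled in both samples (the maximum number of strains
    the pair could share). ``post`` flags post-FMT recipient samples and
    ``donor`` flags pairs where the donor sample is the recipient's true
    donor. Restricted to one sub-study when requested (the default pair
    universe of the cohort-level model).
    """
    dsets = list(dsets)
    trs = [t for t in triads.triads() if substudy is None or t.substudy == substudy]
    donor_samples = sorted({t.donor_sample for t in trs})
    rows = []
    for t in trs:
        for recip_sample, is_post in ((t.pre_sample, 0), (t.post_sample, 1)):
            for donor_sample in donor_samples:
                n_shared, n_common = _shared_over(
                    recip_sample, donor_sample, dsets, thresholds
                )
                if n_common == 0:
                    continue
                rows.append(
                    {
                        "recipient_sample": recip_sample,
                        "donor_sample": donor_sample,
                        "subject_id": t.subject_id,
                        "substudy": t.substudy,
                        "post": is_post,
                        "donor": int(donor_sample == t.donor_sample),
                        "dissimilarity": 1.0 - n_shared / n_common,
                    }
                )
    return pd.DataFrame(rows)


def fit_dissimilarity_model(
    pairs: pd.DataFrame, interaction: bool = True
) -> DissimilarityModelResult:
    """OLS of dissimilarity on sample type and true-donor status.

    With ``interaction`` (the default) the model includes the donor×post
    term whose coefficient measures how much closer post-FMT samples are
    to their own donor than expected from the main effects.
    """
    y = pairs["dissimilarity"].to_numpy(dtype=float)
    X = pd.DataFrame(
        {
            "post": pairs["post"].to_numpy(dtype=float),
            "donor": pairs["donor"].to_numpy(dtype=float),
        }
    )
    if interaction:
        X["donor:post"] = X["post"] * X["donor"]
    X = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the aliased column for the caller
        for col in X.columns[1:]:
            reduced = X.drop(columns=[col])
            if np.linalg.matrix_rank(reduced.to_numpy()) == rank:
                raise IntegrityError(
                    f"dissimilarity design is rank deficient: column {col!r} aliased"
                )
        raise IntegrityError("dissimilarity design is rank deficient")
    fit = sm.OLS(y, X).fit()
    return DissimilarityModelResult(
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        nobs=int(fit.nobs),
        model="interaction" if interaction else "main_effects",
    )


# ---------------------------------------------------------------------------
# Engraftment patterns
# ---------------------------------------------------------------------------


def compare_abundance(
    pre: np.ndarray, post: np.ndarray
) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test of pre vs post abundance.

    Used for the niche question: does an engrafted strain occupy a larger
    niche after the intervention than the native strain did before?
    Requires at least 3 pairs; the exact null distribution is used at
    small n (scipy's default for n ≤ 25 without ties).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size:
        raise ValueError("pre and post must be paired")
    if pre.size < 3:
        raise NotEstimableError("fewer than 3 pairs")
    if np.allclose(pre, post):
        return 0.0, 1.0
    res = stats.wilcoxon(post, pre, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def classify_pattern(
    sgb_id: str,
    subject_id: str,
    engraftment: pd.DataFrame,
    abundance_pre: Mapping[str, float],
    abundance_post: Mapping[str, float],
    alpha: float = 0.05,
    presence_tol: float = 0.0,
) -> PatternCall:
    """Classify the engraftment pattern of one (SGB, recipient) cell.

    novel — the SGB engrafted into a recipient with no native strain
    (pre-FMT abundance at or below ``presence_tol``); expansion — engrafted
    with a cohort-level significant abundance increase among engrafted
    recipients; replacement — engrafted without such an increase (strain
    turnover in a fixed niche). ``abundance_pre``/``abundance_post`` map
    recipient subjects to this SGB's relative abundance.
    """
    if engraftment.at[sgb_id, subject_id] != 1:
        a_pre = abundance_pre.get(subject_id, float("nan"))
        a_post = abundance_post.get(subject_id, float("nan"))
        return PatternCall(sgb_id, subject_id, "not_engrafted", a_pre, a_post)
    a_pre = abundance_pre.get(subject_id)
    a_post = abundance_post.get(subject_id)
    if a_pre is None or a_post is None or np.isnan(a_pre) or np.isnan(a_post):
        return PatternCall(sgb_id, subject_id, "missing", float("nan"), float("nan"))
    if a_pre <= presence_tol:
        return PatternCall(sgb_id, subject_id, "novel", a_pre, a_post)
    engrafted = [
        s
        for s in engraftment.columns
        if engraftment.at[sgb_id, s] == 1
        and s in abundance_pre
        and s in abundance_post
        and not (np.isnan(abundance_pre[s]) or np.isnan(abundance_post[s]))
        and abundance_pre[s] > presence_tol
    ]
    pattern = "replacement"
    if len(engrafted) >= 3:
        pre = np.array([abundance_pre[s] for s in engrafted])
        post = np.array([abundance_post[s] for s in engrafted])
        try:
            _, p = compare_abundance(pre, post)
        except NotEstimableError:
            p = 1.0
        if p <= alpha and np.median(post - pre) > 0:
            pattern = "expansion"
    return PatternCall(sgb_id, subject_id, pattern, float(a_pre), float(a_post))


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------


def export_network(
    sharing: Iterable[SharingResult],
    roles: Mapping[str, str],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strain-sharing network with a deterministic force-directed layout.

    Nodes are samples (attributed with their triad role); edges connect
    pairs sharing at least one strain, weighted by the *squared* number of
    shared strains. Coordinates come from the Fruchterman–Reingold layout
    with a fixed seed. Returns (nodes, edges) tables.
    """
    G = nx.Graph()
    for s in roles:
        G.add_node(s, role=roles[s])
    for res in sharing:
        if res.n_shared > 0:
            G.add_edge(
                res.sample_a,
                res.sample_b,
                weight=float(res.n_shared) ** 2,
                n_shared=res.n_shared,
            )
    if len(G) == 0:
        return (
            pd.DataFrame(columns=["sample_id", "role", "x", "y"]),
            pd.DataFrame(columns=["sample_a", "sample_b", "n_shared", "weight"]),
        )
    pos = nx.spring_layout(G, seed=seed, weight="weight")
    nodes = pd.DataFrame(
        [
            {"sample_id": n, "role": G.nodes[n].get("role", ""),
             "x": float(pos[n][0]), "y": float(pos[n][1])}
            for n in sorted(G.nodes)
        ]
    )
    edges = pd.DataFrame(
        [
            {
                "sample_a": a,
                "sample_b": b,
                "n_shared": G.edges[a, b]["n_shared"],
                "weight": G.edges[a, b]["weight"],
            }
            for a, b in sorted(G.edges)
        ],
        columns=["sample_a", "sample_b", "n_shared", "weight"],
    )
    return nodes, edges
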