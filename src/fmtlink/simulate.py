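"""Synthetic FMT cohorts with known ground truth.

The generator emulates the structure of a multi-sub-study FMT trial in
metabolic syndrome: ~29 donor/pre/post triads across 3 sub-studies with
donors shared between recipients, per-SGB bimodal distance distributions
(a tight same-strain mode well below a broad different-strain mode), a
block of recipients with missing diastolic blood pressure, and planted
engraftment → metabolite → clinical effects. Every downstream stage of the
pipeline can therefore be tested against the planted truth without any
external data.

Distances are drawn from normal distributions truncated at 0; downstream
methods only consume the ordering and quantiles of these values, so the
parametric family is deliberately simple. Randomness is driven by
deterministic sub-streams derived from ``SimConfig.seed`` (one stream per
SGB plus dedicated streams for the cohort layout, clinical values and
metabolites), so adding SGBs does not reshuffle earlier draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as flio
from .errors import ConfigError

SUBSTUDIES = ("Appetite", "Fatmed", "Febaligo")

#: Clinical parameters generated by default: (name, units, baseline mean,
#: baseline SD, post-pre noise SD). Baselines reflect a MetSyn population.
DEFAULT_CLINICAL = (
    ("diastolic_bp", "mmHg", 88.0, 8.0, 4.0),
    ("systolic_bp", "mmHg", 136.0, 12.0, 6.0),
    ("rate_glucose_disappearance", "mg/kg/min", 3.5, 1.0, 0.5),
    ("fasting_glucose", "mmol/L", 6.2, 0.8, 0.4),
    ("hdl_cholesterol", "mmol/L", 1.0, 0.2, 0.1),
    ("triglycerides", "mmol/L", 2.1, 0.6, 0.3),
)

#: Named metabolites always present in the panel (arginine-pathway
#: intermediates and a heme intermediate, the candidate mediators).
NAMED_METABOLITES = ("2-oxoarginine", "4-guanidinobutanoate", "biliverdin")


@dataclass(frozen=True)
class EffectSpec:
    """A planted effect: engraftment of ``sgb_id`` shifts ``target`` by ``delta``.

    ``target`` names either a clinical parameter or a metabolite; the delta
    is added to the post value of every recipient in which the SGB engrafts.
    """

    sgb_id: str
    target: str
    delta: float


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions the pipeline is designed for:
    29 triads over 3 sub-studies, shared donors, 50 strain-profiled SGBs,
    a same-strain distance mode at 0.01 against a different-strain mode at
    0.30, ~35% per-SGB engraftment probability, 10 recipients of the
    second sub-study with missing diastolic blood pressure, and a planted
    chain in which engraftment of SGB0001 lowers diastolic blood pressure
    by 16 mmHg and the plasma level of 2-oxoarginine.
    """

    n_triads: int = 29
    n_substudies: int = 3
    n_sgb: int = 50
    n_donors: int = 12
    same_strain_dist: tuple[float, float] = (0.01, 0.005)
    diff_strain_dist: tuple[float, float] = (0.30, 0.10)
    engraft_prob: float | dict[str, float] = 0.35
    donor_presence_prob: float = 0.9
    pre_presence_prob: float = 0.8
    effect_map: list[EffectSpec] = field(
        default_factory=lambda: [
            EffectSpec("SGB0001", "diastolic_bp", -16.0),
            EffectSpec("SGB0001", "2-oxoarginine", -0.4),
            EffectSpec("SGB0002", "4-guanidinobutanoate", -0.3),
        ]
    )
    missing_dbp_subjects: int = 10
    n_metabolites: int = 40
    metabolite_missing_frac: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        mu_s, _ = self.same_strain_dist
        mu_d, _ = self.diff_strain_dist
        if not mu_s < mu_d:
            raise ConfigError("same-strain mean must be below different-strain mean")
        probs = (
            self.engraft_prob.values()
            if isinstance(self.engraft_prob, dict)
            else [self.engraft_prob]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("engraftment probabilities must lie in [0, 1]")
        if self.n_triads < 1 or self.n_sgb < 1 or self.n_donors < 1:
            raise ConfigError("cohort sizes must be positive")
        if not 1 <= self.n_substudies <= len(SUBSTUDIES):
            raise ConfigError(
                f"n_substudies must be in [1, {len(SUBSTUDIES)}]"
            )

    @property
    def sgb_ids(self) -> list[str]:
        return [f"SGB{i + 1:04d}" for i in range(self.n_sgb)]

    def engraft_prob_of(self, sgb_id: str) -> float:
        if isinstance(self.engraft_prob, dict):
            return self.engraft_prob.get(sgb_id, 0.0)
        return self.engraft_prob

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_map"] = [dataclasses.asdict(e) for e in self.effect_map]
        return d


@dataclass
class GroundTruth:
    """Planted truth of a simulated cohort.

    ``engraftment``: binary SGB × recipient-subject matrix. ``origins``:
    the origin label each (SGB, post sample) should receive under perfect
    strain calling. ``effects``: the planted effect sizes.
    """

    engraftment: pd.DataFrame
    origins: pd.DataFrame
    effects: list[EffectSpec]


@dataclass
class CohortBundle:
    """Everything `simulate_cohort` produces, ready for the pipeline."""

    config: SimConfig
    triads: flio.TriadTable
    distance_sets: list[flio.DistanceSet]
    abundance: pd.DataFrame
    clinical: pd.DataFrame
    metabolites: pd.DataFrame
    ground_truth: GroundTruth


def _rng(seed: int, domain: int, index: int = 0) -> np.random.Generator:
    """Deterministic sub-stream: one per (domain, index)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(domain, index))
    )


def _trunc_normal(
    rng: np.random.Generator, mu: float, sd: float, size: int
) -> np.ndarray:
    """Normal(mu, sd) truncated at 0. sd = 0 degenerates to the constant mu."""
    if sd <= 0:
        return np.full(size, max(mu, 0.0))
    a = (0.0 - mu) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=size, random_state=rng)


def _layout(cfg: SimConfig) -> tuple[flio.TriadTable, list[str], pd.DataFrame]:
    """Build the triad table: recipients round-robin over sub-studies and donors."""
    substudies = list(SUBSTUDIES[: cfg.n_substudies])
    records = []
    donor_ids = [f"D{i + 1:02d}" for i in range(cfg.n_donors)]
    for d in donor_ids:
        records.append(
            flio.SampleRecord(f"{d}_don", d, "donor", substudies[0], "")
        )
    rows = []
    for i in range(cfg.n_triads):
        subject = f"S{i + 1:02d}"
        substudy = substudies[i % len(substudies)]
        donor = donor_ids[i % len(donor_ids)]
        for role in ("pre", "post"):
            records.append(
                flio.SampleRecord(f"{subject}_{role}", subject, role, substudy, donor)
            )
        rows.append((subject, substudy, donor))
    frame = pd.DataFrame(rows, columns=["subject_id", "substudy", "donor_id"])
    return flio.TriadTable(records), donor_ids, frame


def _simulate_sgb(
    cfg: SimConfig, sgb_index: int, triads: list[flio.Triad]
) -> tuple[flio.DistanceSet, pd.Series, pd.DataFrame]:
    """Distance set, engraftment vector and presence table for one SGB."""
    sgb_id = cfg.sgb_ids[sgb_index]
    rng = _rng(cfg.seed, 1, sgb_index)
    p_eng = cfg.engraft_prob_of(sgb_id)
    mu_s, sd_s = cfg.same_strain_dist
    mu_d, sd_d = cfg.diff_strain_dist

    donor_samples = sorted({t.donor_sample for t in triads})
    donor_present = {
        s: bool(rng.random() < cfg.donor_presence_prob) for s in donor_samples
    }

    present: list[str] = [s for s in donor_samples if donor_present[s]]
    engrafted: dict[str, bool] = {}
    relation: dict[frozenset, str] = {}  # pair -> "same" | "diff"
    origin_rows = []
    for t in triads:
        pre_present = bool(rng.random() < cfg.pre_presence_prob)
        can_engraft = donor_present[t.donor_sample]
        eng = bool(can_engraft and rng.random() < p_eng)
        post_present = eng or pre_present
        engrafted[t.subject_id] = eng
        if pre_present:
            present.append(t.pre_sample)
        if post_present:
            present.append(t.post_sample)
        if post_present:
            if eng:
                origin = "novel_donor" if not pre_present else "donor"
            else:
                origin = "recipient"
        else:
            origin = "absent"
        origin_rows.append((sgb_id, t.subject_id, t.post_sample, origin))
        # related-pair relations; everything not set is a different strain
        if post_present and pre_present:
            relation[frozenset((t.pre_sample, t.post_sample))] = (
                "diff" if eng else "same"
            )
        if post_present and donor_present[t.donor_sample]:
            relation[frozenset((t.donor_sample, t.post_sample))] = (
                "same" if eng else "diff"
            )

    n = len(present)
    iu, ju = np.triu_indices(n, k=1)
    same = np.array(
        [
            relation.get(frozenset((present[i], present[j])), "diff") == "same"
            for i, j in zip(iu, ju)
        ],
        dtype=bool,
    )
    dists = np.empty(same.size)
    dists[same] = _trunc_normal(rng, mu_s, sd_s, int(same.sum()))
    dists[~same] = _trunc_normal(rng, mu_d, sd_d, int((~same).sum()))
    D = np.zeros((n, n))
    D[iu, ju] = dists
    D[ju, iu] = dists
    marker_counts = {s: int(rng.integers(25, 151)) for s in present}
    dset = flio.DistanceSet(
        sgb_id=sgb_id, sample_ids=present, D=D, marker_counts=marker_counts
    )
    eng_series = pd.Series(
        {t.subject_id: int(engrafted[t.subject_id]) for t in triads},
        name=sgb_id,
    )
    origins = pd.DataFrame(
        origin_rows, columns=["sgb_id", "subject_id", "post_sample", "origin"]
    )
    return dset, eng_series, origins


def _simulate_abundance(
    cfg: SimConfig,
    triads: list[flio.Triad],
    dsets: list[flio.DistanceSet],
    origins: pd.DataFrame,
) -> pd.DataFrame:
    """Relative abundances consistent with presence/absence and origins.

    Post-FMT abundances track the pre-FMT value for retained or replaced
    strains (replacement happens in a fixed niche); novel engraftment gets
    a fresh draw (a previously unoccupied niche being filled).
    """
    rng = _rng(cfg.seed, 2)
    sgb_ids = [d.sgb_id for d in dsets]
    samples = sorted({s for d in dsets for s in d.sample_ids})
    weights = pd.DataFrame(0.0, index=samples, columns=sgb_ids)
    novel = {
        (r.sgb_id, r.post_sample)
        for r in origins.itertuples()
        if r.origin == "novel_donor"
    }
    pre_of = {t.post_sample: t.pre_sample for t in triads}
    for d in dsets:
        for s in d.sample_ids:
            base = pre_of.get(s)
            if (
                base is not None
                and base in d.sample_ids
                and (d.sgb_id, s) not in novel
            ):
                w = weights.at[base, d.sgb_id] * float(
                    np.exp(rng.normal(0.0, 0.1))
                )
            else:
                w = float(rng.gamma(1.2, 1.0))
            weights.at[s, d.sgb_id] = w
    sums = weights.sum(axis=1)
    sums[sums == 0] = 1.0
    return weights.div(sums, axis=0) * 0.85


def _simulate_clinical(
    cfg: SimConfig,
    layout: pd.DataFrame,
    engraftment: pd.DataFrame,
) -> pd.DataFrame:
    rng = _rng(cfg.seed, 3)
    params = {name: (units, mu, sd, noise) for name, units, mu, sd, noise in DEFAULT_CLINICAL}
    rows = []
    fatmed = [
        r.subject_id for r in layout.itertuples() if r.substudy == "Fatmed"
    ]
    missing_dbp = set(fatmed[: cfg.missing_dbp_subjects])
    if cfg.missing_dbp_subjects > len(fatmed):
        missing_dbp |= set(
            s for s in layout.subject_id if s not in fatmed
        )  # pragma: no cover - only with non-default layouts
    for r in layout.itertuples():
        subject = r.subject_id
        for name, (units, mu, sd, noise) in params.items():
            pre = float(rng.normal(mu, sd))
            delta = sum(
                e.delta
                for e in cfg.effect_map
                if e.target == name and engraftment.at[e.sgb_id, subject] == 1
            )
            post = pre + delta + float(rng.normal(0.0, noise))
            if name == "diastolic_bp" and subject in missing_dbp:
                pre = post = np.nan
            rows.append((subject, name, "pre", pre, units))
            rows.append((subject, name, "post", post, units))
    return flio.validate_clinical(
        pd.DataFrame(
            rows, columns=["subject_id", "parameter", "time", "value", "units"]
        )
    )


def _simulate_metabolites(
    cfg: SimConfig,
    layout: pd.DataFrame,
    engraftment: pd.DataFrame,
) -> pd.DataFrame:
    rng = _rng(cfg.seed, 4)
    names = list(NAMED_METABOLITES) + [
        f"met_{i + 1:04d}" for i in range(max(cfg.n_metabolites - len(NAMED_METABOLITES), 0))
    ]
    subjects = list(layout.subject_id)
    index = pd.MultiIndex.from_product(
        [subjects, ["pre", "post"]], names=["subject_id", "time"]
    )
    data = {}
    for name in names:
        pre = rng.lognormal(0.0, 0.4, size=len(subjects))
        noise = rng.normal(0.0, 0.15, size=len(subjects))
        delta = np.zeros(len(subjects))
        for e in cfg.effect_map:
            if e.target == name:
                eng = engraftment.loc[e.sgb_id, subjects].to_numpy()
                delta = delta + e.delta * eng
        post = np.maximum(pre + delta + noise, 0.0)
        col = np.empty(2 * len(subjects))
        col[0::2] = pre
        col[1::2] = post
        data[name] = col
    df = pd.DataFrame(data, index=index)
    # censor low intensities to missing (below detection limit)
    if cfg.metabolite_missing_frac > 0:
        for name in names:
            cut = np.quantile(df[name], cfg.metabolite_missing_frac)
            df.loc[df[name] <= cut, name] = np.nan
    return df


def _validate_effects(cfg: SimConfig) -> None:
    clinical = {name for name, *_ in DEFAULT_CLINICAL}
    metabolites = set(NAMED_METABOLITES) | {
        f"met_{i + 1:04d}" for i in range(cfg.n_metabolites)
    }
    for e in cfg.effect_map:
        if e.sgb_id not in set(cfg.sgb_ids):
            raise ConfigError(f"effect_map names unknown SGB {e.sgb_id!r}")
        if e.target not in clinical | metabolites:
            raise ConfigError(f"effect_map names unknown target {e.target!r}")


def simulate_cohort(cfg: SimConfig) -> CohortBundle:
    """Generate a full synthetic cohort with planted ground truth."""
    _validate_effects(cfg)
    table, _, layout = _layout(cfg)
    triads = table.triads()

    dsets, eng_cols, origin_frames = [], [], []
    for k in range(cfg.n_sgb):
        dset, eng, origins = _simulate_sgb(cfg, k, triads)
        dsets.append(dset)
        eng_cols.append(eng)
        origin_frames.append(origins)
    engraftment = pd.DataFrame(eng_cols)
    engraftment.index.name = "sgb_id"
    engraftment.columns.name = "subject_id"
    origins = pd.concat(origin_frames, ignore_index=True)

    abundance = _simulate_abundance(cfg, triads, dsets, origins)
    clinical = _simulate_clinical(cfg, layout, engraftment)
    metabolites = _simulate_metabolites(cfg, layout, engraftment)
    truth = GroundTruth(
        engraftment=engraftment, origins=origins, effects=list(cfg.effect_map)
    )
    return CohortBundle(
        config=cfg,
        triads=table,
        distance_sets=dsets,
        abundance=abundance,
        clinical=clinical,
        metabolites=metabolites,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# Fixture writing / reading
# ---------------------------------------------------------------------------


def write_fixture(bundle: CohortBundle, out_dir: str | Path) -> dict:
    """Write all tables of a bundle in the standard formats; return the manifest."""
    out = Path(out_dir)
    (out / "distances").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    flio.write_triad_table(bundle.triads, out / "triads.tsv")
    marker_rows = []
    for dset in bundle.distance_sets:
        flio.write_distances(dset, out / "distances" / f"{dset.sgb_id}.tsv")
        for s, m in dset.marker_counts.items():
            marker_rows.append((dset.sgb_id, s, m))
    flio.write_marker_counts(
        pd.DataFrame(marker_rows, columns=["sgb_id", "sample_id", "n_markers"]),
        out / "marker_counts.tsv",
    )
    flio.write_abundance(bundle.abundance, out / "abundance.tsv")
    flio.write_clinical(bundle.clinical, out / "clinical.tsv")
    flio.write_metabolites(bundle.metabolites, out / "metabolites.tsv")
    bundle.ground_truth.engraftment.to_csv(out / "truth" / "engraftment.tsv", sep="\t")
    bundle.ground_truth.origins.to_csv(
        out / "truth" / "origins.tsv", sep="\t", index=False
    )
    manifest = {
        "config": bundle.config.to_dict(),
        "seed": bundle.config.seed,
        "n_triads": len(bundle.triads.triads()),
        "n_sgb": len(bundle.distance_sets),
        "files": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
            if p.name != "manifest.json"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def checksum_tree(out_dir: str | Path) -> str:
    """SHA-256 over all files of a fixture directory (order-independent)."""
    h = hashlib.sha256()
    for p in sorted(Path(out_dir).rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(out_dir)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()
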