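"""End-to-end orchestration: simulate → thresholds → engraft → metrics →
integrate → linkstats.

Stages communicate only through files, so any stage can be rerun in
isolation and every intermediate result can be audited. A JSON manifest
records the effective configuration, a hash of it, per-stage row counts
and the key cohort-level statistics; under a fixed seed the whole run is
deterministic and the manifest's ``stages``/``results`` sections are
byte-stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as flio
from . import metrics as flmetrics
from . import rcca as flrcca
from . import simulate as flsim
from . import stats_link as flstats
from . import strain_calling as flsc
from .errors import ConfigError, NotEstimableError

log = logging.getLogger("fmtlink")

STAGES = ("simulate", "thresholds", "engraft", "metrics", "integrate", "linkstats")


@dataclass
class RunConfig:
    """Effective parameters of one pipeline run.

    Defaults equal the documented design choices of the individual
    modules: inclusive sharing boundary, linear-interpolation percentiles,
    ≥50 related pairs for the Youden/5th-percentile rule, 21-point
    log-spaced penalty grid on [1e-4, 1], outer-ring radius 0.5, top-10
    inner-product pairs, BH FDR, 999 permutations.
    """

    out_dir: str = "fmtlink_run"
    data_dir: str | None = None  # input fixture; defaults to <out_dir>/data
    simulate: bool = True
    seed: int = 0
    stages: tuple[str, ...] = STAGES

    # strain calling
    min_markers: int = 20
    min_related: int = flsc.MIN_RELATED_DEFAULT

    # rCCA
    tune: bool = True
    grid_min: float = 1e-4
    grid_max: float = 1.0
    grid_size: int = 21
    lambda1: float = 0.1
    lambda2: float = 0.1
    r_outer: float = flrcca.R_OUTER_DEFAULT
    n_top_pairs: int = 10
    n_rcca_sgbs: int = 15
    complete_case_parameter: str = "diastolic_bp"

    # downstream stats
    n_perm: int = 999
    metabolite_panel: tuple[str, ...] = flsim.NAMED_METABOLITES
    network_seed: int = 0

    sim: flsim.SimConfig = field(default_factory=flsim.SimConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @property
    def data_path(self) -> Path:
        return Path(self.data_dir) if self.data_dir else Path(self.out_dir) / "data"

    def grid(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.grid_min), np.log10(self.grid_max), self.grid_size
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["stages"] = list(self.stages)
        d["metabolite_panel"] = list(self.metabolite_panel)
        return d


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw)
    sim_raw = dict(raw.pop("sim", {}))
    if "effect_map" in sim_raw:
        sim_raw["effect_map"] = [
            flsim.EffectSpec(**e) for e in sim_raw["effect_map"]
        ]
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**raw, sim=flsim.SimConfig(**sim_raw))
    return cfg


def load_config(path: str | Path) -> RunConfig:
    return config_from_dict(flio.read_config(path))


# ---------------------------------------------------------------------------
# Shared stage inputs
# ---------------------------------------------------------------------------


def _require(path: Path) -> Path:
    if not path.exists():
        raise ConfigError(f"required input does not exist: {path}")
    return path


def _load_distances(data: Path) -> list[flio.DistanceSet]:
    marker_path = data / "marker_counts.tsv"
    markers = (
        flio.read_marker_counts(marker_path) if marker_path.exists() else None
    )
    dsets = []
    for path in sorted(_require(data / "distances").glob("*.tsv")):
        counts = None
        if markers is not None:
            sub = markers[markers.sgb_id == path.stem]
            counts = dict(zip(sub.sample_id, sub.n_markers))
        dsets.append(
            flio.read_distances(path, mode="matrix", marker_counts=counts)
        )
    return dsets


def _load_thresholds(out: Path) -> dict[str, flsc.ThresholdEntry]:
    df = pd.read_csv(_require(out / "thresholds.tsv"), sep="\t")
    entries = {}
    for r in df.itertuples():
        entries[r.sgb_id] = flsc.ThresholdEntry(
            sgb_id=r.sgb_id,
            threshold=float(r.threshold),
            rule=r.rule,
            n_related=int(r.n_related),
            n_unrelated=int(r.n_unrelated),
            passed_filters=bool(r.passed_filters),
            estimable=bool(r.estimable),
            youden_j=float(r.youden_j),
        )
    return entries


def _filtered_dsets(cfg: RunConfig) -> tuple[flio.TriadTable, list[flio.DistanceSet]]:
    data = cfg.data_path
    triads = flio.read_triad_table(_require(data / "triads.tsv"))
    dsets = []
    for dset in _load_distances(data):
        filtered, usable = flsc.filter_profiles(dset, min_markers=cfg.min_markers)
        if usable:
            dsets.append(filtered)
    return triads, dsets


def _clinical_deltas(clinical: pd.DataFrame) -> pd.DataFrame:
    """Post − pre per (subject, parameter), wide: subjects × parameters."""
    pre = clinical[clinical.time == "pre"].pivot(
        index="subject_id", columns="parameter", values="value"
    )
    post = clinical[clinical.time == "post"].pivot(
        index="subject_id", columns="parameter", values="value"
    )
    return (post - pre).sort_index()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig) -> dict:
    bundle = flsim.simulate_cohort(cfg.sim)
    manifest = flsim.write_fixture(bundle, cfg.data_path)
    return {"rows": manifest["n_triads"], "n_sgb": manifest["n_sgb"]}


def stage_thresholds(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    triads, dsets = _filtered_dsets(cfg)
    entries = []
    for dset in dsets:
        labeling = flsc.label_pairs(triads, dset)
        entries.append(
            flsc.estimate_threshold(labeling, min_related=cfg.min_related)
        )
    table = flsc.thresholds_to_frame(entries)
    table.to_csv(out / "thresholds.tsv", sep="\t", index=False,
                 float_format=flio.FLOAT_FORMAT)
    return {"rows": len(table), "n_estimable": int(table.estimable.sum())}


def stage_engraft(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    triads, dsets = _filtered_dsets(cfg)
    thresholds = _load_thresholds(out)
    calls = []
    for dset in dsets:
        entry = thresholds.get(dset.sgb_id)
        if entry is None or not entry.estimable:
            continue
        for triad in triads.triads():
            calls.append(flsc.assign_origin(triad, dset, entry.threshold))
    flsc.origin_calls_to_frame(calls).to_csv(
        out / "origin_calls.tsv", sep="\t", index=False,
        float_format=flio.FLOAT_FORMAT,
    )
    subjects = sorted({t.subject_id for t in triads.triads()})
    matrix = flsc.build_engraftment_matrix(
        calls, sgb_ids=sorted({d.sgb_id for d in dsets}), subjects=subjects
    )
    matrix.to_csv(out / "engraftment.tsv", sep="\t")
    return {"rows": len(calls), "n_engrafted": int(matrix.to_numpy().sum())}


def stage_metrics(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    triads, dsets = _filtered_dsets(cfg)
    thresholds = _load_thresholds(out)

    sharing_rows = []
    fraction_rows = []
    for t in triads.triads():
        for a, b, kind in (
            (t.pre_sample, t.post_sample, "pre_post"),
            (t.donor_sample, t.post_sample, "donor_post"),
        ):
            res = flmetrics.sharing_rate(a, b, dsets, thresholds)
            sharing_rows.append(
                {
                    "subject_id": t.subject_id,
                    "substudy": t.substudy,
                    "pair_type": kind,
                    "sample_a": a,
                    "sample_b": b,
                    "n_shared": res.n_shared,
                    "n_common_species": res.n_common_species,
                    "sharing_rate": res.rate,
                }
            )
        f_donor, f_pre = flmetrics.post_fractions(t, dsets, thresholds)
        fraction_rows.append(
            {
                "subject_id": t.subject_id,
                "substudy": t.substudy,
                "f_donor": f_donor,
                "f_pre": f_pre,
            }
        )
    sharing = pd.DataFrame(sharing_rows)
    sharing.to_csv(out / "sharing_rates.tsv", sep="\t", index=False,
                   float_format=flio.FLOAT_FORMAT)
    fractions = pd.DataFrame(fraction_rows)
    fractions.to_csv(out / "post_fractions.tsv", sep="\t", index=False,
                     float_format=flio.FLOAT_FORMAT)

    model_rows = []
    for substudy in triads.substudies:
        trs = [t for t in triads.triads() if t.substudy == substudy]
        if not trs:
            continue
        pairs = flmetrics.build_dissimilarity_pairs(
            triads, dsets, thresholds, substudy=substudy
        )
        if pairs.empty or pairs.donor.nunique() < 2 or pairs.post.nunique() < 2:
            continue
        fit = flmetrics.fit_dissimilarity_model(pairs)
        model_rows.append(
            {
                "substudy": substudy,
                "beta_donor_post": fit.beta_donor_post,
                "p_donor_post": float(fit.pvalues["donor:post"]),
                "n_pairs": fit.nobs,
            }
        )
        roles = {r.sample_id: r.role for r in triads.records}
        samples = {s for t in trs for s in t.sample_ids}
        sharing_results = []
        sample_list = sorted(samples)
        for i, a in enumerate(sample_list):
            for b in sample_list[i + 1:]:
                sharing_results.append(
                    flmetrics.sharing_rate(a, b, dsets, thresholds)
                )
        nodes, edges = flmetrics.export_network(
            sharing_results,
            roles={s: roles[s] for s in sample_list},
            seed=cfg.network_seed,
        )
        nodes.to_csv(out / f"network_{substudy}_nodes.tsv", sep="\t",
                     index=False, float_format=flio.FLOAT_FORMAT)
        edges.to_csv(out / f"network_{substudy}_edges.tsv", sep="\t",
                     index=False, float_format=flio.FLOAT_FORMAT)
    models = pd.DataFrame(
        model_rows, columns=["substudy", "beta_donor_post", "p_donor_post", "n_pairs"]
    )
    models.to_csv(out / "dissimilarity_model.tsv", sep="\t", index=False,
                  float_format=flio.FLOAT_FORMAT)
    return {
        "rows": len(sharing),
        "beta_donor_post": [round(float(b), 12) for b in models.beta_donor_post],
    }


def _rcca_inputs(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """X = engraftment of the most-engrafting SGBs; Y = clinical deltas.

    Complete cases are defined by the configured parameter (subjects
    missing it are dropped entirely, as the integration handles complete
    cases only).
    """
    out = Path(cfg.out_dir)
    data = cfg.data_path
    engraftment = pd.read_csv(
        _require(out / "engraftment.tsv"), sep="\t", index_col=0
    )
    clinical = flio.read_clinical(_require(data / "clinical.tsv"))
    deltas = _clinical_deltas(clinical)
    rates = engraftment.mean(axis=1)
    top = rates[rates > 0].sort_values(ascending=False, kind="stable")
    keep = top.index[: cfg.n_rcca_sgbs]
    X = engraftment.loc[keep].T.sort_index()
    if cfg.complete_case_parameter in deltas.columns:
        complete = deltas[cfg.complete_case_parameter].notna()
        deltas = deltas[complete]
        X = X.loc[deltas.index]
    deltas = deltas.dropna(axis=0)
    X = X.loc[deltas.index]
    return X, deltas


def stage_integrate(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    X, Y = _rcca_inputs(cfg)
    if cfg.tune:
        l1, l2, grid_results = flrcca.tune_rcc(X, Y, cfg.grid(), cfg.grid())
        grid_results.to_csv(out / "rcca_grid.tsv", sep="\t", index=False,
                            float_format=flio.FLOAT_FORMAT)
    else:
        l1, l2 = cfg.lambda1, cfg.lambda2
    model = flrcca.fit_rcc(X, Y, l1, l2)
    coords_x, coords_y = flrcca.circle_coords(model, X, Y, r_outer=cfg.r_outer)
    pairs = flrcca.select_pairs(coords_x, coords_y, k=cfg.n_top_pairs)

    pd.DataFrame(
        model.x_loadings, index=model.x_names,
        columns=[f"comp{j+1}" for j in range(model.n_components)],
    ).to_csv(out / "rcca_x_loadings.tsv", sep="\t", float_format=flio.FLOAT_FORMAT)
    pd.DataFrame(
        model.y_loadings, index=model.y_names,
        columns=[f"comp{j+1}" for j in range(model.n_components)],
    ).to_csv(out / "rcca_y_loadings.tsv", sep="\t", float_format=flio.FLOAT_FORMAT)
    scores = pd.DataFrame(
        np.hstack([model.x_scores[:, :2], model.y_scores[:, :2]]),
        index=X.index,
        columns=["x_variate1", "x_variate2", "y_variate1", "y_variate2"],
    )
    scores.to_csv(out / "rcca_variates.tsv", sep="\t", float_format=flio.FLOAT_FORMAT)
    pd.concat([coords_x, coords_y]).to_csv(
        out / "rcca_circle_coords.tsv", sep="\t", index=False,
        float_format=flio.FLOAT_FORMAT,
    )
    flrcca.pairs_to_frame(pairs).to_csv(
        out / "selected_pairs.tsv", sep="\t", index=False,
        float_format=flio.FLOAT_FORMAT,
    )
    with open(out / "rcca_model.json", "w") as fh:
        json.dump(
            {
                "lambda1": l1,
                "lambda2": l2,
                "canonical_correlations": [
                    round(float(c), 12) for c in model.canonical_correlations
                ],
                "n_subjects": int(X.shape[0]),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return {
        "rows": len(pairs),
        "lambda1": l1,
        "lambda2": l2,
        "first_canonical_correlation": round(
            float(model.canonical_correlations[0]), 12
        ),
        "n_complete_cases": int(X.shape[0]),
    }


def stage_linkstats(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    data = cfg.data_path
    clinical = flio.read_clinical(_require(data / "clinical.tsv"))
    engraftment = pd.read_csv(
        _require(out / "engraftment.tsv"), sep="\t", index_col=0
    )
    selected = pd.read_csv(_require(out / "selected_pairs.tsv"), sep="\t")

    # confirmatory LMM on the selected (SGB, clinical parameter) pairs
    pairs = [(r.x_feature, r.y_feature) for r in selected.itertuples()]
    lmm = flstats.fit_engraftment_lmm(clinical, engraftment, pairs)
    lmm_frame = flstats.lmm_results_to_frame(lmm)
    lmm_frame.to_csv(out / "lmm_results.tsv", sep="\t", index=False,
                     float_format=flio.FLOAT_FORMAT)

    # metabolites: preprocess, then test panel metabolites against the
    # SGBs of the selected pairs and correlate their change with the
    # clinical deltas
    metabolites = flstats.preprocess_metabolites(
        flio.read_metabolites(data / "metabolites.tsv")
    )
    flio.write_metabolites(metabolites, out / "metabolites_scaled.tsv")
    met_long_rows = []
    for (subject, time), row in metabolites.iterrows():
        for name in cfg.metabolite_panel:
            if name in metabolites.columns:
                met_long_rows.append(
                    (subject, name, time, float(row[name]), "scaled"))
    met_long = pd.DataFrame(
        met_long_rows,
        columns=["subject_id", "parameter", "time", "value", "units"],
    )
    sgbs = sorted({a for a, _ in pairs} & set(engraftment.index))
    met_pairs = [
        (s, m)
        for s in sgbs
        for m in cfg.metabolite_panel
        if m in metabolites.columns
    ]
    met_lmm = flstats.fit_engraftment_lmm(met_long, engraftment, met_pairs)
    flstats.lmm_results_to_frame(met_lmm).to_csv(
        out / "metabolite_lmm.tsv", sep="\t", index=False,
        float_format=flio.FLOAT_FORMAT,
    )

    # Spearman links: donor fraction vs clinical deltas, metabolite delta
    # vs clinical delta
    fractions = pd.read_csv(
        _require(out / "post_fractions.tsv"), sep="\t"
    ).set_index("subject_id")
    deltas = _clinical_deltas(clinical)
    corr_rows = []
    for parameter in deltas.columns:
        joined = fractions.join(deltas[parameter], how="inner").dropna(
            subset=["f_donor", parameter]
        )
        try:
            res = flstats.spearman_link(joined["f_donor"], joined[parameter])
        except NotEstimableError:
            continue
        corr_rows.append(
            {
                "x": "f_donor",
                "y": parameter,
                "rho": res.rho,
                "pvalue": res.pvalue,
                "n": res.n,
                "method": res.method,
            }
        )
    met_pre = metabolites.xs("pre", level="time")
    met_post = metabolites.xs("post", level="time")
    met_delta = (met_post - met_pre).dropna(how="all")
    for name in cfg.metabolite_panel:
        if name not in met_delta.columns:
            continue
        joined = met_delta[[name]].join(
            deltas[cfg.complete_case_parameter], how="inner"
        ).dropna()
        if len(joined) < 4:
            continue
        res = flstats.spearman_link(
            joined[name], joined[cfg.complete_case_parameter]
        )
        corr_rows.append(
            {
                "x": f"delta {name}",
                "y": f"delta {cfg.complete_case_parameter}",
                "rho": res.rho,
                "pvalue": res.pvalue,
                "n": res.n,
                "method": res.method,
            }
        )
    correlations = pd.DataFrame(corr_rows)
    correlations.to_csv(out / "spearman_links.tsv", sep="\t", index=False,
                        float_format=flio.FLOAT_FORMAT)

    # Procrustes concordance: engraftment configuration vs metabolite deltas
    subjects = sorted(
        set(engraftment.columns) & set(met_delta.index) & set(deltas.index)
    )
    A = engraftment[subjects].T.to_numpy(dtype=float)
    B = met_delta.loc[subjects].fillna(0.0).to_numpy(dtype=float)
    proc = flstats.procrustes_test(
        A, B, n_perm=cfg.n_perm, seed=cfg.seed, n_components=2
    )

    # multilevel decomposition of the metabolite table (within-subject part
    # carries the pre → post variation)
    between, within, flagged = flstats.multilevel_split(
        metabolites, metabolites.index.get_level_values("subject_id")
    )
    within.to_csv(out / "metabolites_within.tsv", sep="\t",
                  float_format=flio.FLOAT_FORMAT)

    summary = {
        "lmm_top": lmm_frame.iloc[0].to_dict() if len(lmm_frame) else {},
        "procrustes_m2": round(proc.m2, 12),
        "procrustes_p": proc.pvalue,
        "n_correlations": len(correlations),
        "n_single_observation_subjects": len(flagged),
    }
    with open(out / "linkstats_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return {
        "rows": len(lmm_frame),
        "procrustes_m2": round(proc.m2, 12),
        "procrustes_p": proc.pvalue,
    }


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "thresholds": stage_thresholds,
    "engraft": stage_engraft,
    "metrics": stage_metrics,
    "integrate": stage_integrate,
    "linkstats": stage_linkstats,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages in order and write the run manifest.

    Returns the manifest. A stage failure is recorded in the manifest
    (``failed_stage``) and re-raised after the manifest is written;
    partial outputs are preserved.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = cfg.to_dict()
    # the hash covers the scientific parameters, not filesystem locations,
    # so identical analyses in different directories hash identically
    hashed = {k: v for k, v in cfg_dict.items() if k not in ("out_dir", "data_dir")}
    cfg_hash = hashlib.sha256(
        json.dumps(hashed, sort_keys=True).encode()
    ).hexdigest()
    manifest: dict = {
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "seed": cfg.seed,
        "stages": {},
        "timing_s": {},
    }
    stages = [s for s in STAGES if s in cfg.stages]
    if not cfg.simulate:
        stages = [s for s in stages if s != "simulate"]
        if not cfg.data_path.exists():
            raise ConfigError(
                f"input data directory does not exist: {cfg.data_path} "
                "(simulation disabled)"
            )
    error: Exception | None = None
    for name in stages:
        t0 = time.perf_counter()
        log.info("stage %s starting", name)
        try:
            manifest["stages"][name] = _STAGE_FUNCS[name](cfg)
        except Exception as exc:  # record, then re-raise below
            manifest["failed_stage"] = name
            manifest["error"] = f"{type(exc).__name__}: {exc}"
            error = exc
            break
        finally:
            manifest["timing_s"][name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s done in %.2fs", name, manifest["timing_s"][name])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    if error is not None:
        raise error
    return manifest
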